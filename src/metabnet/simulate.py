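"""Synthetic two-group cohorts with a known covariance-generating graph.

Because group covariance networks are estimated from inter-subject
correlations, a synthetic cohort is fully specified by (i) a ground-truth
graph per group, (ii) a correlation matrix induced by that graph, and
(iii) a generative model mapping latent multivariate-normal signals to
positive, globally-scaled, covariate-confounded "metabolism-like" values.

The latent graph is a ring-rewired (Watts–Strogatz) small-world graph; the
induced correlation decays geometrically with graph distance,
``r_ij = edge_corr * corr_decay**(d_ij - 1)``, repaired to the nearest
positive-definite correlation matrix.  Group B can differ from group A by
degree-preserving rewiring of a fraction of latent edges, so group
differences are topological rather than degree-driven.

Default cohort sizes and covariate distributions follow a two-group
FDG-PET design: 73 subjects with elevated fasting glucose (8.4 ± 0.9
mmol/L, age 57 ± 10) versus 91 controls (5.1 ± 0.4 mmol/L, age 56 ± 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import BinaryNetwork, is_connected
from .preprocess import SubjectPanel

# latent -> uptake transform: value = global_i * BASE * exp(SHAPE * y)
_UPTAKE_BASE = 5.0  # SUV-like scale of the mean regional uptake
_UPTAKE_SHAPE = 0.15  # log-scale spread; small enough to keep exp() near-linear
_GLOBAL_SD = 0.2  # sd of the per-subject lognormal global factor

_GROUP_COVARIATES = {
    # mean age, sd age, P(male), mean glucose, sd glucose
    "A": (57.0, 10.0, 54 / 73, 8.4, 0.9),
    "B": (56.0, 8.0, 66 / 91, 5.1, 0.4),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic two-group cohort generator."""

    n_group_a: int = 73
    n_group_b: int = 91
    n_regions: int = 90
    latent_degree: int = 8
    rewire_prob: float = 0.1
    edge_corr: float = 0.6
    corr_decay: float = 0.5
    noise_sd: float = 0.2
    covariate_effects: Optional[np.ndarray] = None  # (n_regions, 3): age, sex, glucose
    group_b_perturbation: float = 0.0  # fraction of latent edges rewired in group B
    perturb_nodes: Optional[Sequence[int]] = None  # restrict rewiring to these nodes
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 3 or self.n_group_b < 3:
            raise ValueError("each group needs at least 3 subjects")
        if self.latent_degree >= self.n_regions:
            raise ValueError("latent_degree must be smaller than n_regions")
        for name in ("rewire_prob", "group_b_perturbation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("edge_corr", "corr_decay"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.covariate_effects is not None:
            eff = np.asarray(self.covariate_effects, dtype=float)
            if eff.shape != (self.n_regions, 3):
                raise ValueError(
                    f"covariate_effects must have shape ({self.n_regions}, 3), got {eff.shape}"
                )

    def effects(self) -> np.ndarray:
        """Per-region linear coefficients for (age, sex, glucose).

        Defaults are small region-graded effects with zero mean across
        regions (global normalization removes the region-average component
        of any covariate effect, so only relative effects are recoverable).
        """
        if self.covariate_effects is not None:
            return np.asarray(self.covariate_effects, dtype=float)
        g = np.linspace(-1, 1, self.n_regions)
        return np.column_stack((0.004 * g, 0.05 * g[::-1], -0.02 * g))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    adjacency_a: np.ndarray
    adjacency_b: np.ndarray
    correlation_a: np.ndarray
    correlation_b: np.ndarray
    covariate_effects: np.ndarray
    repair_deviation_a: float = 0.0
    repair_deviation_b: float = 0.0


def generate_latent_network(
    n_regions: int, latent_degree: int, rewire_prob: float, seed: int | None = None
) -> BinaryNetwork:
    """Connected ring-rewired lattice with exactly ``n k / 2`` edges.

    At ``rewire_prob = 0`` this is the deterministic ring lattice where each
    node links to its ``latent_degree`` nearest ring neighbours; rewiring
    relocates edges without changing the edge count, so the realized density
    is exactly ``latent_degree / (n_regions - 1)``.
    """
    if latent_degree < 2 or latent_degree % 2:
        raise ValueError(f"latent_degree must be even and >= 2, got {latent_degree}")
    if latent_degree >= n_regions:
        raise ValueError("latent_degree must be smaller than n_regions")
    if rewire_prob == 0:
        G = nx.watts_strogatz_graph(n_regions, latent_degree, 0)
    else:
        G = nx.connected_watts_strogatz_graph(
            n_regions, latent_degree, rewire_prob, tries=1000, seed=seed
        )
    A = nx.to_numpy_array(G, nodelist=range(n_regions))
    A[A > 0] = 1.0
    return BinaryNetwork(adjacency=A, density=latent_degree / (n_regions - 1))


def nearest_pd_correlation(
    R: np.ndarray, floor: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped positive-definite repair of a correlation matrix.

    Clips eigenvalues at ``floor`` and renormalizes to unit diagonal,
    iterating because renormalization can reintroduce tiny negative
    eigenvalues.  Returns the repaired matrix and the maximum absolute
    deviation from the input.
    """
    R0 = R.copy()
    out = (R + R.T) / 2
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() > floor / 2:
            break
        vals = np.clip(vals, floor, None)
        out = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
        np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("correlation matrix could not be repaired to positive definite")
    return out, float(np.abs(out - R0).max())


def correlation_from_network(
    net: BinaryNetwork, edge_corr: float, corr_decay: float
) -> tuple[np.ndarray, float]:
    """Distance-decay correlation matrix induced by a connected graph.

    Entry ``(i, j)`` targets ``edge_corr * corr_decay**(d_ij - 1)`` for
    shortest-path distance ``d_ij``; the result is repaired to the nearest
    positive-definite correlation matrix.  Returns the matrix and the
    repair's maximum absolute deviation from the target.
    """
    if not is_connected(net):
        raise ValueError("latent network must be connected")
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import shortest_path

    D = shortest_path(csr_array(net.adjacency), method="D", unweighted=True, directed=False)
    R = edge_corr * corr_decay ** (D - 1)
    np.fill_diagonal(R, 1.0)
    return nearest_pd_correlation(R)


def rewire_fraction(
    adjacency: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    nodes: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Degree-preserving rewiring of roughly ``fraction`` of the edges.

    Performs ``round(fraction * m / 2)`` double edge swaps (each swap
    relocates two edges).  With ``nodes`` given, the first edge of every
    swap is drawn from edges incident to those nodes, concentrating the
    topological change there while still preserving every degree.
    """
    A = adjacency.copy()
    m = int(A.sum()) // 2
    n_swaps = int(round(fraction * m / 2))
    if n_swaps == 0:
        return A
    targeted = set(int(v) for v in nodes) if nodes is not None else None
    edges = [tuple(e) for e in np.argwhere(np.triu(A) > 0)]
    done = 0
    for _ in range(1000 * n_swaps):
        if done >= n_swaps:
            break
        if targeted is not None:
            pool = [e for e in edges if e[0] in targeted or e[1] in targeted]
            if not pool:
                break
            u, v = pool[rng.integers(len(pool))]
        else:
            u, v = edges[rng.integers(len(edges))]
        x, y = edges[rng.integers(len(edges))]
        if rng.random() < 0.5:
            x, y = y, x
        # swap (u,v),(x,y) -> (u,x),(v,y)
        if len({u, v, x, y}) < 4 or A[u, x] or A[v, y]:
            continue
        A[u, v] = A[v, u] = A[x, y] = A[y, x] = 0
        A[u, x] = A[x, u] = A[v, y] = A[y, v] = 1
        edges = [tuple(e) for e in np.argwhere(np.triu(A) > 0)]
        done += 1
    return A


def sample_panel(
    correlation: np.ndarray,
    n_subjects: int,
    group: str,
    effects: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    region_labels: Optional[Sequence[str]] = None,
    subject_prefix: str = "S",
) -> SubjectPanel:
    """Draw one group's panel from a planted correlation matrix.

    Pipeline: latent MVN signal with the planted correlation -> add linear
    covariate effects (standardized covariates) and independent noise ->
    exponentiate to a positive uptake scale -> multiply by a per-subject
    lognormal global factor.  Global normalization exactly removes the
    global factor; residualization removes the covariate effects.
    """
    p = correlation.shape[0]
    stats = _GROUP_COVARIATES.get(group, _GROUP_COVARIATES["A"])
    age_mu, age_sd, p_male, glu_mu, glu_sd = stats
    age = rng.normal(age_mu, age_sd, n_subjects)
    sex = (rng.random(n_subjects) < p_male).astype(float)
    glucose = rng.normal(glu_mu, glu_sd, n_subjects)
    # standardized covariates keep the planted effect sizes unit-comparable
    X = np.column_stack(((age - 56.5) / 10.0, sex - 0.5, (glucose - 6.75) / 1.7))

    L = np.linalg.cholesky(correlation)
    Z = rng.standard_normal((n_subjects, p)) @ L.T
    Y = Z + X @ effects.T + noise_sd * rng.standard_normal((n_subjects, p))
    global_factor = np.exp(rng.normal(0.0, _GLOBAL_SD, n_subjects))
    values = global_factor[:, None] * _UPTAKE_BASE * np.exp(_UPTAKE_SHAPE * Y)

    labels = list(region_labels) if region_labels is not None else [
        f"R{i + 1:03d}" for i in range(p)
    ]
    ids = [f"{subject_prefix}{i + 1:03d}" for i in range(n_subjects)]
    return SubjectPanel(
        values=pd.DataFrame(values, index=ids, columns=labels),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "glucose": glucose}, index=ids
        ),
        group=group,
    )


def generate_cohort(
    spec: CohortSpec, region_labels: Optional[Sequence[str]] = None
) -> tuple[SubjectPanel, SubjectPanel, GroundTruth]:
    """Two-group synthetic cohort plus the planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    net_a = generate_latent_network(
        spec.n_regions, spec.latent_degree, spec.rewire_prob,
        seed=int(rng.integers(2**31)),
    )
    adj_a = net_a.adjacency
    if spec.group_b_perturbation > 0:
        adj_b = rewire_fraction(
            adj_a, spec.group_b_perturbation, rng, nodes=spec.perturb_nodes
        )
    else:
        adj_b = adj_a.copy()
    corr_a, dev_a = correlation_from_network(
        BinaryNetwork(adj_a, net_a.density), spec.edge_corr, spec.corr_decay
    )
    if np.array_equal(adj_a, adj_b):
        corr_b, dev_b = corr_a, dev_a
    else:
        corr_b, dev_b = correlation_from_network(
            BinaryNetwork(adj_b, net_a.density), spec.edge_corr, spec.corr_decay
        )
    effects = spec.effects()
    panel_a = sample_panel(
        corr_a, spec.n_group_a, "A", effects, spec.noise_sd, rng,
        region_labels, subject_prefix="A",
    )
    panel_b = sample_panel(
        corr_b, spec.n_group_b, "B", effects, spec.noise_sd, rng,
        region_labels, subject_prefix="B",
    )
    truth = GroundTruth(
        adjacency_a=adj_a, adjacency_b=adj_b,
        correlation_a=corr_a, correlation_b=corr_b,
        covariate_effects=effects,
        repair_deviation_a=dev_a, repair_deviation_b=dev_b,
    )
    return panel_a, panel_b, truth


def generate_null_pair(
    spec: CohortSpec, region_labels: Optional[Sequence[str]] = None
) -> tuple[SubjectPanel, SubjectPanel]:
    """Two panels drawn i.i.d. from the identical generative model.

    Both groups share group A's latent graph, correlation matrix and
    covariate distributions, so the pooled cohort is exchangeable under
    group relabeling — the configuration for type-I-error checks.
    """
    null_spec = replace(spec, group_b_perturbation=0.0, perturb_nodes=None)
    null_spec.validate()
    rng = np.random.default_rng(null_spec.seed)
    net = generate_latent_network(
        null_spec.n_regions, null_spec.latent_degree, null_spec.rewire_prob,
        seed=int(rng.integers(2**31)),
    )
    corr, _ = correlation_from_network(net, null_spec.edge_corr, null_spec.corr_decay)
    effects = null_spec.effects()
    panel_a = sample_panel(
        corr, null_spec.n_group_a, "A", effects, null_spec.noise_sd, rng,
        region_labels, subject_prefix="A",
    )
    panel_b = sample_panel(
        corr, null_spec.n_group_b, "A", effects, null_spec.noise_sd, rng,
        region_labels, subject_prefix="B",
    )
    panel_b.group = "B"
    return panel_a, panel_b
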