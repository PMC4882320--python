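"""Graph-theoretical characterization of the binary networks.

Implements the standard small-world and centrality measures used for
metabolic covariance networks:

* nodal clustering ``C_i = 2 e_i / (k_i (k_i - 1))`` and its network mean
  ``C`` (``C_i = 0`` for degree < 2, included in the mean);
* characteristic path length ``L``, the mean unweighted shortest-path
  length over ordered node pairs;
* Freeman betweenness ``B(i) = sum_{j<k} n_jk(i) / n_jk`` (endpoints
  excluded), normalized per node as ``b_i = B(i) / mean(B)``;
* small-world normalization against degree-preserving random references:
  ``gamma = C / <C_random>``, ``lambda = L / <L_random>``, and the
  small-world index ``sigma = gamma / lambda``;
* hub detection: regions with ``b_i > 1.5``.

Shortest-path machinery comes from scipy's csgraph and betweenness from
networkx's Brandes implementation; the test suite checks both against
brute-force oracles.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .atlas import Region, RegionTable
from .network import BinaryNetwork

HUB_THRESHOLD = 1.5


class DisconnectedNetworkError(ValueError):
    """Raised when a path-based metric is requested on a disconnected graph."""


@dataclass
class GlobalMetrics:
    """Clustering, path length and their random-reference normalizations."""

    C: float
    L: float
    gamma: float
    lambda_: float
    sigma: float
    density: float
    n_random_refs: int
    c_random: float = np.nan
    l_random: float = np.nan
    ref_c: np.ndarray | None = None  # per-reference values, for dispersion
    ref_l: np.ndarray | None = None
    n_disconnected_refs: int = 0


@dataclass
class NodalCentrality:
    """Per-node betweenness, normalized betweenness, degree and clustering."""

    B: np.ndarray
    b: np.ndarray
    degree: np.ndarray
    C_i: np.ndarray
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.B, "b": self.b, "degree": self.degree, "C_i": self.C_i},
            index=self.labels or range(len(self.B)),
        )


@dataclass
class HubSet:
    """Regions whose normalized betweenness exceeds the hub threshold."""

    entries: list[tuple[Region, float]]  # sorted by descending b
    threshold: float = HUB_THRESHOLD

    @property
    def regions(self) -> list[Region]:
        return [r for r, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _as_adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    return net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net, dtype=float)


def nodal_clustering(net: BinaryNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their unweighted mean.

    ``(A^3)_ii`` counts twice the edges among the neighbours of ``i``, so
    ``C_i = (A^3)_ii / (k_i (k_i - 1))``; nodes with degree < 2 get 0.
    """
    A = _as_adjacency(net)
    k = A.sum(axis=1)
    closed = np.diag(A @ A @ A)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C_i = np.where(denom > 0, closed / np.where(denom > 0, denom, 1), 0.0)
    return C_i, float(C_i.mean())


def _distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(A), method="D", unweighted=True, directed=False)


def characteristic_path_length(
    net: BinaryNetwork | np.ndarray, on_disconnected: str = "error"
) -> float:
    """Mean shortest-path length over all ordered pairs ``i != j``.

    ``on_disconnected='error'`` (default) raises on a disconnected network,
    naming the component sizes; ``'connected_pairs'`` averages over the
    reachable pairs only (used for sparse random references, where dropping
    disconnected realizations would bias the normalization).
    """
    A = _as_adjacency(net)
    n = A.shape[0]
    D = _distances(A)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if finite.sum() < off.sum():
        if on_disconnected == "error":
            from scipy.sparse.csgraph import connected_components

            _, labels = connected_components(csr_array(A), directed=False)
            sizes = sorted((int(s) for s in np.bincount(labels)), reverse=True)
            raise DisconnectedNetworkError(
                f"network is disconnected (component sizes {sizes})"
            )
        if on_disconnected != "connected_pairs":
            raise ValueError(f"unknown disconnected mode {on_disconnected!r}")
    return float(D[finite].mean())


def betweenness(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Freeman betweenness per node (unordered pairs, endpoints excluded)."""
    A = _as_adjacency(net)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


def normalized_betweenness(B: np.ndarray) -> np.ndarray:
    """``b_i = B(i) / mean(B)``; mean of the output is 1."""
    B = np.asarray(B, dtype=float)
    mean = B.mean()
    if mean <= 0:
        raise ValueError("mean betweenness is zero; normalized betweenness undefined")
    return B / mean


def nodal_centrality(net: BinaryNetwork) -> NodalCentrality:
    """Degree, clustering, betweenness and normalized betweenness per node."""
    A = _as_adjacency(net)
    B = betweenness(A)
    C_i, _ = nodal_clustering(A)
    return NodalCentrality(
        B=B,
        b=normalized_betweenness(B),
        degree=A.sum(axis=1).astype(int),
        C_i=C_i,
        labels=list(net.labels) if isinstance(net, BinaryNetwork) else [],
    )


def random_reference(
    net: BinaryNetwork | np.ndarray,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
) -> BinaryNetwork:
    """Degree-preserving randomization by repeated double edge swaps.

    The reference keeps the node count, degree sequence (hence mean degree
    and degree distribution) of the input while destroying its local
    structure.  Graphs admitting no valid swap are returned unchanged with
    a warning.
    """
    A = _as_adjacency(net)
    G = nx.from_numpy_array(A)
    m = G.number_of_edges()
    if m >= 2:
        nswap = n_swaps_per_edge * m
        try:
            nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap, seed=seed)
        except nx.NetworkXError as exc:
            warnings.warn(f"double edge swap stopped early: {exc}")
    else:
        warnings.warn("graph has fewer than 2 edges; returning it unchanged")
    A_rand = nx.to_numpy_array(G, nodelist=range(A.shape[0]))
    A_rand[A_rand > 0] = 1.0
    density = net.density if isinstance(net, BinaryNetwork) else (
        m / (A.shape[0] * (A.shape[0] - 1) / 2)
    )
    labels = list(net.labels) if isinstance(net, BinaryNetwork) else []
    return BinaryNetwork(adjacency=A_rand, density=density, labels=labels)


def small_world(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
    on_disconnected: str = "error",
) -> GlobalMetrics:
    """Normalize C and L against degree-matched random references.

    ``C_random`` and ``L_random`` are means over ``n_random`` independent
    degree-preserving randomizations.  References that come out disconnected
    contribute their connected-pairs path length and are counted in
    ``n_disconnected_refs`` rather than discarded (discarding would bias the
    reference ensemble at sparse densities).  ``on_disconnected`` governs
    the real network: ``'error'`` (default) or ``'connected_pairs'``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    A = _as_adjacency(net)
    _, C_real = nodal_clustering(A)
    L_real = characteristic_path_length(A, on_disconnected=on_disconnected)
    ref_c = np.empty(n_random)
    ref_l = np.empty(n_random)
    n_disc = 0
    for i in range(n_random):
        ref = random_reference(net, n_swaps_per_edge, seed=int(rng.integers(2**31)))
        _, ref_c[i] = nodal_clustering(ref.adjacency)
        try:
            ref_l[i] = characteristic_path_length(ref.adjacency, on_disconnected="error")
        except DisconnectedNetworkError:
            n_disc += 1
            ref_l[i] = characteristic_path_length(
                ref.adjacency, on_disconnected="connected_pairs"
            )
    c_rand = float(ref_c.mean())
    l_rand = float(ref_l.mean())
    gamma = C_real / c_rand
    lambda_ = L_real / l_rand
    return GlobalMetrics(
        C=C_real,
        L=L_real,
        gamma=gamma,
        lambda_=lambda_,
        sigma=gamma / lambda_,
        density=net.density,
        n_random_refs=n_random,
        c_random=c_rand,
        l_random=l_rand,
        ref_c=ref_c,
        ref_l=ref_l,
        n_disconnected_refs=n_disc,
    )


def identify_hubs(
    nc: NodalCentrality | np.ndarray,
    region_table: RegionTable,
    threshold: float = HUB_THRESHOLD,
) -> HubSet:
    """Regions with normalized betweenness above the hub threshold.

    Sorted by descending ``b_i``; exact ties broken by canonical region
    index.  An empty hub set is a valid result.
    """
    b = nc.b if isinstance(nc, NodalCentrality) else np.asarray(nc, dtype=float)
    if len(b) != len(region_table):
        raise ValueError(
            f"centrality vector length {len(b)} != region table size {len(region_table)}"
        )
    picked = [(region_table[i], float(b[i])) for i in np.flatnonzero(b > threshold)]
    picked.sort(key=lambda e: (-e[1], e[0].index))
    return HubSet(entries=picked, threshold=threshold)


def shared_hubs(h1: HubSet, h2: HubSet) -> list[Region]:
    """Intersection of two hub sets, in canonical atlas order."""
    keys = {(r.abbreviation, r.hemisphere) for r in h2.regions}
    common = [r for r in h1.regions if (r.abbreviation, r.hemisphere) in keys]
    return sorted(common, key=lambda r: r.index)


# ---------------------------------------------------------------------------
# Bundled reference hub tables (normalized betweenness of the two groups of
# the motivating cohort study: "dm" = diabetic, "nc" = normal control).
# ---------------------------------------------------------------------------

_REFERENCE_FILES = {"dm": "reference_hubs_dm.tsv", "nc": "reference_hubs_nc.tsv"}


def load_reference_centrality(group: str) -> pd.DataFrame:
    """Bundled reference table of hub normalized betweenness for one group."""
    try:
        fname = _REFERENCE_FILES[group.lower()]
    except KeyError:
        raise ValueError(f"unknown reference group {group!r}; use 'dm' or 'nc'") from None
    text = resources.files("metabnet.data").joinpath(fname).read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    return pd.DataFrame(
        {
            "abbreviation": [r["abbreviation"] for r in rows],
            "hemisphere": [r["hemisphere"] for r in rows],
            "func_class": [r["func_class"] for r in rows],
            "b": [float(r["b"]) for r in rows],
        }
    )


def centrality_table_to_array(
    table: pd.DataFrame, region_table: RegionTable, fill: float = 0.0
) -> np.ndarray:
    """Expand a (abbreviation, hemisphere, b) table to a full per-node vector.

    Regions absent from the table get ``fill`` (reference tables list hub
    rows only; unlisted regions sit below the hub threshold).
    """
    b = np.full(len(region_table), fill, dtype=float)
    for _, row in table.iterrows():
        region = region_table.lookup(row["abbreviation"], row["hemisphere"])
        b[region.index - 1] = row["b"]
    return b
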