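"""Group correlation matrices and density-thresholded binary networks.

The group network is the across-subject Pearson correlation matrix of the
residualized regional values, binarized by connection density: for density
``d`` the ``round(d * N(N-1)/2)`` region pairs with the largest ``|r|``
become edges.  Because no single threshold is canonical, properties are
estimated over a sweep of densities (default 10–40% in 1% steps).
Anticorrelations count via the absolute value by default; a positive-only
mode is available as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .preprocess import ResidualPanel


@dataclass
class CorrelationMatrix:
    """Symmetric inter-regional Pearson matrix computed across subjects."""

    r: np.ndarray
    n_subjects: int
    labels: list[str] = field(default_factory=list)
    group: str = ""

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a given connection density."""

    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    density: float  # realized edge fraction
    source_threshold: Optional[float] = None  # |r| cutoff actually applied
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def validate(self) -> None:
        A = self.adjacency
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency is not symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency has self-loops")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency is not binary")


def pearson_matrix(res: ResidualPanel, group: str | None = None) -> CorrelationMatrix:
    """Across-subject Pearson correlation of the residual panel."""
    Y = res.matrix()
    n, p = Y.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects to correlate, got {n}")
    sd = Y.std(axis=0)
    # tolerance catches constant columns stored with float round-off
    tiny = sd <= 1e-12 * np.maximum(1.0, np.abs(Y).max(axis=0))
    if np.any(tiny):
        bad = res.region_labels[int(np.flatnonzero(tiny)[0])]
        raise ValueError(f"region {bad!r} has zero variance across subjects")
    r = np.corrcoef(Y.T)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        r=r, n_subjects=n, labels=list(res.region_labels),
        group=res.group if group is None else group,
    )


def _edge_order(r: np.ndarray, positive_only: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by (larger |r|, smaller i, smaller j)."""
    n = r.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    weight = r[ii, jj] if positive_only else np.abs(r[ii, jj])
    order = np.lexsort((jj, ii, -weight))
    return ii[order], jj[order], weight[order]


def threshold_adjacency(
    r: np.ndarray, density: float, positive_only: bool = False
) -> tuple[np.ndarray, float, float]:
    """Binarize a correlation matrix at a connection density.

    Returns ``(adjacency, realized_density, cutoff)`` where ``cutoff`` is the
    smallest retained ``|r|``.  Ties at the cutoff are broken
    deterministically by larger ``|r|``, then smaller row, then smaller
    column index, so results are bit-reproducible.
    """
    n = r.shape[0]
    n_pairs = n * (n - 1) // 2
    k = int(round(density * n_pairs))
    if k < 1:
        raise ValueError(f"density {density} keeps no edges among {n_pairs} pairs")
    if k > n_pairs:
        raise ValueError(f"density {density} exceeds the {n_pairs} possible pairs")
    ii, jj, weight = _edge_order(r, positive_only)
    keep_i, keep_j = ii[:k], jj[:k]
    A = np.zeros((n, n))
    A[keep_i, keep_j] = 1.0
    A[keep_j, keep_i] = 1.0
    return A, k / n_pairs, float(weight[k - 1])


def density_threshold(
    corr: CorrelationMatrix, density: float, positive_only: bool = False
) -> BinaryNetwork:
    """Keep the ``round(density * N(N-1)/2)`` strongest ``|r|`` pairs as edges."""
    if not 0 < density < 1:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    A, realized, cutoff = threshold_adjacency(corr.r, density, positive_only)
    return BinaryNetwork(
        adjacency=A, density=realized, source_threshold=cutoff, labels=list(corr.labels)
    )


def sweep_densities(d_min: float = 0.10, d_max: float = 0.40, step: float = 0.01) -> list[float]:
    """The density grid, computed in integer arithmetic to dodge float drift."""
    if step <= 0 or d_max < d_min:
        raise ValueError("empty density range")
    n_steps = int(round((d_max - d_min) / step))
    densities = [round(d_min + i * step, 10) for i in range(n_steps + 1)]
    return [d for d in densities if d <= d_max + 1e-12]


def density_sweep(
    corr: CorrelationMatrix,
    d_min: float = 0.10,
    d_max: float = 0.40,
    step: float = 0.01,
    positive_only: bool = False,
) -> list[BinaryNetwork]:
    """Binarize over the density range (default 10–40%, 1% increments)."""
    return [
        density_threshold(corr, d, positive_only) for d in sweep_densities(d_min, d_max, step)
    ]


def largest_component_size(net: BinaryNetwork | np.ndarray) -> int:
    """Number of nodes in the largest connected component."""
    A = net.adjacency if isinstance(net, BinaryNetwork) else net
    n_comp, labels = connected_components(csr_array(A), directed=False)
    return int(np.bincount(labels, minlength=n_comp).max())


def is_connected(net: BinaryNetwork | np.ndarray) -> bool:
    A = net.adjacency if isinstance(net, BinaryNetwork) else net
    return largest_component_size(A) == A.shape[0]


def min_full_connection_density(
    corr: CorrelationMatrix, densities: Sequence[float] | None = None
) -> Optional[float]:
    """Smallest sweep density whose network spans all regions, or ``None``.

    ``None`` is a reported absence (no density in the sweep fully connects
    the graph), not an error.
    """
    if densities is None:
        densities = sweep_densities()
    if len(densities) == 0:
        raise ValueError("empty density sweep")
    for d in sorted(densities):
        net = density_threshold(corr, d)
        if largest_component_size(net) == corr.n_regions:
            return d
    return None
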