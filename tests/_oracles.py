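"""Brute-force graph-metric oracles, independent of the package internals.

Deliberately naive implementations: triangle counting by neighbour-pair
enumeration, Floyd–Warshall distances, and shortest-path counting by
dynamic programming over distance layers.  They share no code path with
the package (which uses matrix powers, scipy's Dijkstra and networkx's
Brandes algorithm).
"""

from __future__ import annotations

import numpy as np


def oracle_clustering(A: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.asarray(A)
    n = len(A)
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(
            1 for a in range(k) for b in range(a + 1, k) if A[nbrs[a], nbrs[b]]
        )
        C[i] = 2 * e / (k * (k - 1))
    return C, float(C.mean())


def oracle_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by Floyd–Warshall."""
    n = len(A)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[np.asarray(A) > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def oracle_path_length(A: np.ndarray, connected_pairs_only: bool = False) -> float:
    D = oracle_distances(A)
    n = len(A)
    off = ~np.eye(n, dtype=bool)
    if connected_pairs_only:
        mask = off & np.isfinite(D)
        return float(D[mask].mean())
    return float(D[off].mean())


def oracle_shortest_path_counts(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """N[j, k] = number of shortest j-k paths, by distance-layer recursion."""
    n = len(A)
    N = np.zeros((n, n))
    for j in range(n):
        N[j, j] = 1.0
        for k in sorted(range(n), key=lambda x: D[j, x]):
            if k == j or not np.isfinite(D[j, k]):
                continue
            N[j, k] = sum(
                N[j, m] for m in range(n) if A[k, m] and D[j, m] == D[j, k] - 1
            )
    return N


def oracle_betweenness(A: np.ndarray) -> np.ndarray:
    """Freeman betweenness: unordered pairs, endpoints excluded.

    Uses the path-composition identity n_jk(i) = n_ji * n_ik when i lies on
    a shortest j-k path (d_ji + d_ik = d_jk).
    """
    A = np.asarray(A)
    n = len(A)
    D = oracle_distances(A)
    N = oracle_shortest_path_counts(A, D)
    B = np.zeros(n)
    for j in range(n):
        for k in range(j + 1, n):
            if not np.isfinite(D[j, k]) or N[j, k] == 0:
                continue
            for i in range(n):
                if i in (j, k):
                    continue
                if D[j, i] + D[i, k] == D[j, k]:
                    B[i] += N[j, i] * N[i, k] / N[j, k]
    return B


def random_connected_adjacency(n: int, rng: np.random.Generator, p: float = 0.3) -> np.ndarray:
    """Random Erdos–Renyi adjacency, resampled until connected (BFS check)."""
    while True:
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(A[u]):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) == n:
            return A
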