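import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import random_connected_adjacency
from metabnet.network import (
    BinaryNetwork,
    CorrelationMatrix,
    density_sweep,
    density_threshold,
    largest_component_size,
    min_full_connection_density,
    pearson_matrix,
    sweep_densities,
)
from metabnet.preprocess import ResidualPanel


def residual_panel(matrix):
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, columns=[f"R{j}" for j in range(matrix.shape[1])])
    coef = pd.DataFrame(index=df.columns)
    return ResidualPanel(residuals=df, coefficients=coef, group="A")


def random_corr(n, seed):
    """Symmetric matrix with distinct off-diagonal entries in (-1, 1)."""
    rng = np.random.default_rng(seed)
    r = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(-0.99, 0.99, len(iu[0]))
    r[iu] = vals
    r += r.T
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, n_subjects=50)


class TestPearsonMatrix:
    def test_identical_and_negated_columns(self):
        x = np.random.default_rng(0).normal(size=20)
        res = residual_panel(np.column_stack([x, x, -x]))
        corr = pearson_matrix(res)
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(5, 3))
        corr = pearson_matrix(residual_panel(Y))
        for i in range(3):
            for j in range(3):
                xi, xj = Y[:, i] - Y[:, i].mean(), Y[:, j] - Y[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_region_named(self):
        Y = np.random.default_rng(2).normal(size=(10, 3))
        Y[:, 1] = 4.2
        with pytest.raises(ValueError, match="R1"):
            pearson_matrix(residual_panel(Y))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            pearson_matrix(residual_panel(np.random.default_rng(0).normal(size=(2, 4))))


class TestDensityThreshold:
    def test_keeps_exactly_the_strongest_pairs(self):
        corr = random_corr(4, 0)
        net = density_threshold(corr, 0.5)
        assert net.n_edges == 3
        iu = np.triu_indices(4, 1)
        strongest = np.sort(np.abs(corr.r[iu]))[-3:]
        kept = np.abs(corr.r[iu])[net.adjacency[iu] > 0]
        assert np.allclose(np.sort(kept), strongest)
        assert net.source_threshold == pytest.approx(strongest.min())
        net.validate()

    @pytest.mark.parametrize("seed", range(5))
    def test_near_full_density_is_complement_of_weakest(self, seed):
        corr = random_corr(6, seed)
        n_pairs = 15
        net = density_threshold(corr, (n_pairs - 1) / n_pairs)
        iu = np.triu_indices(6, 1)
        absr = np.abs(corr.r[iu])
        # brute-force sort oracle: the one missing edge is the weakest pair
        missing = np.flatnonzero(net.adjacency[iu] == 0)
        assert len(missing) == 1
        assert missing[0] == np.argsort(absr)[0]

    def test_sign_blind(self):
        corr = random_corr(8, 3)
        net = density_threshold(corr, 0.3)
        flipped = corr.r.copy()
        iu = np.triu_indices(8, 1)
        flipped[iu] *= -1
        flipped[(iu[1], iu[0])] *= -1
        net2 = density_threshold(CorrelationMatrix(r=flipped, n_subjects=50), 0.3)
        assert np.array_equal(net.adjacency, net2.adjacency)

    def test_positive_only_mode_excludes_anticorrelations(self):
        corr = random_corr(8, 3)
        net = density_threshold(corr, 0.2, positive_only=True)
        iu = np.triu_indices(8, 1)
        assert corr.r[iu][net.adjacency[iu] > 0].min() > 0

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10**6))
    def test_nestedness_across_densities(self, seed):
        corr = random_corr(7, seed)
        small = density_threshold(corr, 0.2).adjacency
        large = density_threshold(corr, 0.6).adjacency
        assert np.all(large[small > 0] == 1)

    def test_degenerate_densities_rejected(self):
        corr = random_corr(5, 1)
        with pytest.raises(ValueError):
            density_threshold(corr, 0.01)  # keeps no edges
        with pytest.raises(ValueError):
            density_threshold(corr, 1.0)


class TestDensitySweep:
    def test_default_grid_has_31_networks(self):
        assert len(sweep_densities()) == 31
        corr = random_corr(20, 4)
        nets = density_sweep(corr)
        assert len(nets) == 31

    def test_realized_density_within_one_edge(self):
        corr = random_corr(20, 5)
        n_pairs = 20 * 19 // 2
        for net, d in zip(density_sweep(corr), sweep_densities()):
            assert abs(net.n_edges - d * n_pairs) <= 0.5 + 1e-9

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sweep_densities(0.4, 0.1)


class TestComponents:
    def test_known_components(self):
        ring = np.roll(np.eye(6), 1, axis=1)
        ring = ((ring + ring.T) > 0).astype(float)
        assert largest_component_size(ring) == 6
        two_triangles = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
            two_triangles[a, b] = two_triangles[b, a] = 1
        assert largest_component_size(two_triangles) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((12, 12)) < 0.15).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        # independent BFS oracle
        unvisited = set(range(12))
        best = 0
        while unvisited:
            start = unvisited.pop()
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(A[u]):
                    if v in unvisited:
                        unvisited.discard(int(v))
                        comp.add(int(v))
                        stack.append(int(v))
            best = max(best, len(comp))
        assert largest_component_size(A) == best


class TestMinFullConnectionDensity:
    def test_matches_exhaustive_scan(self, small_cohort):
        from metabnet.preprocess import preprocess

        panel_a, _, _ = small_cohort
        corr = pearson_matrix(preprocess(panel_a))
        densities = sweep_densities(0.05, 0.40, 0.01)
        found = min_full_connection_density(corr, densities)
        scan = [
            d for d in densities
            if largest_component_size(density_threshold(corr, d)) == corr.n_regions
        ]
        assert found == min(scan)

    def test_uniformly_strong_matrix_connects_at_minimum(self):
        # all |r| tied: the deterministic tie-break keeps lexicographically
        # first pairs, a star-plus-extras that already spans at d_min
        r = np.full((10, 10), 0.9)
        np.fill_diagonal(r, 1.0)
        corr = CorrelationMatrix(r=r, n_subjects=50)
        densities = sweep_densities(0.25, 0.60, 0.05)
        assert min_full_connection_density(corr, densities) == 0.25

    def test_isolated_region_reports_absence(self):
        corr = random_corr(10, 9)
        r = corr.r.copy()
        r[5, :] = r[:, 5] = 0.001  # region 5 barely correlates with anything
        np.fill_diagonal(r, 1.0)
        weak = CorrelationMatrix(r=r, n_subjects=50)
        densities = [0.05, 0.1]
        assert min_full_connection_density(weak, densities) is None
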