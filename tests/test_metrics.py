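import networkx as nx
import numpy as np
import pytest

from _oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_path_length,
    random_connected_adjacency,
)
from metabnet.metrics import (
    DisconnectedNetworkError,
    betweenness,
    centrality_table_to_array,
    characteristic_path_length,
    identify_hubs,
    load_reference_centrality,
    nodal_centrality,
    nodal_clustering,
    normalized_betweenness,
    random_reference,
    shared_hubs,
    small_world,
)
from metabnet.network import BinaryNetwork
from metabnet.simulate import generate_latent_network


def adjacency_from_edges(n, edges):
    A = np.zeros((n, n))
    for u, v in edges:
        A[u, v] = A[v, u] = 1
    return A


def atlas_connected_graphs():
    """All connected graphs of the networkx atlas (non-isomorphic, 2-7 nodes)."""
    from networkx.generators.atlas import graph_atlas_g

    for G in graph_atlas_g():
        if G.number_of_nodes() >= 2 and nx.is_connected(G):
            yield nx.to_numpy_array(G)


class TestKnownValues:
    def test_triangle(self):
        A = adjacency_from_edges(3, [(0, 1), (1, 2), (2, 0)])
        C_i, C = nodal_clustering(A)
        assert np.allclose(C_i, 1.0) and C == 1.0
        assert characteristic_path_length(A) == 1.0

    def test_path_graph_clustering_and_length(self):
        P3 = adjacency_from_edges(3, [(0, 1), (1, 2)])
        C_i, _ = nodal_clustering(P3)
        assert C_i[1] == 0.0  # degree 2, no neighbour edge
        P4 = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert characteristic_path_length(P4) == pytest.approx(10 / 6)

    def test_star_betweenness(self):
        star = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        B = betweenness(star)
        assert B[0] == pytest.approx(3.0)  # all 3 leaf pairs route through the hub
        assert np.allclose(B[1:], 0.0)
        b = normalized_betweenness(B)
        assert b[0] == pytest.approx(4.0)
        assert b.mean() == pytest.approx(1.0)

    def test_cycle_betweenness_splits_ties(self):
        C4 = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert np.allclose(betweenness(C4), 0.5)

    def test_complete_graph_has_undefined_normalization(self):
        K5 = 1 - np.eye(5)
        assert np.allclose(betweenness(K5), 0.0)
        with pytest.raises(ValueError, match="undefined"):
            normalized_betweenness(betweenness(K5))

    def test_constant_betweenness_normalizes_to_one(self):
        assert np.allclose(normalized_betweenness(np.full(6, 2.5)), 1.0)


class TestOracleEquivalence:
    """C, L and B(i) against independent brute-force implementations."""

    def test_all_small_connected_graphs(self):
        count = 0
        for A in atlas_connected_graphs():
            C_i, C = nodal_clustering(A)
            oC_i, oC = oracle_clustering(A)
            assert np.allclose(C_i, oC_i) and C == pytest.approx(oC)
            assert characteristic_path_length(A) == pytest.approx(oracle_path_length(A))
            assert np.allclose(betweenness(A), oracle_betweenness(A), atol=1e-9)
            count += 1
        assert count == 995  # every connected atlas graph on 2..7 nodes

    @pytest.mark.parametrize("seed", range(40))
    def test_sampled_eight_node_graphs(self, seed):
        A = random_connected_adjacency(8, np.random.default_rng(seed))
        assert np.allclose(nodal_clustering(A)[0], oracle_clustering(A)[0])
        assert characteristic_path_length(A) == pytest.approx(oracle_path_length(A))
        assert np.allclose(betweenness(A), oracle_betweenness(A), atol=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_medium_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 13))
        A = random_connected_adjacency(n, rng, p=0.25)
        assert np.allclose(nodal_clustering(A)[0], oracle_clustering(A)[0])
        assert characteristic_path_length(A) == pytest.approx(oracle_path_length(A))
        assert np.allclose(betweenness(A), oracle_betweenness(A), atol=1e-9)


class TestDisconnectedHandling:
    def test_error_names_component_sizes(self):
        A = adjacency_from_edges(5, [(0, 1), (2, 3), (3, 4)])
        with pytest.raises(DisconnectedNetworkError, match=r"\[3, 2\]"):
            characteristic_path_length(A)

    def test_connected_pairs_mode(self):
        A = adjacency_from_edges(5, [(0, 1), (2, 3), (3, 4)])
        assert characteristic_path_length(A, on_disconnected="connected_pairs") == (
            pytest.approx(oracle_path_length(A, connected_pairs_only=True))
        )


class TestRandomReference:
    def test_degree_sequence_preserved(self):
        net = generate_latent_network(60, 6, 0.2, seed=2)
        ref = random_reference(net, seed=5)
        assert np.array_equal(
            np.sort(net.adjacency.sum(1)), np.sort(ref.adjacency.sum(1))
        )
        assert np.array_equal(net.adjacency.sum(1), ref.adjacency.sum(1))

    def test_seed_determinism(self):
        net = generate_latent_network(40, 4, 0.1, seed=3)
        r1 = random_reference(net, seed=9)
        r2 = random_reference(net, seed=9)
        assert np.array_equal(r1.adjacency, r2.adjacency)

    def test_randomization_destroys_lattice_clustering(self):
        net = generate_latent_network(90, 8, 0.0, seed=0)
        ref = random_reference(net, seed=1)
        _, C_in = nodal_clustering(net.adjacency)
        _, C_out = nodal_clustering(ref.adjacency)
        assert C_out < C_in

    def test_tiny_graph_returned_with_warning(self):
        net = BinaryNetwork(adjacency_from_edges(3, [(0, 1)]), density=1 / 3)
        with pytest.warns(UserWarning):
            ref = random_reference(net, seed=0)
        assert np.array_equal(ref.adjacency, net.adjacency)


class TestSmallWorld:
    def test_sigma_is_gamma_over_lambda(self):
        net = generate_latent_network(60, 6, 0.2, seed=4)
        gm = small_world(net, n_random=20, seed=7)
        assert gm.sigma == gm.gamma / gm.lambda_
        assert len(gm.ref_c) == 20

    def test_lattice_strongly_clustered_relative_to_random(self):
        net = generate_latent_network(90, 8, 0.0, seed=0)
        gm = small_world(net, n_random=30, seed=2)
        assert gm.gamma > 2.0

    def test_rewiring_trajectory_monotone(self):
        """Along ring -> rewired -> fully random, both C and L decrease
        (seeded means over a few instances per rewiring probability)."""
        C_means, L_means = [], []
        for p in (0.0, 0.1, 0.5, 1.0):
            Cs, Ls = [], []
            for s in range(5):
                net = generate_latent_network(60, 6, p, seed=10 * s + 1)
                Cs.append(nodal_clustering(net.adjacency)[1])
                Ls.append(
                    characteristic_path_length(
                        net.adjacency, on_disconnected="connected_pairs"
                    )
                )
            C_means.append(np.mean(Cs))
            L_means.append(np.mean(Ls))
        assert all(a >= b - 1e-9 for a, b in zip(C_means, C_means[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(L_means, L_means[1:]))


class TestHubs:
    def test_reference_tables_reproduce_published_hub_counts(self, region_table):
        dm = centrality_table_to_array(load_reference_centrality("dm"), region_table)
        nc = centrality_table_to_array(load_reference_centrality("nc"), region_table)
        hubs_dm = identify_hubs(dm, region_table)
        hubs_nc = identify_hubs(nc, region_table)
        assert len(hubs_dm) == 21
        assert len(hubs_nc) == 19
        assert min(b for _, b in hubs_dm) == pytest.approx(1.53)
        shared = shared_hubs(hubs_dm, hubs_nc)
        assert {r.label for r in shared} == {"SPG_R", "PCUN_R", "PHG_L", "PHG_R", "SOG_L"}

    def test_sorted_descending_with_index_tiebreak(self, region_table):
        b = np.zeros(90)
        b[10] = b[40] = 2.0
        b[3] = 3.0
        hubs = identify_hubs(b, region_table)
        assert [r.index - 1 for r in hubs.regions] == [3, 10, 40]

    def test_all_average_centrality_means_no_hubs(self, region_table):
        assert len(identify_hubs(np.ones(90), region_table)) == 0

    def test_membership_invariant_to_rescaling_B(self, region_table):
        rng = np.random.default_rng(0)
        B = rng.exponential(1.0, 90)
        h1 = identify_hubs(normalized_betweenness(B), region_table)
        h2 = identify_hubs(normalized_betweenness(7.3 * B), region_table)
        assert [r.label for r in h1.regions] == [r.label for r in h2.regions]

    def test_shared_hubs_edge_cases(self, region_table):
        full = identify_hubs(np.full(90, 2.0), region_table)
        empty = identify_hubs(np.zeros(90), region_table)
        assert shared_hubs(full, empty) == []
        assert len(shared_hubs(full, full)) == 90


def test_nodal_centrality_bundle(small_cohort):
    from metabnet.network import density_threshold, pearson_matrix
    from metabnet.preprocess import preprocess

    panel_a, _, _ = small_cohort
    net = density_threshold(pearson_matrix(preprocess(panel_a)), 0.15)
    nc = nodal_centrality(net)
    assert nc.b.mean() == pytest.approx(1.0)
    assert np.array_equal(nc.degree, net.adjacency.sum(1).astype(int))
    frame = nc.to_frame()
    assert list(frame.columns) == ["B", "b", "degree", "C_i"]
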