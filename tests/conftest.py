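import networkx as nx
import numpy as np
import pytest

from metabnet.atlas import load_region_table
from metabnet.network import BinaryNetwork
from metabnet.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def region_table():
    return load_region_table()


@pytest.fixture(scope="session")
def small_cohort():
    """30-region, 40+40-subject cohort with default confounds (seeded)."""
    spec = CohortSpec(
        n_group_a=40, n_group_b=40, n_regions=30, latent_degree=4, seed=5
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_hub_networks():
    """Two 90-node latent graphs differing only in who bridges two modules.

    Graph A routes all inter-module shortest paths through node 0 (six
    bridges), making it an extreme betweenness hub; graph B distributes the
    same six bridges over other nodes, detaching the hub while keeping the
    edge count (hence density) identical.
    """

    def ring_edges(nodes, k):
        G = nx.watts_strogatz_graph(len(nodes), k, 0)
        return [(nodes[u], nodes[v]) for u, v in G.edges]

    n = 90
    base = np.zeros((n, n))
    for u, v in ring_edges(list(range(45)), 8) + ring_edges(list(range(45, 90)), 8):
        base[u, v] = base[v, u] = 1
    bridges_a = [(0, 45), (0, 56), (0, 67), (0, 78), (0, 88), (0, 50)]
    bridges_b = [(7, 45), (14, 56), (21, 67), (28, 78), (35, 88), (42, 50)]
    adj_a, adj_b = base.copy(), base.copy()
    for u, v in bridges_a:
        adj_a[u, v] = adj_a[v, u] = 1
    for u, v in bridges_b:
        adj_b[u, v] = adj_b[v, u] = 1
    density = adj_a.sum() / 2 / (n * (n - 1) / 2)
    return (
        BinaryNetwork(adj_a, density),
        BinaryNetwork(adj_b, density),
        0,  # the planted hub node
    )
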