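"""Graph metrics against closed forms and independent oracles.

networkx and scipy's Floyd-Warshall serve as the independent reference
implementations; the closed-form values are derived by hand.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

import nbacknet as nb
from conftest import (
    complete_graph,
    cycle_graph,
    graph_from_edges,
    path_graph,
    star_graph,
    triangle_plus_pendant,
)


def to_nx(net: nb.BinaryNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(map(tuple, net.edge_list()))
    return g


def all_metrics(net):
    return (
        nb.clustering_coefficient(net),
        nb.global_efficiency(net),
        nb.local_efficiency(net),
        nb.betweenness_centrality(net),
    )


class TestClosedForms:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_complete_graph(self, n):
        net = complete_graph(n)
        assert nb.clustering_coefficient(net) == pytest.approx(1.0)
        assert nb.characteristic_path_length(net) == pytest.approx(1.0)
        assert nb.global_efficiency(net) == pytest.approx(1.0)
        assert nb.local_efficiency(net) == pytest.approx(1.0)
        np.testing.assert_allclose(nb.betweenness_centrality(net), 0.0)

    def test_three_node_path(self):
        net = path_graph(3)
        assert nb.clustering_coefficient(net) == pytest.approx(0.0)
        assert nb.characteristic_path_length(net) == pytest.approx(4 / 3)
        assert nb.global_efficiency(net) == pytest.approx(5 / 6)

    def test_four_node_path_betweenness(self):
        net = path_graph(4)
        np.testing.assert_allclose(nb.betweenness_centrality(net),
                                   [0.0, 2.0, 2.0, 0.0])

    def test_star_graph(self):
        net = star_graph(4)
        assert nb.local_efficiency(net) == pytest.approx(0.0)
        b = nb.betweenness_centrality(net)
        assert b[0] == pytest.approx(6.0)  # C(4, 2) leaf pairs via center
        np.testing.assert_allclose(b[1:], 0.0)

    def test_triangle_plus_pendant(self):
        net = triangle_plus_pendant()
        assert nb.clustering_coefficient(net) == pytest.approx(7 / 12)
        assert nb.characteristic_path_length(net) == pytest.approx(4 / 3)
        assert nb.local_efficiency(net) == pytest.approx(7 / 12)

    def test_four_cycle_shortest_path_multiplicity(self):
        dm = nb.shortest_paths(cycle_graph(4))
        assert dm.lengths[0, 2] == 2
        assert dm.n_shortest_paths[0, 2] == 2

    def test_disconnected_pairs_contribute_zero_efficiency(self):
        net = graph_from_edges(4, [(0, 1), (2, 3)])
        assert nb.global_efficiency(net) == pytest.approx(1 / 3)

    def test_path_length_raises_on_disconnection(self):
        net = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            nb.characteristic_path_length(net)


def assert_matches_oracles(net: nb.BinaryNetwork):
    g = to_nx(net)
    n = net.n_nodes
    # distances: Floyd-Warshall (scipy) is the independent algorithm
    fw = floyd_warshall(net.adjacency.astype(float), unweighted=True)
    dm = nb.shortest_paths(net)
    np.testing.assert_allclose(dm.lengths, fw, atol=1e-10)
    # exhaustive triangle count per node
    adj = net.adjacency
    tri = np.zeros(n)
    for i, j, k in itertools.combinations(range(n), 3):
        if adj[i, j] and adj[j, k] and adj[i, k]:
            tri[[i, j, k]] += 1
    table = nb.nodal_metrics(net)
    np.testing.assert_allclose(table["triangles"], tri, atol=1e-10)
    assert nb.clustering_coefficient(net) == pytest.approx(
        nx.average_clustering(g), abs=1e-10
    )
    assert nb.global_efficiency(net) == pytest.approx(
        nx.global_efficiency(g), abs=1e-10
    )
    assert nb.local_efficiency(net) == pytest.approx(
        nx.local_efficiency(g), abs=1e-10
    )
    np.testing.assert_allclose(
        nb.betweenness_centrality(net),
        np.array([v for _, v in sorted(
            nx.betweenness_centrality(g, normalized=False).items()
        )]),
        atol=1e-10,
    )
    if nx.is_connected(g):
        assert nb.characteristic_path_length(net) == pytest.approx(
            nx.average_shortest_path_length(g), abs=1e-10
        )


class TestOracleEquivalence:
    def test_all_graphs_up_to_five_nodes(self):
        pairs = list(itertools.combinations(range(5), 2))
        for mask in range(2 ** len(pairs)):
            edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
            assert_matches_oracles(graph_from_edges(5, edges))

    def test_random_connected_graphs(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 9))
            p = rng.uniform(0.3, 0.9)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            assert_matches_oracles(
                graph_from_edges(n, [tuple(e) for e in g.edges()])
            )
            checked += 1


class TestEnsembleProperties:
    def test_monotonicity_over_nested_sweep(self, synthetic_connectivity):
        ensemble = nb.sweep_sparsity(synthetic_connectivity,
                                     nb.SparsityGrid())
        L_prev, E_prev = np.inf, 0.0
        for net in ensemble.networks:
            gm = nb.global_metrics(net)
            assert gm.L <= L_prev + 1e-12
            assert gm.E_global >= E_prev - 1e-12
            L_prev, E_prev = gm.L, gm.E_global

    def test_bounds_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            p = rng.uniform(0.1, 0.8)
            adj = (rng.random((n, n)) < p).astype(np.uint8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            net = nb.BinaryNetwork(adj)
            gm = nb.global_metrics(net)
            assert 0 <= gm.C <= 1
            assert 0 <= gm.E_global <= 1
            assert 0 <= gm.E_local <= 1
            b = nb.betweenness_centrality(net)
            assert np.all(b >= 0)
            assert np.all(b <= (n - 1) * (n - 2) / 2 + 1e-9)

    def test_nodal_metrics_are_permutation_equivariant(self):
        rng = np.random.default_rng(9)
        adj = (rng.random((12, 12)) < 0.4).astype(np.uint8)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        net = nb.BinaryNetwork(adj)
        perm = rng.permutation(12)
        net_p = nb.BinaryNetwork(adj[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            nb.betweenness_centrality(net_p),
            nb.betweenness_centrality(net)[perm],
            atol=1e-10,
        )
        t = nb.nodal_metrics(net)
        t_p = nb.nodal_metrics(net_p)
        np.testing.assert_array_equal(t_p["degree"],
                                      t["degree"].to_numpy()[perm])
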