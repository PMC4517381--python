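import warnings

import networkx as nx
import numpy as np
import pytest

from mbnet import (
    Graph,
    all_pairs_paths,
    assortativity,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    degree,
    metrics_report,
    network_global_efficiency,
    network_local_efficiency,
    nodal_global_efficiency,
    nodal_local_efficiency,
)
from _oracles import brute_force_betweenness, brute_force_paths, random_adjacency


def graph(n, edges):
    return Graph.from_edges([str(i) for i in range(n)], edges)


P3 = graph(3, [(0, 1), (1, 2)])
P4 = graph(4, [(0, 1), (1, 2), (2, 3)])
C4 = graph(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
K4 = graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
STAR3 = graph(4, [(0, 1), (0, 2), (0, 3)])
TRIANGLE = graph(3, [(0, 1), (1, 2), (0, 2)])
EMPTY2 = graph(2, [])


class TestPathStats:
    def test_path_graph(self):
        ps = all_pairs_paths(P3)
        assert ps.lengths[0, 2] == 2
        assert ps.sigma[0, 2] == 1
        assert ps.sigma_through[1, 0, 2] == 1

    def test_cycle_has_two_shortest_paths_between_opposite_corners(self):
        ps = all_pairs_paths(C4)
        assert ps.lengths[0, 2] == 2
        assert ps.sigma[0, 2] == 2

    def test_disconnected_pair(self):
        ps = all_pairs_paths(EMPTY2)
        assert ps.lengths[0, 1] == np.inf
        assert ps.sigma[0, 1] == 0

    def test_invariants_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = Graph(labels=[str(i) for i in range(7)],
                      adj=random_adjacency(rng, 7, 0.4))
            ps = all_pairs_paths(g)
            assert np.array_equal(ps.lengths, ps.lengths.T)
            assert np.array_equal(ps.sigma, ps.sigma.T)
            assert np.all(np.diag(ps.lengths) == 0)
            # interior-path counts never exceed total shortest-path counts
            for i in range(7):
                assert np.all(ps.sigma_through[i] <= ps.sigma)


class TestEfficiencies:
    @pytest.mark.parametrize(
        "g,node,expected",
        [
            (K4, 0, 1.0),
            (P3, 0, 0.75),        # (1 + 1/2) / 2
            (STAR3, 1, (1 + 1 / 2 + 1 / 2) / 3),  # leaf: hub at 1, leaves at 2
            (graph(3, [(0, 1)]), 2, 0.0),  # isolated node
        ],
    )
    def test_nodal_global_efficiency_closed_forms(self, g, node, expected):
        assert nodal_global_efficiency(g, node) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "g,node,expected",
        [
            (TRIANGLE, 0, 1.0),
            (P3, 0, 0.0),          # degree-1 node
            (STAR3, 0, 0.0),       # hub of edgeless neighborhood
            (K4, 0, 1.0),
        ],
    )
    def test_nodal_local_efficiency(self, g, node, expected):
        assert nodal_local_efficiency(g, node) == pytest.approx(expected)

    def test_one_linked_neighbor_pair_of_three(self):
        # node 0 with neighbors 1,2,3 of which only (1,2) adjacent:
        # subgraph efficiency = 2 / 6
        g = graph(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
        assert nodal_local_efficiency(g, 0) == pytest.approx(1 / 3)

    def test_network_efficiency_extremes(self):
        assert network_global_efficiency(K4) == 1.0
        assert network_global_efficiency(graph(3, [])) == 0.0
        assert network_local_efficiency(K4) == 1.0
        assert network_local_efficiency(STAR3) == 0.0

    def test_network_equals_mean_of_nodal(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            g = Graph(labels=[str(i) for i in range(n)],
                      adj=random_adjacency(rng, n, float(rng.random())))
            ps = all_pairs_paths(g)
            mean_nodal = np.mean(
                [nodal_global_efficiency(g, i, ps) for i in range(n)]
            )
            assert network_global_efficiency(g, ps) == pytest.approx(
                mean_nodal, abs=1e-12
            )

    def test_bounds_and_edge_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            adj = random_adjacency(rng, n, 0.3)
            g = Graph(labels=[str(i) for i in range(n)], adj=adj)
            e = network_global_efficiency(g)
            assert 0.0 <= e <= 1.0
            assert 0.0 <= network_local_efficiency(g) <= 1.0
            # add one absent edge: global efficiency never decreases
            absent = np.argwhere(np.triu(adj == 0, 1))
            if len(absent):
                i, j = absent[rng.integers(len(absent))]
                adj2 = adj.copy()
                adj2[i, j] = adj2[j, i] = 1
                g2 = Graph(labels=g.labels, adj=adj2)
                assert network_global_efficiency(g2) >= e - 1e-12


class TestBetweenness:
    @pytest.mark.parametrize(
        "g,node,expected",
        [
            (STAR3, 0, 3.0),   # 3 unordered leaf pairs
            (P4, 1, 2.0),
            (P3, 0, 0.0),      # degree-1 node
            (K4, 2, 0.0),
        ],
    )
    def test_closed_forms(self, g, node, expected):
        assert betweenness(g, node) == pytest.approx(expected)

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            adj = random_adjacency(rng, n, 0.5)
            g = Graph(labels=[str(i) for i in range(n)], adj=adj)
            ours = np.array([betweenness(g, i) for i in range(n)])
            assert np.allclose(ours, brute_force_betweenness(adj), atol=1e-9)
            gx = nx.from_numpy_array(adj)
            ref = nx.betweenness_centrality(gx, normalized=False)
            assert np.allclose(ours, [ref[i] for i in range(n)], atol=1e-9)

    def test_sum_identity_on_random_graphs(self):
        # sum_i B_i == sum over connected unordered pairs of (l_jk - 1)
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            g = Graph(labels=[str(i) for i in range(n)],
                      adj=random_adjacency(rng, n, 0.35))
            ps = all_pairs_paths(g)
            total_b = sum(betweenness(g, i, ps) for i in range(n))
            iu = np.triu_indices(n, 1)
            lens = ps.lengths[iu]
            expected = np.sum(lens[np.isfinite(lens)] - 1)
            assert total_b == pytest.approx(expected, abs=1e-9)


class TestClassicalMetrics:
    def test_complete_and_path_graph_values(self):
        assert all(clustering_coefficient(K4, i) == 1.0 for i in range(4))
        cpl, connected = characteristic_path_length(K4)
        assert (cpl, connected) == (1.0, True)
        assert clustering_coefficient(P3, 1) == 0.0
        assert characteristic_path_length(P3)[0] == pytest.approx(4 / 3)
        assert degree(STAR3, 0) == 3

    def test_against_networkx(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            adj = random_adjacency(rng, n, 0.5)
            g = Graph(labels=[str(i) for i in range(n)], adj=adj)
            gx = nx.from_numpy_array(adj)
            ref_clust = nx.clustering(gx)
            for i in range(n):
                assert clustering_coefficient(g, i) == pytest.approx(ref_clust[i])
            degs = adj.sum(axis=1)
            if adj.sum() and np.ptp(degs[np.where(adj.any(axis=1))]) > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ours = assortativity(g)
                    theirs = nx.degree_assortativity_coefficient(gx)
                if np.isfinite(theirs):
                    assert ours == pytest.approx(theirs, abs=1e-9)

    def test_disconnected_path_length_flagged(self):
        g = graph(4, [(0, 1), (2, 3)])
        with pytest.warns(UserWarning, match="disconnected"):
            cpl, connected = characteristic_path_length(g)
        assert not connected
        assert cpl == 1.0  # both connected pairs at distance 1

    def test_degenerate_assortativity_flagged_nan(self):
        with pytest.warns(UserWarning, match="assortativity undefined"):
            assert np.isnan(assortativity(C4))  # all degrees equal


class TestMetricsReport:
    def test_complete_graph_report(self):
        rep = metrics_report(K4)
        assert np.all(rep.nodal["global_efficiency"] == 1.0)
        assert np.all(rep.nodal["betweenness"] == 0.0)
        assert rep.network["characteristic_path_length"] == 1.0

    def test_empty_graph_report_all_zero(self):
        rep = metrics_report(graph(3, []))
        assert np.all(rep.nodal["global_efficiency"] == 0.0)
        assert np.all(rep.nodal["local_efficiency"] == 0.0)
        assert rep.network["global_efficiency"] == 0.0
        assert rep.flags  # disconnectedness / undefined assortativity noted
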