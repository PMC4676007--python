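"""Graph construction, admissibility, and metrics vs brute-force oracles."""

import numpy as np
import pytest

from tcsync import netgraph
from tcsync.netgraph import (
    FunctionalGraph,
    GraphEnsemble,
    GraphError,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    ensemble_stats,
    filter_outlier_graphs,
    graph_stats,
    is_admissible_connectivity,
    threshold_graph,
)

# ---------------------------------------------------------------------------
# independent oracles (pure-python brute force)
# ---------------------------------------------------------------------------


def oracle_clustering(n, edges):
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    per = []
    for i in range(n):
        k = len(adj[i])
        if k < 2:
            per.append(0.0)
            continue
        tri = sum(
            1
            for a in adj[i]
            for b in adj[i]
            if a < b and b in adj[a]
        )
        per.append(2.0 * tri / (k * (k - 1)))
    return per, float(np.mean(per))


def oracle_path_length(n, edges):
    INF = float("inf")
    d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for i, j in edges:
        d[i][j] = d[j][i] = 1.0
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    n_disc = n * (n - 1) - len(finite)
    return (float(np.mean(finite)) if finite else float("nan")), n_disc


def oracle_betweenness(n, edges):
    """Exhaustive geodesic enumeration via BFS path counting."""
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            # enumerate all shortest s-t paths by BFS layers
            from collections import deque

            dist = {s: 0}
            q = deque([s])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            if t not in dist:
                continue
            paths = []

            def extend(path):
                u = path[-1]
                if u == t:
                    paths.append(path)
                    return
                for v in adj[u]:
                    if dist.get(v, -1) == dist[u] + 1 and dist[v] <= dist[t]:
                        extend(path + [v])

            extend([s])
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def random_graph(rng, n, p):
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return FunctionalGraph(n_nodes=n, edges=edges)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


class TestThresholdGraph:
    def _mat(self, weights, n):
        m = np.eye(n)
        iu = np.triu_indices(n, k=1)
        m[iu] = weights
        m[(iu[1], iu[0])] = weights
        return m

    def test_interpolated_percentile_example(self):
        g = threshold_graph(self._mat([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], 4))
        assert g.threshold_used == pytest.approx(0.525)
        assert g.n_edges == 1 and not g.degenerate

    def test_all_tied_degenerate_empty(self):
        g = threshold_graph(self._mat([0.5] * 6, 4))
        assert g.n_edges == 0 and g.degenerate

    def test_percentile_zero_complete(self):
        g = threshold_graph(self._mat([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], 4), percentile=0)
        assert g.density == 1.0

    def test_density_near_quarter_at_default(self, rng):
        w = rng.uniform(0, 1, 153)  # 18 nodes, all-distinct weights
        g = threshold_graph(self._mat(w, 18))
        assert g.density <= 0.25 + 1.0 / 153

    def test_raising_percentile_never_adds_edges(self, rng):
        w = rng.uniform(0, 1, 45)
        m = self._mat(w, 10)
        prev = None
        for pct in (0, 25, 50, 75, 90):
            edges = set(threshold_graph(m, pct).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_single_node_rejected(self):
        with pytest.raises(GraphError):
            threshold_graph(np.ones((1, 1)))


class TestAdmissibility:
    def test_isolated_node_inadmissible(self):
        # 9 nodes, one isolated: 8/9 = 88.9% < 99%
        g = FunctionalGraph(9, [(i, i + 1) for i in range(7)])
        assert not is_admissible_connectivity(g)

    def test_connected_graph_admissible(self):
        g = FunctionalGraph(18, [(i, i + 1) for i in range(17)])
        assert is_admissible_connectivity(g)

    def test_edgeless_inadmissible(self):
        assert not is_admissible_connectivity(FunctionalGraph(5, []))


class TestOutlierFilter:
    def test_identical_graphs_none_removed(self):
        graphs = [FunctionalGraph(5, [(0, 1), (1, 2)]) for _ in range(100)]
        out = filter_outlier_graphs(graphs)
        assert len(out) == 100

    def test_extreme_edge_count_removed(self):
        small = [FunctionalGraph(21, [(i, i + 1) for i in range(20)]) for _ in range(99)]
        big = FunctionalGraph(
            21, [(i, j) for i in range(21) for j in range(i + 1, 21)]
        )
        out = filter_outlier_graphs(small + [big])
        assert len(out) == 99
        assert all(g.n_edges == 20 for g in out.graphs)

    def test_small_ensemble_noop(self, caplog):
        graphs = [FunctionalGraph(4, [(0, 1)]) for _ in range(10)]
        with caplog.at_level("WARNING"):
            out = filter_outlier_graphs(graphs)
        assert len(out) == 10
        assert any("too small" in r.message for r in caplog.records)

    def test_removal_bounded_on_continuous_ensembles(self, rng):
        graphs = [random_graph(rng, 15, rng.uniform(0.2, 0.6)) for _ in range(200)]
        out = filter_outlier_graphs(graphs)
        assert len(out) >= 0.4 * len(graphs)  # far below the 60% worst case


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestClustering:
    def test_complete_graph(self):
        g = FunctionalGraph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        _, C = clustering_coefficient(g)
        assert C == 1.0

    def test_path_graph_zero(self):
        _, C = clustering_coefficient(FunctionalGraph(4, [(0, 1), (1, 2), (2, 3)]))
        assert C == 0.0

    def test_square_with_chord(self):
        g = FunctionalGraph(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        per, C = clustering_coefficient(g)
        assert np.allclose(per, [2 / 3, 1.0, 2 / 3, 1.0])
        assert C == pytest.approx(5 / 6)


class TestPathLength:
    def test_complete_graph_one(self):
        g = FunctionalGraph(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        L, nd = characteristic_path_length(g)
        assert L == 1.0 and nd == 0

    def test_path_graph(self):
        L, _ = characteristic_path_length(FunctionalGraph(4, [(0, 1), (1, 2), (2, 3)]))
        assert L == pytest.approx(5 / 3)

    def test_five_cycle(self):
        g = FunctionalGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
        L, _ = characteristic_path_length(g)
        assert L == pytest.approx(1.5)

    def test_disconnected_pairs_excluded_and_counted(self):
        g = FunctionalGraph(4, [(0, 1), (2, 3)])
        L, nd = characteristic_path_length(g)
        assert L == 1.0 and nd == 8

    def test_edgeless_undefined(self):
        L, _ = characteristic_path_length(FunctionalGraph(3, []))
        assert np.isnan(L)


class TestBetweenness:
    def test_star_center(self):
        g = FunctionalGraph(5, [(0, i) for i in range(1, 5)])
        bc = betweenness_centrality(g)
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)

    def test_complete_graph_zero(self):
        g = FunctionalGraph(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert np.allclose(betweenness_centrality(g), 0.0)

    def test_path_graph(self):
        bc = betweenness_centrality(FunctionalGraph(4, [(0, 1), (1, 2), (2, 3)]))
        assert np.allclose(bc, [0.0, 2 / 3, 2 / 3, 0.0])


class TestOracleEquivalence:
    def test_clustering_and_path_length_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 21))
            g = random_graph(rng, n, rng.uniform(0.1, 0.8))
            per, C = clustering_coefficient(g)
            oper, oC = oracle_clustering(n, g.edges)
            assert np.allclose(per, oper) and C == pytest.approx(oC, abs=1e-12)
            L, nd = characteristic_path_length(g)
            oL, ond = oracle_path_length(n, g.edges)
            assert nd == ond
            assert (np.isnan(L) and np.isnan(oL)) or L == pytest.approx(oL, abs=1e-12)

    def test_betweenness_matches_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            g = random_graph(rng, n, rng.uniform(0.2, 0.9))
            assert np.allclose(
                betweenness_centrality(g), oracle_betweenness(n, g.edges), atol=1e-12
            )


class TestEnsembleStats:
    def test_identical_complete_graphs(self):
        k4 = [
            FunctionalGraph(
                4, [(i, j) for i in range(4) for j in range(i + 1, 4)], window=(0.0, 0.5)
            )
            for _ in range(5)
        ]
        df = ensemble_stats(k4)
        assert np.allclose(df["C"], 1.0) and df["C"].std() == 0.0
        assert np.allclose(df["L"], 1.0)

    def test_mean_is_arithmetic_mean(self):
        gs = [
            FunctionalGraph(4, [(0, 1), (1, 2), (2, 3)]),
            FunctionalGraph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
        ]
        df = ensemble_stats(gs)
        assert df["C"].mean() == pytest.approx((0.0 + 1.0) / 2)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(GraphError):
            ensemble_stats(GraphEnsemble(graphs=[]))

    def test_stats_flags(self):
        g = FunctionalGraph(4, [(0, 1), (1, 2), (2, 3)])
        st = graph_stats(g)
        assert st.admissible and st.n_edges == 3 and st.density == pytest.approx(0.5)


class TestExports:
    def test_edge_list_uses_labels(self):
        g = FunctionalGraph(3, [(0, 1), (1, 2)], node_labels=["ch0", "ch1", "ch2"])
        assert netgraph.export_edge_list(g) == "ch0\tch1\nch1\tch2"

    def test_graphml_round_trips_through_networkx(self, tmp_path):
        import networkx as nx

        g = FunctionalGraph(4, [(0, 1), (2, 3)], node_labels=["a", "b", "c", "d"])
        p = tmp_path / "g.graphml"
        netgraph.export_graphml(g, p)
        back = nx.read_graphml(p)
        assert back.number_of_nodes() == 4 and back.number_of_edges() == 2
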