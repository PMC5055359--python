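import numpy as np
import pytest

import oracles
from conftest import graph_from, random_connected_graph
from pknet.metrics import (
    WeightedGraph,
    assortativity,
    betweenness,
    characteristic_path_length,
    complexity_report,
    global_efficiency,
    local_efficiency,
    shortest_path_matrix,
)


def wgraph(n, edges, lengths=None):
    return WeightedGraph(n, np.asarray(edges).reshape(-1, 2),
                         None if lengths is None else np.asarray(lengths, float))


def random_sparse_graph(rng, n_max=10):
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.2, 0.7))
    edges = [(a, b) for a in range(n) for b in range(a + 1, n) if rng.random() < p]
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    return n, np.array(edges).reshape(-1, 2), lengths


class TestShortestPaths:
    def test_chain_distance(self):
        g = wgraph(3, [[0, 1], [1, 2]], [1.0, 1.0])
        d = shortest_path_matrix(g)
        assert d[0, 2] == pytest.approx(2.0)
        assert np.all(np.diag(d) == 0.0)

    def test_disconnected_is_infinite(self):
        d = shortest_path_matrix(wgraph(2, np.empty((0, 2))))
        assert np.isinf(d[0, 1])

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n, edges, lengths = random_sparse_graph(rng, n_max=12)
            if len(edges) == 0:
                continue
            mine = shortest_path_matrix(wgraph(n, edges, lengths))
            brute = oracles.brute_distance_matrix(n, edges, lengths)
            assert np.allclose(mine, brute, atol=1e-9, equal_nan=True)


class TestEfficiencies:
    def test_complete_graph_unit_efficiency(self):
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        assert global_efficiency(wgraph(4, edges), "binary") == pytest.approx(1.0)

    def test_path_of_three(self):
        g = wgraph(3, [[0, 1], [1, 2]], [1.0, 1.0])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_edgeless_zero(self):
        assert global_efficiency(wgraph(5, np.empty((0, 2))), "binary") == 0.0

    def test_triangle_local_efficiency_one(self):
        g = wgraph(3, [[0, 1], [1, 2], [0, 2]])
        per, mean = local_efficiency(g, "binary")
        assert np.allclose(per, 1.0)
        assert mean == pytest.approx(1.0)

    def test_star_local_efficiency_zero(self):
        g = wgraph(4, [[0, 1], [0, 2], [0, 3]])
        per, mean = local_efficiency(g, "binary")
        assert mean == 0.0

    def test_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n, edges, lengths = random_sparse_graph(rng)
            if len(edges) == 0:
                continue
            _, mine_w = local_efficiency(wgraph(n, edges, lengths), "weighted")
            assert mine_w == pytest.approx(
                oracles.brute_local_efficiency(n, edges, lengths), abs=1e-9
            )
            _, mine_b = local_efficiency(wgraph(n, edges), "binary")
            assert mine_b == pytest.approx(
                oracles.brute_local_efficiency(n, edges, np.ones(len(edges))), abs=1e-9
            )

    def test_binary_efficiencies_bounded(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            n, edges, _ = random_sparse_graph(rng)
            g = wgraph(n, edges)
            assert 0.0 <= global_efficiency(g, "binary") <= 1.0
            assert 0.0 <= local_efficiency(g, "binary")[1] <= 1.0

    def test_weighted_ge_scales_inversely(self):
        rng = np.random.default_rng(31)
        n, edges, lengths = random_sparse_graph(rng)
        if len(edges) == 0:
            edges, lengths = np.array([[0, 1]]), np.array([1.0])
        base = global_efficiency(wgraph(n, edges, lengths))
        scaled = global_efficiency(wgraph(n, edges, lengths * 2.5))
        assert scaled == pytest.approx(base / 2.5, rel=1e-12)

    def test_ge_monotone_under_edge_addition(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            edges, lengths = random_connected_graph(rng, n)
            g = wgraph(n, edges, lengths)
            before = global_efficiency(g, "binary")
            missing = [(a, b) for a in range(n) for b in range(a + 1, n)
                       if not any((a, b) == tuple(e) for e in edges.tolist())]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            g2 = wgraph(n, np.vstack([edges, extra]), np.append(lengths, 1.0))
            assert global_efficiency(g2, "binary") >= before - 1e-12


class TestBetweenness:
    def test_path_middle_node(self):
        bc = betweenness(wgraph(3, [[0, 1], [1, 2]]), "binary")
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_star_hub_is_one(self):
        bc = betweenness(wgraph(5, [[0, 1], [0, 2], [0, 3], [0, 4]]), "binary")
        assert bc[0] == pytest.approx(1.0)
        assert np.all(bc[1:] == 0.0)

    def test_terminals_always_zero(self):
        rng = np.random.default_rng(41)
        for seed in range(10):
            n = int(rng.integers(5, 12))
            edges, lengths = random_connected_graph(rng, n, extra_edges=2)
            g = wgraph(n, edges, lengths)
            bc = betweenness(g)
            for node in np.flatnonzero(g.degrees() == 1):
                assert bc[node] == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            n, edges, lengths = random_sparse_graph(rng)
            if len(edges) == 0:
                continue
            mine = betweenness(wgraph(n, edges, lengths), "weighted")
            brute = oracles.brute_betweenness(n, edges, lengths)
            assert np.allclose(mine, brute, atol=1e-9)


class TestAssortativity:
    def test_y_with_tail_matches_hand_computation(self):
        """Furcation hub linked to two terminals and a pass-through chain."""
        g = wgraph(5, [[0, 1], [0, 2], [0, 3], [3, 4]])
        assert round(assortativity(g), 3) == -0.667

    def test_ring_undefined(self):
        edges = [[i, (i + 1) % 5] for i in range(5)]
        assert np.isnan(assortativity(wgraph(5, edges)))

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            assortativity(wgraph(3, np.empty((0, 2))))

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(47)
        checked = 0
        for _ in range(100):
            n, edges, _ = random_sparse_graph(rng, n_max=12)
            if len(edges) < 2:
                continue
            mine = assortativity(wgraph(n, edges))
            ref = oracles.pearson_assortativity(n, edges)
            if np.isnan(ref):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)
                checked += 1
        assert checked > 50


class TestCharacteristicPathLength:
    def test_triangle(self):
        g = wgraph(3, [[0, 1], [1, 2], [0, 2]])
        assert characteristic_path_length(g, "binary")[0] == pytest.approx(1.0)

    def test_path_binary_and_weighted(self):
        g = wgraph(3, [[0, 1], [1, 2]], [2.0, 3.0])
        assert characteristic_path_length(g, "binary")[0] == pytest.approx(4 / 3)
        assert characteristic_path_length(g, "weighted")[0] == pytest.approx(10 / 3)

    def test_unreachable_pairs_counted(self):
        g = wgraph(4, [[0, 1]])
        value, n_inf = characteristic_path_length(g, "binary")
        assert value == pytest.approx(1.0)
        assert n_inf == 10  # 12 ordered pairs, 2 reachable

    def test_fully_disconnected_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path_length(wgraph(3, np.empty((0, 2))), "binary")


class TestReport:
    def test_report_panel_consistency(self, y_graph):
        report = complexity_report(y_graph, "weighted")
        d = report.to_dict()
        assert d["n_nodes"] == 4
        assert d["Assort"] is not None
        assert report.betweenness[0] == pytest.approx(1.0)
        assert 0.0 < d["G.E"]
        assert d["C.P.Length"] > 0
        assert sum(d["Betweenness.hist"]["counts"]) == 4
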