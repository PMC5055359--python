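import numpy as np
import pytest

from conftest import graph_from, random_rotation
from pknet.io_formats import LandmarkSet
from pknet.network import (
    CenterlineGraph,
    GraphBuildError,
    branch_stats,
    build_graph,
    extract_branches,
    furcation_angles,
)
from pknet.synthetic import SyntheticNetworkConfig, simulate_network


class TestBuildGraph:
    def test_euclidean_edge_length(self):
        lm = LandmarkSet(["A", "B"], np.array([[0, 0, 0], [3, 4, 0]], float))
        g = build_graph(lm, [("A", "B")])
        assert g.lengths[0] == pytest.approx(5.0)

    def test_roles_from_degree(self, y_graph):
        assert y_graph.node_role(0) == "furcation"
        assert all(y_graph.node_role(i) == "terminal" for i in (1, 2, 3))

    def test_pass_through_role(self):
        g = graph_from([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1], [1, 2]])
        assert g.node_role(1) == "pass_through"

    @pytest.mark.parametrize(
        "edges,message",
        [
            ([("A", "A")], "self-loop A–A"),
            ([("A", "B"), ("B", "A")], "duplicate edge"),
            ([("A", "C")], "unknown landmark 'C'"),
        ],
    )
    def test_bad_edges_rejected(self, edges, message):
        lm = LandmarkSet(["A", "B"], np.array([[0, 0, 0], [1, 1, 1]], float))
        with pytest.raises(GraphBuildError, match=message):
            build_graph(lm, edges)

    def test_zero_length_edge_rejected(self):
        lm = LandmarkSet(["A", "B"], np.array([[0, 0, 0], [0, 0, 0]], float))
        with pytest.raises(GraphBuildError, match="zero-length"):
            build_graph(lm, [("A", "B")])


class TestBranches:
    def test_chain_merges_into_one_branch(self):
        g = graph_from([[0, 0, 0], [50, 0, 0], [120, 0, 0]], [[0, 1], [1, 2]])
        branches = extract_branches(g)
        assert len(branches) == 1
        assert branches.branches[0].length == pytest.approx(120.0)

    def test_y_of_equal_arms(self, y_graph):
        branches = extract_branches(y_graph)
        assert len(branches) == 3
        assert branches.lengths == pytest.approx([50.0, 50.0, 50.0])

    def test_total_length_conserved_on_random_trees(self):
        for seed in range(100):
            g = simulate_network(SyntheticNetworkConfig(seed=seed, n_target_branches=30))
            branches = extract_branches(g)
            assert branches.lengths.sum() == pytest.approx(g.lengths.sum(), rel=1e-12)

    def test_pure_cycle_reported_closed(self):
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        positions = np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)
        edges = [[i, (i + 1) % 6] for i in range(6)]
        branches = extract_branches(graph_from(positions, edges))
        assert len(branches) == 1
        assert branches.branches[0].closed
        assert branches.branches[0].length == pytest.approx(6 * np.linalg.norm(positions[1] - positions[0]))

    def test_extraction_idempotent_under_contraction(self):
        g = simulate_network(SyntheticNetworkConfig(seed=12, n_target_branches=60))
        branches = extract_branches(g)
        # rebuild a graph whose edges are the extracted branches (lengths kept)
        endpoints = sorted({b.nodes[0] for b in branches.branches}
                          | {b.nodes[-1] for b in branches.branches})
        remap = {v: i for i, v in enumerate(endpoints)}
        contracted = CenterlineGraph(
            positions=g.positions[endpoints],
            edges=np.array([[remap[b.nodes[0]], remap[b.nodes[-1]]]
                            for b in branches.branches]),
            lengths=np.array([b.length for b in branches.branches]),
        )
        again = extract_branches(contracted)
        assert np.allclose(np.sort(again.lengths), np.sort(branches.lengths))

    def test_stats_arithmetic(self):
        g = graph_from([[0, 0, 0], [50, 0, 0]], [[0, 1]])
        single = branch_stats(extract_branches(g))
        assert single["mean"] == single["median"] == pytest.approx(50.0)
        two = graph_from([[0, 0, 0], [50, 0, 0], [50, 100, 0]], [[0, 1], [1, 2]])
        # degree-2 middle node: one 150 um branch
        assert branch_stats(extract_branches(two))["mean"] == pytest.approx(150.0)

    def test_stats_histogram_binning(self):
        lengths = type("B", (), {})()
        from pknet.network import Branch, BranchSet

        bs = BranchSet([Branch([0, 1], 50.0), Branch([1, 2], 100.0)])
        stats = branch_stats(bs)
        assert stats["mean"] == pytest.approx(75.0)
        assert stats["median"] == pytest.approx(75.0)
        assert sum(stats["hist_counts"]) == 2
        assert stats["hist_edges"][1] - stats["hist_edges"][0] == pytest.approx(25.0)

    def test_empty_graph_has_no_branches(self):
        g = graph_from(np.zeros((3, 3)) + np.arange(3)[:, None], np.empty((0, 2)))
        assert len(extract_branches(g)) == 0
        with pytest.raises(ValueError):
            branch_stats(extract_branches(g))


class TestFurcationAngles:
    def test_symmetric_y_all_obtuse(self):
        positions = [[0, 0, 0]] + [
            [np.cos(np.radians(a)), np.sin(np.radians(a)), 0] for a in (0, 120, 240)
        ]
        angles = furcation_angles(graph_from(positions, [[0, 1], [0, 2], [0, 3]]))
        assert len(angles) == 3
        assert all(a.angle_deg == pytest.approx(120.0) for a in angles)
        assert all(a.population == "beta" for a in angles)

    def test_planar_y_alpha_and_betas(self):
        positions = [
            [0, 0, 0],
            [-1, 0, 0],
            [np.cos(np.radians(30)), np.sin(np.radians(30)), 0],
            [np.cos(np.radians(-30)), np.sin(np.radians(-30)), 0],
        ]
        angles = furcation_angles(graph_from(positions, [[0, 1], [0, 2], [0, 3]]))
        by_pop = sorted((a.population, round(a.angle_deg, 6)) for a in angles)
        assert by_pop == [("alpha", 60.0), ("beta", 150.0), ("beta", 150.0)]

    def test_exactly_ninety_degrees_is_beta(self):
        positions = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, -1, 0]]
        angles = furcation_angles(graph_from(positions, [[0, 1], [0, 2], [0, 3]]))
        ninety = [a for a in angles if abs(a.angle_deg - 90.0) < 1e-9]
        assert ninety and all(a.population == "beta" for a in ninety)

    def test_degree_four_yields_six_angles(self):
        positions = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, 0, 1]]
        angles = furcation_angles(
            graph_from(positions, [[0, 1], [0, 2], [0, 3], [0, 4]])
        )
        assert len(angles) == 6
        assert all(0.0 <= a.angle_deg <= 180.0 for a in angles)

    def test_rigid_motion_invariance(self, y_graph):
        ref = sorted(a.angle_deg for a in furcation_angles(y_graph))
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        moved = CenterlineGraph(y_graph.positions @ rot.T + [5.0, -3.0, 8.0],
                                y_graph.edges)
        got = sorted(a.angle_deg for a in furcation_angles(moved))
        assert np.abs(np.array(got) - np.array(ref)).max() <= 1e-9

    def test_planar_angles_sum_to_360(self):
        """At a planar degree-3 node the three angles close to a full turn."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            # draw azimuthal gaps that are each below 180 degrees, otherwise
            # the inter-branch angles are not the gaps themselves
            g1, g2 = rng.uniform(np.pi / 2, 17 * np.pi / 18, size=2)
            azimuths = np.cumsum([rng.uniform(0, 2 * np.pi), g1, g2])
            positions = [[0, 0, 0]] + [
                [np.cos(a), np.sin(a), 0] for a in azimuths
            ]
            angles = furcation_angles(graph_from(positions, [[0, 1], [0, 2], [0, 3]]))
            assert sum(a.angle_deg for a in angles) == pytest.approx(360.0, abs=1e-9)

    def test_coincident_neighbour_rejected(self):
        g = CenterlineGraph(
            positions=np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
            edges=np.array([[0, 1], [0, 2], [0, 3]]),
        )
        with pytest.raises(GraphBuildError, match="coincident"):
            furcation_angles(g)
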