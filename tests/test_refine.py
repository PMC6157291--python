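import numpy as np
import pytest

from gmalign.construct import AlignParams, Matching
from gmalign.evalmetrics import conserved_edges
from gmalign.refine import (
    BipartiteWeightMatrix,
    complete_matching,
    is_minimal_cover,
    is_vertex_cover,
    max_weight_assignment,
    minimal_vertex_cover,
    partition,
    refine_loop,
    refine_once,
    refinement_weights,
)
from conftest import brute_force_assignment, net_from_edges, random_net


@pytest.fixture
def isolated_instance():
    """Worked instance: one wrong matched pair fixable by a single refinement.

    G1 has edge a-b plus isolated c; G2 has edge x-y plus isolated z.
    The matching {(a,x), (b,z)} conserves nothing; matching b to y instead
    conserves the one edge.
    """
    net1 = net_from_edges("g1", [("a", "b")], nodes=["a", "b", "c"])
    net2 = net_from_edges("g2", [("x", "y")], nodes=["x", "y", "z"])
    m = Matching([("a", "x"), ("b", "z")])
    return net1, net2, m


class TestMinimalVertexCover:
    def test_triangle_cover_has_two_nodes(self, k3):
        cover = minimal_vertex_cover(k3, np.random.default_rng(0))
        assert len(cover) == 2 and is_vertex_cover(k3, cover)

    @pytest.mark.parametrize("seed", range(5))
    def test_star_cover_is_center_or_all_leaves(self, seed):
        # the only two minimal covers of a star: the hub, or all the leaves
        star = net_from_edges("star", [("c", f"l{i}") for i in range(4)])
        cover = minimal_vertex_cover(star, np.random.default_rng(seed))
        assert cover == {"c"} or cover == {f"l{i}" for i in range(4)}
        assert is_minimal_cover(star, cover)

    def test_edgeless_graph_has_empty_cover(self):
        net = net_from_edges("e", [], nodes=["a", "b", "c"])
        assert minimal_vertex_cover(net, np.random.default_rng(0)) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_random_covers_are_valid_and_minimal(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net("r", int(rng.integers(5, 40)), 0.2, seed)
        cover = minimal_vertex_cover(net, rng)
        assert is_vertex_cover(net, cover)
        assert is_minimal_cover(net, cover)


class TestPartition:
    def test_path_cover_center(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        m = Matching([("a", "x"), ("b", "y"), ("c", "z")])
        part = partition(m, net1, p3, "G1", {"b"})
        assert part.h_cov == {"b"} and part.h_img == {"y"}
        assert part.independent == {"a", "c"}

    def test_empty_matching_makes_everything_refinable(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        part = partition(Matching(), net1, p3, "G1", {"b"})
        assert part.h_cov == set() and part.h_img == set()

    def test_cover_on_second_network_mirrors(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        m = Matching([("a", "x"), ("b", "y"), ("c", "z")])
        part = partition(m, net1, p3, "G2", {"y"})
        assert part.h_cov == {"y"} and part.h_img == {"b"}

    def test_non_cover_rejected(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError, match="not a vertex cover"):
            partition(Matching(), net1, p3, "G1", {"a"})


class TestRefinementWeights:
    def test_paths_with_center_cover(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        m = Matching([("a", "x"), ("b", "y"), ("c", "z")])
        part = partition(m, net1, p3, "G1", {"b"})
        w = refinement_weights(part, net1, p3, m)
        get = lambda u, v: w.weights[w.rows.index(u), w.cols.index(v)]
        assert get("a", "x") == get("a", "z") == get("c", "x") == get("c", "z") == 1

    def test_node_without_frozen_neighbours_has_zero_row(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        m = Matching([("a", "x"), ("b", "y"), ("c", "z")])
        part = partition(m, net1, p3, "G1", {"b"})
        w = refinement_weights(part, net1, p3, m)
        # x and z have no neighbours inside the frozen image {y}... but a, c
        # do have the frozen neighbour b; a fully detached node is c's twin:
        net1b = net_from_edges("pb", [("a", "b")], nodes=["a", "b", "c"])
        m2 = Matching([("a", "x"), ("b", "y")])
        part2 = partition(m2, net1b, p3, "G1", {"a"})
        w2 = refinement_weights(part2, net1b, p3, m2)
        assert (w2.weights[w2.rows.index("c")] == 0).all()

    def test_isolated_instance_weights(self, isolated_instance):
        net1, net2, m = isolated_instance
        part = partition(m, net1, net2, "G1", {"a"})
        w = refinement_weights(part, net1, net2, m)
        get = lambda u, v: w.weights[w.rows.index(u), w.cols.index(v)]
        assert get("b", "y") == 1
        assert get("b", "z") == 0
        assert (w.weights[w.rows.index("c")] == 0).all()
        assert (w.weights <= 1).all() and (w.weights >= 0).all()


class TestAssignment:
    def test_two_by_two(self):
        w = BipartiteWeightMatrix(["u1", "u2"], ["v1", "v2"],
                                  np.array([[2, 1], [1, 1]]))
        m = max_weight_assignment(w)
        assert m.pairs == {("u1", "v1"), ("u2", "v2")}

    def test_singleton(self):
        w = BipartiteWeightMatrix(["u"], ["v"], np.array([[5]]))
        assert max_weight_assignment(w).pairs == {("u", "v")}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        weights = rng.integers(0, 10, size=(n, m))
        w = BipartiteWeightMatrix(
            [f"u{i}" for i in range(n)], [f"v{j}" for j in range(m)], weights
        )
        got = max_weight_assignment(w)
        total = sum(
            weights[int(u[1:]), int(v[1:])] for u, v in got.pairs
        )
        assert total == brute_force_assignment(weights)
        assert len(got) == min(n, m)  # smaller side fully assigned


class TestRefineSteps:
    def test_isolated_instance_improves(self, isolated_instance):
        net1, net2, m = isolated_instance
        assert conserved_edges(m, net1, net2) == 0
        part = partition(m, net1, net2, "G1", {"a"})
        m_star = refine_once(m, part, net1, net2)
        assert ("a", "x") in m_star  # frozen pair kept
        assert m_star.image("b") == "y"
        assert conserved_edges(m_star, net1, net2) == 1

    def test_tie_case_does_not_decrease(self, p3):
        net1 = net_from_edges("pa", [("a", "b"), ("b", "c")])
        m = Matching([("a", "x"), ("b", "y"), ("c", "z")])
        part = partition(m, net1, p3, "G1", {"b"})
        m_star = refine_once(m, part, net1, p3)
        assert conserved_edges(m_star, net1, p3) == 2

    def test_all_frozen_returns_same_matching(self, k3):
        m = Matching([("a", "a"), ("b", "b"), ("c", "c")])
        part = partition(m, k3, k3, "G1", {"a", "b"})
        m_star = refine_once(m, part, k3, k3)
        assert conserved_edges(m_star, k3, k3) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_refine_once_never_loses_conserved_edges(self, seed):
        """With unit sequence scores the conserved-edge count is
        non-decreasing across any single cover-based refinement step."""
        rng = np.random.default_rng(seed)
        net1 = random_net("a", 20, 0.15, seed)
        net2 = random_net("b", 22, 0.15, seed + 1000)
        nodes2 = net2.nodes
        perm = rng.permutation(len(nodes2))[: net1.n_nodes]
        m = Matching(
            (u, nodes2[int(j)]) for u, j in zip(net1.nodes, perm)
        )
        for step in range(5):
            side = "G1" if rng.random() < 0.5 else "G2"
            cover_net = net1 if side == "G1" else net2
            cover = minimal_vertex_cover(cover_net, rng)
            part = partition(m, net1, net2, side, cover)
            m_star = refine_once(m, part, net1, net2)
            assert conserved_edges(m_star, net1, net2) >= conserved_edges(
                m, net1, net2
            )
            m = m_star


class TestRefineLoop:
    def test_terminates_and_completes(self, isolated_instance):
        net1, net2, m = isolated_instance
        out = refine_loop(m, net1, net2, params=AlignParams(patience=3, seed=0))
        assert conserved_edges(out, net1, net2) == 1
        assert out.matched1 == net1.node_set  # total mapping

    def test_deterministic_under_seed(self):
        net1 = random_net("a", 20, 0.2, 5)
        net2 = random_net("b", 24, 0.2, 6)
        m0 = Matching([(net1.nodes[0], net2.nodes[0])])
        runs = [
            refine_loop(m0, net1, net2, params=AlignParams(seed=42))
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_patience_one_single_failed_trial(self, k3):
        m0 = Matching([("a", "a"), ("b", "b"), ("c", "c")])
        out = refine_loop(m0, k3, k3, params=AlignParams(patience=1, seed=0))
        assert conserved_edges(out, k3, k3) == 3

    def test_completion_pass(self, k3, p3):
        out = complete_matching(Matching([("a", "x")]), k3, p3)
        assert out.matched1 == {"a", "b", "c"}
        assert len(out) == 3
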