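"""Prior-knowledge graphs, PageRank potential, receptor activity, paths."""

import numpy as np
import pytest

import nnet
from nnet.prior import (
    PriorKnowledgeNetwork,
    classify_edges,
    personalized_pagerank,
    population_receptor_activity,
    reachable_within,
    receptor_activity,
    regulatory_potential,
    select_mediating_tfs,
    shortest_signaling_path,
    usp_triplets,
)


def _pkn(edges, kind="signaling"):
    return PriorKnowledgeNetwork.from_edges([(u, v, 1) for u, v in edges], kind=kind)


class TestPageRank:
    def test_edgeless_graph_has_zero_potential(self):
        pkn = PriorKnowledgeNetwork.from_edges([("a", "b", 1)], kind="signaling")
        rp = regulatory_potential(pkn, ["b"], ["a"])  # b is a sink
        # b's mass teleports back to itself; 'a' is unreachable
        assert rp.matrix[0, 0] == 0.0

    def test_two_state_chain_closed_form(self):
        # r -> t, t dangling; x_r = 1/(1+d), x_t = d/(1+d)
        pkn = _pkn([("r", "t")])
        d = 0.85
        vec = personalized_pagerank(pkn, "r", damping=d)
        np.testing.assert_allclose(vec["r"], 1 / (1 + d), atol=1e-12)
        np.testing.assert_allclose(vec["t"], d / (1 + d), atol=1e-12)

    def test_vectors_sum_to_one(self, rng):
        edges = {(f"n{a}", f"n{b}") for a, b in rng.integers(0, 20, (60, 2)) if a != b}
        pkn = _pkn(sorted(edges))
        for node in ["n0", "n5", "n11"]:
            if node in pkn.graph:
                vec = personalized_pagerank(pkn, node)
                np.testing.assert_allclose(sum(vec.values()), 1.0, atol=1e-10)

    def test_matches_dense_power_iteration_oracle(self, rng):
        edges = sorted({(f"n{a}", f"n{b}") for a, b in rng.integers(0, 20, (50, 2)) if a != b})
        pkn = _pkn(edges)
        nodes = pkn.nodes
        n = len(nodes)
        pos = {v: i for i, v in enumerate(nodes)}
        d = 0.85
        P = np.zeros((n, n))
        for u, v in edges:
            P[pos[u], pos[v]] = 1.0
        out = P.sum(axis=1)
        restart = pos[nodes[0]]
        M = np.zeros((n, n))
        for i in range(n):
            if out[i] > 0:
                M[i] = P[i] / out[i]
            else:
                M[i, restart] = 1.0  # dangling mass teleports to the restart node
        e = np.zeros(n)
        e[restart] = 1.0
        x = e.copy()
        for _ in range(20000):
            x_new = d * (M.T @ x) + (1 - d) * e
            if np.abs(x_new - x).sum() < 1e-15:
                break
            x = x_new
        vec = personalized_pagerank(pkn, nodes[0], damping=d)
        np.testing.assert_allclose([vec[v] for v in nodes], x, atol=1e-10)

    def test_missing_receptor_gives_zero_row_with_warning(self):
        pkn = _pkn([("a", "b")])
        with pytest.warns(UserWarning, match="absent"):
            rp = regulatory_potential(pkn, ["nope"], ["b"])
        np.testing.assert_array_equal(rp.matrix, 0.0)


class TestReceptorActivity:
    def test_identity_potential_gives_row_sums(self):
        rp = nnet.RegulatoryPotential(np.eye(2), ["r1", "r2"], ["p", "q"])
        csn = np.array([[1.0, 2.0], [3.0, 4.0]])
        res = receptor_activity(rp, csn, ["p", "q"], ["x", "y"])
        np.testing.assert_allclose(res.scores, [3.0, 7.0])

    def test_hand_product(self):
        rp = nnet.RegulatoryPotential(np.array([[1.0, 0.0], [0.0, 2.0]]), ["r1", "r2"], ["p", "q"])
        csn = np.array([[1.0, 2.0], [3.0, 4.0]])
        res = receptor_activity(rp, csn, ["p", "q"], ["x", "y"])
        np.testing.assert_allclose(res.activity, [[1.0, 2.0], [6.0, 8.0]])
        np.testing.assert_allclose(res.scores, [3.0, 14.0])

    def test_zero_network_gives_zero_scores(self):
        rp = nnet.RegulatoryPotential(np.ones((2, 2)), ["r1", "r2"], ["p", "q"])
        res = receptor_activity(rp, np.zeros((2, 3)), ["p", "q"], ["x", "y", "z"])
        np.testing.assert_array_equal(res.scores, 0.0)

    def test_linearity_in_the_network(self, rng):
        rp = nnet.RegulatoryPotential(rng.random((3, 2)), ["r1", "r2", "r3"], ["p", "q"])
        a, b = rng.random((2, 4)), rng.random((2, 4))
        ids = (["p", "q"], ["w", "x", "y", "z"])
        s = receptor_activity(rp, a + b, *ids).scores
        np.testing.assert_allclose(
            s,
            receptor_activity(rp, a, *ids).scores + receptor_activity(rp, b, *ids).scores,
            atol=1e-12,
        )

    def test_population_weighting(self, rng):
        scores = np.array([[1.0, 5.0], [3.0, 7.0]])  # cells x receptors
        out = population_receptor_activity(scores, np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [2.0, 6.0])
        one_hot = population_receptor_activity(scores, np.array([0.0, 1.0]))
        np.testing.assert_allclose(one_hot, scores[1])
        w = rng.random(2)
        oracle = sum(w[i] * scores[i] for i in range(2))
        np.testing.assert_allclose(population_receptor_activity(scores, w), oracle)


class TestReachability:
    def test_chain_reachable_within_two_steps(self):
        pkn = _pkn([("a", "b"), ("b", "c")], kind="regulation")
        assert reachable_within(pkn, "a", "c", 2)
        assert not reachable_within(pkn, "a", "c", 1)

    def test_unknown_node_is_false_not_error(self):
        pkn = _pkn([("a", "b")], kind="regulation")
        assert not reachable_within(pkn, "zz", "b", 2)

    def test_matches_boolean_matrix_power_oracle(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        edges = sorted({(nodes[a], nodes[b]) for a, b in rng.integers(0, 10, (20, 2)) if a < b})
        pkn = _pkn(edges, kind="regulation")
        adj = np.zeros((10, 10), dtype=bool)
        for u, v in edges:
            adj[int(u[1:]), int(v[1:])] = True
        reach = np.zeros_like(adj)
        power = np.eye(10, dtype=bool)
        for _ in range(3):
            power = power @ adj
            reach |= power
        for i in range(10):
            for j in range(10):
                assert reachable_within(pkn, nodes[i], nodes[j], 3) == bool(reach[i, j])


class TestMediatingTFs:
    def test_single_candidate(self):
        rp = nnet.RegulatoryPotential(np.array([[0.4]]), ["r"], ["p"])
        out = select_mediating_tfs(np.array([[1.0, 0.0]]), ["p"], rp, "r")
        assert out == ["p"]

    def test_dominant_tf_ranks_first(self):
        rp = nnet.RegulatoryPotential(np.array([[0.9, 0.1]]), ["r"], ["p", "q"])
        csn = np.array([[5.0, 1.0], [1.0, 1.0]])
        assert select_mediating_tfs(csn, ["p", "q"], rp, "r", top_t=2)[0] == "p"

    def test_matches_exhaustive_scoring_oracle(self, rng):
        tfs = [f"p{i}" for i in range(5)]
        rp = nnet.RegulatoryPotential(rng.random((1, 5)), ["r"], tfs)
        csn = rng.random((5, 6))
        degree = csn.sum(axis=1)
        pot = rp.matrix[0]
        rank = (degree / degree.max()) * (pot / pot.max())
        oracle = [tfs[i] for i in sorted(range(5), key=lambda i: (-rank[i], tfs[i]))][:3]
        assert select_mediating_tfs(csn, tfs, rp, "r", top_t=3) == oracle

    def test_all_zero_ranks_give_empty_list(self):
        rp = nnet.RegulatoryPotential(np.zeros((1, 2)), ["r"], ["p", "q"])
        assert select_mediating_tfs(np.zeros((2, 2)), ["p", "q"], rp, "r") == []


class TestShortestPaths:
    def test_direct_edge(self):
        path = shortest_signaling_path(_pkn([("r", "t")]), "r", "t")
        assert path.nodes == ["r", "t"] and path.hops == 1

    def test_chain(self):
        path = shortest_signaling_path(_pkn([("r", "m"), ("m", "t")]), "r", "t")
        assert path.nodes == ["r", "m", "t"]

    def test_no_path_returns_none(self):
        assert shortest_signaling_path(_pkn([("t", "r")]), "r", "t") is None

    def test_equal_length_ties_resolve_lexicographically(self):
        pkn = _pkn([("r", "b"), ("r", "a"), ("a", "t"), ("b", "t")])
        assert shortest_signaling_path(pkn, "r", "t").nodes == ["r", "a", "t"]

    def test_length_matches_networkx_bfs_oracle(self, rng):
        import networkx as nx

        edges = sorted({(f"n{a}", f"n{b}") for a, b in rng.integers(0, 12, (30, 2)) if a != b})
        pkn = _pkn(edges)
        for src, dst in [("n0", "n5"), ("n1", "n9"), ("n3", "n0")]:
            if src not in pkn.graph or dst not in pkn.graph:
                continue
            ours = shortest_signaling_path(pkn, src, dst)
            try:
                expected = nx.shortest_path_length(pkn.graph, src, dst)
            except nx.NetworkXNoPath:
                assert ours is None
                continue
            assert ours.hops == expected


class TestUSPTriplets:
    def test_single_surviving_edge_gives_one_triplet(self):
        rp = nnet.RegulatoryPotential(np.array([[0.5]]), ["REC"], ["p"])
        signaling = _pkn([("REC", "p")])
        csn = np.array([[0.0, 2.0]])
        out = usp_triplets(csn, ["p"], ["x", "y"], rp, signaling, ["REC"])
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.receptor, row.tf, row.target, row.coexpression) == ("REC", "p", "y", 2.0)

    def test_unreachable_tf_is_skipped_with_warning(self):
        rp = nnet.RegulatoryPotential(np.array([[0.5]]), ["REC"], ["p"])
        signaling = _pkn([("p", "REC")])  # wrong direction: no path REC -> p
        with pytest.warns(UserWarning, match="unreachable"):
            out = usp_triplets(np.array([[1.0]]), ["p"], ["x"], rp, signaling, ["REC"])
        assert out.empty

    def test_toy_system_matches_manual_enumeration(self):
        rp = nnet.RegulatoryPotential(np.array([[0.6, 0.2]]), ["REC"], ["p", "q"])
        signaling = _pkn([("REC", "m"), ("m", "p"), ("m", "q")])
        csn = np.array([[1.0, 0.0], [0.0, 3.0]])
        out = usp_triplets(csn, ["p", "q"], ["x", "y"], rp, signaling, ["REC"], top_t=2)
        got = {(r.tf, r.target, r.path) for r in out.itertuples(index=False)}
        assert got == {("p", "x", "REC->m->p"), ("q", "y", "REC->m->q")}


class TestEdgeClassification:
    def test_rule_table_exhaustive(self):
        grn = PriorKnowledgeNetwork.from_edges(
            [("p0", "x0", 1), ("p1", "x1", -1), ("p2", "x2", 0)], kind="regulation"
        )
        csn = np.ones((3, 3))
        scores = np.array(
            [[0.97, 0.2, 0.97], [0.97, 0.97, 0.2], [0.97, 0.5, 0.97]]
        )
        out = classify_edges(csn, scores, grn, ["p0", "p1", "p2"], ["x0", "x1", "x2"])
        table = {(r.tf, r.target): (r.evidence, r.sign) for r in out.itertuples(index=False)}
        assert table[("p0", "x0")] == ("prior_supported", "activation")
        assert table[("p1", "x1")] == ("prior_supported", "repression")
        assert table[("p2", "x2")] == ("prior_supported", "unknown")
        assert table[("p0", "x1")] == ("none", None)  # below threshold
        assert table[("p0", "x2")] == ("coexpression_only", None)
        assert table[("p1", "x0")] == ("coexpression_only", None)
        assert table[("p2", "x0")] == ("coexpression_only", None)

    def test_two_step_support_carries_unknown_sign(self):
        grn = PriorKnowledgeNetwork.from_edges(
            [("p", "m", 1), ("m", "x", 1)], kind="regulation"
        )
        out = classify_edges(
            np.ones((1, 1)), np.array([[0.99]]), grn, ["p"], ["x"], max_steps=2
        )
        assert out.iloc[0].evidence == "prior_supported"
        assert out.iloc[0].sign == "unknown"  # indirect support has no direct sign


class TestPKNConstruction:
    def test_conflicting_duplicate_edge_collapses_to_ambiguous(self):
        pkn = PriorKnowledgeNetwork.from_edges([("a", "b", 1), ("a", "b", -1)])
        assert pkn.sign("a", "b") == 0

    def test_table_round_trip(self):
        pkn = PriorKnowledgeNetwork.from_edges([("a", "b", 1), ("b", "c", -1)])
        back = PriorKnowledgeNetwork.from_table(pkn.to_table())
        assert back.sign("b", "c") == -1
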