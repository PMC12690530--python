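"""Correlation networks: closed-form graph cases, brute-force oracles,
community recovery, reachability and Jaccard comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sympy.utilities.iterables import multiset_partitions

from ivdkit import network, screen, synthetic as syn

from oracles import (
    betweenness_by_enumeration,
    floyd_warshall_lengths,
    khop_by_bfs,
    modularity_by_formula,
    random_graph,
)


def graph_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def corr_from_matrix(names, mat):
    r = pd.DataFrame(np.asarray(mat, dtype=float), index=names, columns=names)
    counts = pd.DataFrame(10, index=names, columns=names)
    return network.CorrelationMatrix(r=r, counts=counts)


class TestCorrelationMatrix:
    def _panel(self, cols):
        n = len(next(iter(cols.values())))
        base = {"animal_id": [f"a{i}" for i in range(n)],
                "group": ["g"] * n, "replicate": [1] * n}
        return pd.DataFrame({**base, **cols})

    def test_perfect_linearity(self):
        panel = self._panel({"A": [1, 2, 3], "B": [2, 4, 6]})
        corr = network.correlation_matrix(panel, "g")
        assert corr.r.loc["A", "B"] == pytest.approx(1.0)

    def test_diagonal_is_one(self):
        panel = self._panel({"A": [1, 2, 3], "B": [5, 1, 4]})
        corr = network.correlation_matrix(panel, "g")
        assert (np.diag(corr.r) == 1.0).all()

    def test_perfect_anticorrelation(self):
        panel = self._panel({"A": [1, 2, 3], "B": [6, 4, 2]})
        corr = network.correlation_matrix(panel, "g")
        assert corr.r.loc["A", "B"] == pytest.approx(-1.0)

    def test_constant_cytokine_undefined(self):
        panel = self._panel({"A": [1, 2, 3], "B": [2, 2, 2]})
        corr = network.correlation_matrix(panel, "g")
        assert np.isnan(corr.r.loc["A", "B"])
        assert corr.r.loc["B", "B"] == 1.0

    def test_pairwise_complete_counts(self):
        panel = self._panel({"A": [1, 2, 3, 4], "B": [2, np.nan, 6, 8]})
        corr = network.correlation_matrix(panel, "g")
        assert corr.counts.loc["A", "B"] == 3

    def test_too_few_complete_pairs_undefined(self):
        panel = self._panel(
            {"A": [1, 2, 3, 4], "B": [2, np.nan, np.nan, 8]}
        )
        corr = network.correlation_matrix(panel, "g")
        assert np.isnan(corr.r.loc["A", "B"])

    def test_absent_group_rejected(self):
        panel = self._panel({"A": [1, 2, 3]})
        with pytest.raises(ValueError, match="absent"):
            network.correlation_matrix(panel, "other")


class TestThresholdNetwork:
    def test_absolute_threshold(self):
        corr = corr_from_matrix(
            ["a", "b", "c"],
            [[1.0, 0.9, 0.5], [0.9, 1.0, -0.8], [0.5, -0.8, 1.0]],
        )
        net = network.threshold_network(corr, tau=0.7)
        assert set(map(frozenset, net.edges)) == {
            frozenset({"a", "b"}), frozenset({"b", "c"})
        }
        assert net.edges["b", "c"]["r"] == pytest.approx(-0.8)

    def test_high_tau_gives_edgeless_graph_with_all_nodes(self):
        corr = corr_from_matrix(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        net = network.threshold_network(corr, tau=0.99)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"a", "b"}

    def test_nan_never_creates_edge(self):
        corr = corr_from_matrix(["a", "b"], [[1.0, np.nan], [np.nan, 1.0]])
        assert network.threshold_network(corr).number_of_edges() == 0

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        corr = corr_from_matrix([f"n{i}" for i in range(8)], m)
        prev = None
        for tau in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset, network.threshold_network(corr, tau).edges))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_invalid_tau(self):
        corr = corr_from_matrix(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError):
            network.threshold_network(corr, tau=1.0)


class TestCentralities:
    def test_triangle_symmetry(self):
        net = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        table = network.centralities(net)
        np.testing.assert_allclose(
            table["eigenvector"], 1 / np.sqrt(3), atol=1e-8
        )
        assert (table["betweenness"] == 0).all()

    def test_path_betweenness(self):
        net = graph_from_edges([("a", "b"), ("b", "c")])
        table = network.centralities(net)
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)
        assert table.loc["a", "betweenness"] == 0.0
        assert table.loc["c", "betweenness"] == 0.0

    def test_four_cycle_split_credit(self):
        net = graph_from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        )
        table = network.centralities(net)
        np.testing.assert_allclose(table["betweenness"], 0.5)

    def test_eigenvector_residual_on_random_graphs(self):
        # A v = lambda v within tight residual on every emitted network
        for seed in range(20):
            net = random_graph(7, 0.4, seed)
            if net.number_of_edges() == 0:
                continue
            table = network.centralities(net)
            v = table["eigenvector"].to_numpy()
            a = nx.to_numpy_array(net, nodelist=table.index)
            lam = v @ a @ v
            assert np.linalg.norm(a @ v - lam * v) <= 1e-8 * max(lam, 1.0)
            assert np.linalg.norm(v) == pytest.approx(1.0)
            # cross-check against dense eigendecomposition
            w, vecs = np.linalg.eigh(a)
            ref = np.abs(vecs[:, -1])
            assert np.allclose(v, ref, atol=1e-6) or np.allclose(
                lam, w[-1], atol=1e-8
            )

    def test_disconnected_dominant_component(self):
        # triangle + isolated edge: dominant eigenvalue lives on the triangle
        net = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")]
        )
        table = network.centralities(net)
        assert table.loc["x", "eigenvector"] == pytest.approx(0.0, abs=1e-6)
        assert table.loc["a", "eigenvector"] > 0.5


class TestRankHubs:
    def _table(self, values):
        return pd.DataFrame(
            {"eigenvector": values, "betweenness": values},
            index=pd.Index([f"c{i}" for i in range(len(values))],
                           name="cytokine"),
        )

    def test_identical_tables_fully_shared(self):
        t = self._table([5, 4, 3, 2, 1, 0])
        out = network.rank_hubs({"m1": t, "m2": t}, top_k=3)
        assert out["eigenvector"]["shared"] == ["c0", "c1", "c2"]
        assert out["eigenvector"]["unique"] == {"m1": [], "m2": []}

    def test_disjoint_top_sets(self):
        t1 = self._table([5, 4, 0, 0])
        t2 = self._table([0, 0, 5, 4])
        out = network.rank_hubs({"m1": t1, "m2": t2}, top_k=2)
        assert out["betweenness"]["shared"] == []
        assert out["betweenness"]["unique"]["m1"] == ["c0", "c1"]

    def test_tie_broken_lexicographically(self):
        # c1 and c2 tie at rank 2; c1 enters by name order
        t = pd.DataFrame(
            {"eigenvector": [5.0, 3.0, 3.0], "betweenness": [5.0, 3.0, 3.0]},
            index=pd.Index(["c0", "c2", "c1"], name="cytokine"),
        )
        out = network.rank_hubs({"m": t}, top_k=2)
        assert out["eigenvector"]["top"]["m"] == ["c0", "c1"]

    def test_invalid_top_k(self):
        with pytest.raises(ValueError):
            network.rank_hubs({"m": self._table([1.0])}, top_k=0)


class TestAveragePathLength:
    def test_three_node_path(self):
        net = graph_from_edges([("a", "b"), ("b", "c")])
        assert network.average_path_length(net) == pytest.approx(4 / 3)

    def test_complete_graph(self):
        assert network.average_path_length(nx.complete_graph(6)) == 1.0

    def test_disconnected_pairs_excluded(self):
        net = graph_from_edges([("a", "b"), ("c", "d")])
        assert network.average_path_length(net) == 1.0

    def test_edgeless_rejected(self):
        net = graph_from_edges([], nodes=["a", "b"])
        with pytest.raises(ValueError, match="finite"):
            network.average_path_length(net)


class TestLouvain:
    def test_two_triangles(self):
        net = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("x", "y"), ("y", "z"), ("x", "z")]
        )
        part = network.louvain_communities(net, seed=0)
        assert len(set(part.communities.values())) == 2
        assert part.q == pytest.approx(0.5)
        assert part.communities["a"] == part.communities["b"]
        assert part.communities["a"] != part.communities["x"]

    def test_complete_graph_no_structure(self):
        part = network.louvain_communities(nx.complete_graph(4), seed=0)
        assert len(set(part.communities.values())) == 1
        assert part.q == pytest.approx(0.0)

    def test_reported_q_matches_formula(self):
        for seed in range(5):
            net = random_graph(7, 0.5, seed)
            if net.number_of_edges() == 0:
                continue
            part = network.louvain_communities(net, seed=seed)
            assert part.q == pytest.approx(
                modularity_by_formula(net, dict(part.communities))
            )

    def test_never_beats_exhaustive_optimum(self):
        # Louvain is greedy: its Q can never exceed the best partition
        for seed in range(8):
            net = random_graph(6, 0.45, seed)
            if net.number_of_edges() == 0:
                continue
            part = network.louvain_communities(net, seed=seed)
            best = max(
                modularity_by_formula(
                    net, {v: i for i, blk in enumerate(p) for v in blk}
                )
                for p in multiset_partitions(list(net.nodes))
            )
            assert part.q <= best + 1e-9

    def test_planted_two_block_recovery(self):
        struct = syn.two_block_structure(within_block_r=0.9, between_block_r=0.0)
        design = syn.GroupDesign(groups=("g", "h"), n_per_group=(30, 2))
        panel, truth = syn.generate_cytokine_panel(design, struct, seed=0)
        collapsed = screen.collapse_pseudoreplicates(panel)
        corr = network.correlation_matrix(collapsed, "g")
        net = network.threshold_network(corr)
        part = network.louvain_communities(net, seed=0)
        planted = {c: i for i, mem in enumerate(truth.blocks.values())
                   for c in mem}
        nodes = list(part.communities)
        ari = adjusted_rand_score(
            [planted[v] for v in nodes], [part.communities[v] for v in nodes]
        )
        assert ari == 1.0

    def test_edgeless_rejected(self):
        net = graph_from_edges([], nodes=["a"])
        with pytest.raises(ValueError):
            network.louvain_communities(net, seed=0)


class TestReachability:
    def test_path_k1_k2(self):
        net = graph_from_edges([("a", "b"), ("b", "c")])
        r1 = network.khop_reachability(net, 1)
        assert r1.pairs() == {frozenset("ab"), frozenset("bc")}
        r2 = network.khop_reachability(net, 2)
        assert r2.pairs() == {frozenset("ab"), frozenset("bc"),
                              frozenset("ac")}

    def test_monotone_in_k(self):
        for seed in range(10):
            net = random_graph(7, 0.3, seed)
            r1 = network.khop_reachability(net, 1).matrix
            r2 = network.khop_reachability(net, 2).matrix
            assert (r1 <= r2).all()

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            network.khop_reachability(nx.complete_graph(3), 0)


class TestJaccard:
    def test_identity(self):
        net = random_graph(6, 0.4, 1)
        r = network.khop_reachability(net, 2)
        assert network.jaccard_similarity(r, r).jaccard == 1.0

    def test_hand_case_one_third(self):
        nodes = list("abcd")
        net1 = graph_from_edges([("a", "b"), ("b", "c")], nodes=nodes)
        net2 = graph_from_edges([("b", "c"), ("c", "d")], nodes=nodes)
        comp = network.jaccard_similarity(
            network.khop_reachability(net1, 1),
            network.khop_reachability(net2, 1),
        )
        assert comp.jaccard == pytest.approx(1 / 3)

    def test_disjoint_reach_sets(self):
        nodes = list("abcd")
        net1 = graph_from_edges([("a", "b")], nodes=nodes)
        net2 = graph_from_edges([("c", "d")], nodes=nodes)
        comp = network.jaccard_similarity(
            network.khop_reachability(net1, 1),
            network.khop_reachability(net2, 1),
        )
        assert comp.jaccard == 0.0

    def test_empty_relations_identical_nodes(self):
        net = graph_from_edges([], nodes=["a", "b"])
        r = network.khop_reachability(net, 1)
        assert network.jaccard_similarity(r, r).jaccard == 1.0

    def test_symmetric_over_random_pairs(self):
        for seed in range(30):
            a = network.khop_reachability(random_graph(6, 0.35, seed), 2)
            b = network.khop_reachability(random_graph(6, 0.35, seed + 1000), 2)
            jab = network.jaccard_similarity(a, b).jaccard
            jba = network.jaccard_similarity(b, a).jaccard
            assert jab == jba
            assert 0.0 <= jab <= 1.0

    def test_mismatched_k_rejected(self):
        net = random_graph(5, 0.4, 0)
        with pytest.raises(ValueError, match="k"):
            network.jaccard_similarity(
                network.khop_reachability(net, 1),
                network.khop_reachability(net, 2),
            )


class TestOracleEquivalence:
    """Implementation vs brute force on small random graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_betweenness_matches_path_enumeration(self, seed):
        net = random_graph(6, 0.4, seed)
        table = network.centralities(net)
        oracle = betweenness_by_enumeration(net)
        for v in net.nodes:
            assert table.loc[v, "betweenness"] == pytest.approx(
                oracle[v], abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(15))
    def test_path_lengths_match_floyd_warshall(self, seed):
        net = random_graph(7, 0.35, seed)
        d = floyd_warshall_lengths(net)
        finite = d[np.isfinite(d) & (d > 0)]
        if finite.size == 0:
            return
        assert network.average_path_length(net) == pytest.approx(finite.mean())

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_reachability_matches_bfs(self, seed, k):
        net = random_graph(7, 0.3, seed)
        np.testing.assert_array_equal(
            network.khop_reachability(net, k).matrix, khop_by_bfs(net, k)
        )


class TestLayoutExport:
    def test_nodes_emitted_even_without_edges(self):
        net = graph_from_edges([], nodes=["a", "b"])
        table = network.centralities(net)
        nodes, edges = network.layout_export(net, table, seed=0)
        assert len(nodes) == 2 and len(edges) == 0

    def test_seed_determinism(self):
        net = random_graph(6, 0.5, 3)
        table = network.centralities(net)
        n1, _ = network.layout_export(net, table, seed=42)
        n2, _ = network.layout_export(net, table, seed=42)
        pd.testing.assert_frame_equal(n1, n2)

    def test_triangle_equal_colors(self):
        net = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        nodes, _ = network.layout_export(net, network.centralities(net), seed=0)
        assert nodes["color_value"].nunique() == 1 or np.allclose(
            nodes["color_value"], nodes["color_value"].iloc[0], atol=1e-8
        )

    def test_node_mismatch_rejected(self):
        net = graph_from_edges([("a", "b")])
        other = network.centralities(graph_from_edges([("x", "y")]))
        with pytest.raises(ValueError, match="match"):
            network.layout_export(net, other, seed=0)
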