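"""Network construction, scoring, degree ranking and merging."""

import math

import networkx as nx
import numpy as np
import pytest

from angiocompendium.networks import (
    GeneNetwork,
    annotate_regulation,
    build_networks,
    common_nodes,
    confidence_percent,
    degree_ranking,
    merge_networks,
    overlap_percent,
    p_from_score,
    score_network,
)
from conftest import make_de


def brute_force_score(nodes, focus, universe):
    m, k_total, n = len(universe), len(set(focus) & set(universe)), len(nodes)
    overlap = len(set(nodes) & set(focus))
    p = sum(
        math.comb(k_total, k) * math.comb(m - k_total, n - k) / math.comb(m, n)
        for k in range(overlap, min(k_total, n) + 1)
    )
    return -math.log10(min(1.0, p))


class TestCommonNodes:
    def test_disjoint_sets(self):
        table = common_nodes({"A": {"G1", "G2"}, "B": {"G3"}})
        assert table.loc["A", "A"] == 2
        assert table.loc["B", "B"] == 1
        assert table.loc["A", "B"] == 0

    def test_constructed_table_fixture_sizes(self):
        # sizes mirroring a published common-node table row: |A|=539,
        # |B|=1211, |A&B|=52
        shared = {f"S{i}" for i in range(52)}
        a = shared | {f"A{i}" for i in range(539 - 52)}
        b = shared | {f"B{i}" for i in range(1211 - 52)}
        table = common_nodes({"A": a, "B": b})
        assert table.loc["A", "A"] == 539
        assert table.loc["B", "B"] == 1211
        assert table.loc["A", "B"] == table.loc["B", "A"] == 52

    def test_pairwise_but_no_triple_overlap(self):
        sets = {
            "A": {"AB", "CA", "A0"},
            "B": {"AB", "BC", "B0"},
            "C": {"BC", "CA", "C0"},
        }
        table = common_nodes(sets)
        off = [table.loc[a, b] for a in "ABC" for b in "ABC" if a != b]
        assert off == [1] * 6
        assert not (sets["A"] & sets["B"] & sets["C"])

    def test_symmetry_and_diagonal_dominance(self, rng):
        sets = {
            t: set(rng.choice([f"G{i}" for i in range(50)], size=20, replace=False))
            for t in "WXYZ"
        }
        table = common_nodes(sets)
        arr = table.to_numpy()
        assert (arr == arr.T).all()
        assert (np.diag(arr)[:, None] >= arr).all()


class TestOverlapPercent:
    def test_conventions_differ_but_bound_each_other(self):
        a = set(range(100))
        b = set(range(50, 200))
        by_union = overlap_percent(a, b, "union")
        by_smaller = overlap_percent(a, b, "smaller")
        by_mean = overlap_percent(a, b, "mean")
        assert by_union <= by_mean <= by_smaller
        assert by_smaller == pytest.approx(50.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            overlap_percent({"A"}, {"A"}, "jaccardish")


class TestScoreNetwork:
    def test_background_fraction_scores_near_zero(self):
        universe = [f"G{i}" for i in range(1000)]
        focus = set(universe[:100])  # 10% background
        nodes = universe[:3] + universe[500:527]  # 3/30 = 10% focus
        assert score_network(nodes, focus, universe) < 1.0

    def test_score_three_is_99_9_percent_confidence(self):
        assert p_from_score(3.0) == pytest.approx(1e-3)
        assert confidence_percent(3.0) == pytest.approx(99.9)

    def test_all_focus_network_closed_form(self):
        universe = [f"G{i}" for i in range(100)]
        focus = universe[:10]
        score = score_network(focus, focus, universe)
        assert score == pytest.approx(math.log10(math.comb(100, 10)), rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_small_universes(self, seed):
        gen = np.random.default_rng(seed)
        m = int(gen.integers(10, 51))
        universe = [f"G{i}" for i in range(m)]
        focus = list(gen.choice(universe, size=int(gen.integers(1, m)), replace=False))
        nodes = list(gen.choice(universe, size=int(gen.integers(1, m)), replace=False))
        assert score_network(nodes, focus, universe) == pytest.approx(
            brute_force_score(nodes, focus, universe), rel=1e-8
        )

    def test_nodes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            score_network({"X"}, {"X"}, {"Y"})


class TestBuildNetworks:
    def test_star_graph_single_network(self):
        graph = nx.Graph()
        leaves = [f"F{i}" for i in range(10)]
        for leaf in leaves:
            graph.add_edge("HUB", leaf)
        nets = build_networks(leaves, graph, size_cap=11, n_networks=3)
        assert len(nets) == 1
        assert nets[0].nodes == frozenset(["HUB", *leaves])

    def test_two_disconnected_cliques_become_two_networks(self):
        graph = nx.Graph()
        clique1 = [f"A{i}" for i in range(6)]
        clique2 = [f"B{i}" for i in range(6)]
        for clique in (clique1, clique2):
            for i, u in enumerate(clique):
                for v in clique[i + 1:]:
                    graph.add_edge(u, v)
        nets = build_networks(clique1 + clique2, graph, size_cap=35, n_networks=3)
        assert len(nets) == 2
        assert {net.nodes for net in nets} == {frozenset(clique1), frozenset(clique2)}

    def test_high_focus_network_scores_above_three(self, rng):
        universe = [f"G{i}" for i in range(5000)]
        focus = set(universe[:500])
        graph = nx.Graph()
        core = universe[:30] + universe[600:605]
        hub = core[0]
        for node in core[1:]:
            graph.add_edge(hub, node)
        for i in range(0, 4900, 2):  # background edges
            graph.add_edge(universe[i], universe[i + 1])
        nets = build_networks(focus, graph, size_cap=35, n_networks=1)
        assert nets[0].score > 3.0

    def test_deterministic_and_connected(self, rng):
        genes = [f"G{i:03d}" for i in range(120)]
        graph = nx.Graph()
        edges = rng.integers(0, 120, size=(260, 2))
        for a, b in edges:
            if a != b:
                graph.add_edge(genes[a], genes[b])
        focus = list(rng.choice(genes, size=30, replace=False))
        first = build_networks(focus, graph)
        second = build_networks(list(reversed(focus)), graph)
        assert [n.nodes for n in first] == [n.nodes for n in second]
        assert [n.score for n in first] == [n.score for n in second]
        for net in first:
            assert nx.is_connected(nx.Graph(list(net.edges)) if net.edges
                                   else nx.Graph([(net.seed_gene, net.seed_gene)]))
            assert len(net.nodes) <= 35

    def test_focus_outside_graph_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="focus"):
            assert build_networks({"X"}, nx.Graph([("A", "B")])) == []


class TestDegreeRanking:
    def test_star_hub_ranked_first(self):
        leaves = [f"L{i}" for i in range(6)]
        net = GeneNetwork(
            nodes=frozenset(["HUB", *leaves]),
            edges=frozenset(tuple(sorted(("HUB", leaf))) for leaf in leaves),
            seed_gene="HUB",
            score=5.0,
        )
        ranking = degree_ranking(net)
        assert ranking.iloc[0]["gene"] == "HUB"
        assert ranking.iloc[0]["connections"] == 6

    def test_external_edges_do_not_count(self):
        # B's only interactions leave the network, so its intra-network
        # degree is 0
        net = GeneNetwork(
            nodes=frozenset({"A", "B", "C"}),
            edges=frozenset({("A", "C")}),
            seed_gene="A",
            score=1.0,
        )
        ranking = degree_ranking(net).set_index("gene")
        assert ranking.loc["B", "connections"] == 0

    def test_clique_ties_break_lexicographically(self):
        nodes = ["D", "B", "C", "A"]
        edges = frozenset(
            tuple(sorted((u, v))) for i, u in enumerate(nodes) for v in nodes[i + 1:]
        )
        net = GeneNetwork(frozenset(nodes), edges, "A", 1.0)
        ranking = degree_ranking(net)
        assert list(ranking["gene"]) == ["A", "B", "C", "D"]
        assert (ranking["connections"] == 3).all()


class TestMergeNetworks:
    @staticmethod
    def net(nodes, edges, label, regulation=None):
        return GeneNetwork(
            nodes=frozenset(nodes),
            edges=frozenset(tuple(sorted(e)) for e in edges),
            seed_gene=sorted(nodes)[0],
            score=1.0,
            label=label,
            regulation=regulation or {},
        )

    def test_merge_identical_networks_idempotent(self):
        a = self.net({"TGFB1", "X"}, [("TGFB1", "X")], "t1")
        merged = merge_networks([a, a], {"TGFB1"})
        assert merged.nodes == a.nodes
        assert merged.edges == a.edges

    def test_union_of_nodes_and_edges(self):
        a = self.net({"TGFB1", "B"}, [("B", "TGFB1")], "t1")
        b = self.net({"B", "C", "TGFB3"}, [("B", "C")], "t2")
        merged = merge_networks([a, b], {"TGFB1", "TGFB3"})
        assert merged.nodes == {"TGFB1", "B", "C", "TGFB3"}
        assert merged.edges == {("B", "TGFB1"), ("B", "C")}

    def test_conflicting_states_kept_per_treatment(self):
        a = self.net({"TGFB1", "N"}, [("N", "TGFB1")], "t1", {"N": "up"})
        b = self.net({"TGFB1", "N"}, [("N", "TGFB1")], "t2", {"N": "down"})
        merged = merge_networks([a, b], {"TGFB1"})
        assert merged.regulation["N"] == {"t1": "up", "t2": "down"}

    def test_network_without_anchor_excluded_with_warning(self):
        a = self.net({"TGFB1", "X"}, [("TGFB1", "X")], "t1")
        b = self.net({"Y", "Z"}, [("Y", "Z")], "t2")
        with pytest.warns(UserWarning, match="anchor"):
            merged = merge_networks([a, b], {"TGFB1"})
        assert "Y" not in merged.nodes

    def test_no_anchored_network_is_an_error(self):
        a = self.net({"Y", "Z"}, [("Y", "Z")], "t1")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="anchor"):
                merge_networks([a], {"TGFB1"})


class TestAnnotateRegulation:
    def test_states_follow_de_directions(self):
        net = GeneNetwork(frozenset({"A", "B", "C"}), frozenset(), "A", 0.0)
        de = make_de(up=["A"], down=["B"], other=["C"])
        annotated = annotate_regulation(net, de, label="t")
        assert annotated.regulation == {"A": "up", "B": "down", "C": "none"}
        assert annotated.label == "t"
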