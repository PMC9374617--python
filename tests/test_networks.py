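"""Graph builders, metrics and community detection versus independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from aunet import (
    CommunityPartition,
    TestResult,
    build_bipartite_graph,
    build_conditional_graph,
    build_cooccurrence_graph,
    build_significance_graph,
    conditional_probabilities,
    detect_communities,
    export_graph,
    graph_metrics,
    modularity,
    parse_combination_strings,
    read_graph,
    specificity,
    unconditional_probabilities,
)


def result(element, p_increase, observed=0.5, count=5):
    return TestResult(
        element=tuple(sorted(element)),
        observed=observed,
        expected_mean=0.1,
        effect_size=observed - 0.1,
        p_increase=p_increase,
        p_decrease=1.0 - p_increase,
        observed_count=count,
    )


def two_condition_table():
    lines = ["A+B", "A+B", "A+B", "A"] + ["C", "C+A", "C"]
    conds = ["X"] * 4 + ["Y"] * 3
    return parse_combination_strings(lines, conditions=conds)


class TestBipartiteGraph:
    def setup_method(self):
        self.table = two_condition_table()
        self.spec = specificity(self.table)

    def test_edges_follow_significance_and_weights(self):
        tests = {
            "X": [result(("B",), 0.005), result(("A",), 0.5)],
            "Y": [result(("C",), 0.002), result(("A",), 0.9)],
        }
        g = build_bipartite_graph(self.spec, tests, mode="occurrence", alpha=0.01)
        assert set(g.edges) == {("B", "X"), ("C", "Y")}
        assert g.edges["B", "X"]["weight"] == pytest.approx(3 / 4)  # P(B|X)
        g2 = build_bipartite_graph(self.spec, tests, mode="specificity", alpha=0.01)
        assert g2.edges["B", "X"]["weight"] == pytest.approx(1.0)  # P(X|B)

    def test_no_significant_pairs_yields_edgeless_graph(self):
        tests = {c: [result(("A",), 1.0)] for c in ("X", "Y")}
        g = build_bipartite_graph(self.spec, tests, alpha=0.01)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() > 0

    def test_edges_never_within_a_node_class(self):
        tests = {
            "X": [result((u,), 0.001) for u in "ABC"],
            "Y": [result((u,), 0.001) for u in "ABC"],
        }
        g = build_bipartite_graph(self.spec, tests, alpha=0.01)
        for a, b in g.edges:
            assert g.nodes[a]["bipartite"] != g.nodes[b]["bipartite"]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            build_bipartite_graph(self.spec, {}, alpha=0.0)


class TestConditionalGraph:
    def test_one_way_threshold_pass(self):
        # B occurs 5 times, always with A; A occurs 25 times
        lines = ["A+B"] * 5 + ["A"] * 20 + [""] * 5
        t = parse_combination_strings(lines, universe=["A", "B"])
        g = build_conditional_graph(conditional_probabilities(t), 0.3, 3)
        assert list(g.edges) == [("B", "A")]
        assert g.edges["B", "A"]["weight"] == 1.0

    def test_low_joint_count_blocks_edge(self):
        lines = ["A+B"] * 2 + [""] * 2
        t = parse_combination_strings(lines, universe=["A", "B"])
        g = build_conditional_graph(conditional_probabilities(t), 0.3, 3)
        assert g.number_of_edges() == 0

    def test_probability_threshold_is_strict(self):
        lines = ["A+B"] * 3 + ["A"] * 7
        t = parse_combination_strings(lines, universe=["A", "B"])
        g = build_conditional_graph(conditional_probabilities(t), min_probability=0.3, min_count=3)
        # P(B|A) = 0.3 exactly: excluded by the strict threshold
        assert ("A", "B") not in g.edges
        assert ("B", "A") in g.edges  # P(A|B) = 1

    def test_tight_cluster_fully_connected_both_ways(self):
        lines = ["A+B+C+D"] * 6 + [""] * 4
        t = parse_combination_strings(lines, universe=list("ABCD"))
        g = build_conditional_graph(conditional_probabilities(t), 0.3, 3)
        for a, b in itertools.permutations("ABCD", 2):
            assert g.edges[a, b]["weight"] == 1.0
        assert g.nodes["A"]["n_connections"] == 6


class TestSignificanceGraph:
    def test_single_passing_dyad(self):
        tests = [result(("A",), 0.001), result(("B",), 0.5), result(("A", "B"), 0.01), result(("A", "C"), 0.2), result(("C",), 0.3)]
        g = build_significance_graph(tests, alpha=0.01)
        assert set(g.edges) == {("A", "B")}
        assert g.nodes["A"]["significant"] is True
        assert g.nodes["B"]["significant"] is False

    def test_planted_clique_recovered(self):
        units = list("ABCDE")
        tests = [result((u,), 0.001) for u in units]
        tests += [result(pair, 0.001) for pair in itertools.combinations(units, 2)]
        tests += [result(("F",), 0.8), result(("A", "F"), 0.9)]
        g = build_significance_graph(tests, alpha=0.01)
        assert g.number_of_edges() == 10
        assert nx.density(g.subgraph(units)) == 1.0

    def test_raising_alpha_never_removes_edges(self):
        rng = np.random.default_rng(0)
        units = [f"AU{i}" for i in range(8)]
        tests = [result((u,), float(rng.random())) for u in units]
        tests += [result(p, float(rng.random())) for p in itertools.combinations(units, 2)]
        prev = set()
        for alpha in (0.01, 0.05, 0.2, 0.5, 1.0):
            edges = set(build_significance_graph(tests, alpha=alpha).edges)
            assert prev <= edges
            prev = edges


# -- metrics ----------------------------------------------------------------


def oracle_density(g):
    n = g.number_of_nodes()
    return 0.0 if n < 2 else g.number_of_edges() / (n * (n - 1) / 2)


def oracle_transitivity(g):
    nodes = list(g.nodes)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
    )
    triples = sum(1 for _a in nodes for b, c in itertools.combinations(list(g[_a]), 2))
    return 3 * triangles / triples if triples else 0.0


class TestGraphMetrics:
    def test_complete_graph(self):
        m = graph_metrics(nx.complete_graph(5))
        assert m.density == 1.0 and m.transitivity == 1.0

    def test_star_graph(self):
        m = graph_metrics(nx.star_graph(3))  # 4 nodes, 3 edges
        assert m.density == pytest.approx(0.5)
        assert m.transitivity == 0.0 and m.transitivity_defined

    def test_graph_without_triples_flagged(self):
        g = nx.Graph([("A", "B")])
        m = graph_metrics(g)
        assert m.transitivity == 0.0 and not m.transitivity_defined

    def test_strength_is_mean_edge_weight(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.4)
        g.add_edge("A", "C", weight=0.8)
        m = graph_metrics(g)
        assert m.strength["A"] == pytest.approx(0.6)
        assert m.strength["B"] == pytest.approx(0.4)
        assert m.degree["A"] == 2

    def test_directed_graph_symmetrized(self):
        g = nx.DiGraph([("A", "B"), ("B", "A"), ("B", "C")])
        m = graph_metrics(g)
        assert m.n_edges == 2
        assert m.density == pytest.approx(2 / 3)

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)), seed=int(rng.integers(1 << 30)))
            m = graph_metrics(g)
            assert m.density == pytest.approx(oracle_density(g))
            assert m.transitivity == pytest.approx(oracle_transitivity(g))
            assert m.degree == {str(u): d for u, d in g.degree()}


# -- communities ------------------------------------------------------------


def all_partitions(nodes):
    """Every set partition of ``nodes`` (Bell-number many)."""
    if not nodes:
        yield []
        return
    head, *rest = nodes
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1 :]
        yield part + [[head]]


def two_cliques(k=4):
    g = nx.Graph()
    for off in (0, k):
        for i, j in itertools.combinations(range(k), 2):
            g.add_edge(f"n{off + i}", f"n{off + j}")
    return g


class TestCommunities:
    def test_two_disjoint_cliques(self):
        g = two_cliques()
        part = detect_communities(g, weighted=False)
        assert part.modularity == pytest.approx(0.5)
        assert set(part.clusters()) == {
            tuple(f"n{i}" for i in range(4)),
            tuple(f"n{i}" for i in range(4, 8)),
        }

    def test_two_clique_partition_is_global_optimum(self):
        g = two_cliques()
        best = max(
            modularity(g, {u: i for i, cl in enumerate(p) for u in cl}, weighted=False)
            for p in all_partitions(sorted(g.nodes))
        )
        assert best == pytest.approx(0.5)
        assert detect_communities(g, weighted=False).modularity == pytest.approx(best)

    def test_single_clique_is_one_community(self):
        part = detect_communities(nx.complete_graph(5), weighted=False)
        assert len(part.clusters()) == 1
        assert part.modularity == pytest.approx(0.0)

    def test_random_graph_modularity_near_zero(self):
        g = nx.gnp_random_graph(30, 0.4, seed=0)
        part = detect_communities(g, weighted=False)
        assert part.modularity < 0.25

    def test_partition_modularity_recomputable(self, ck_table):
        probs = unconditional_probabilities(ck_table)
        g = build_cooccurrence_graph(probs)
        part = detect_communities(g, weighted=True)
        assert modularity(g, part, weighted=True) == pytest.approx(part.modularity)

    def test_planted_two_block_recovery(self):
        recovered = 0
        n_seeds = 25
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            nodes = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for u, v in itertools.combinations(nodes, 2):
                p = 0.9 if u[0] == v[0] else 0.05
                if rng.random() < p:
                    g.add_edge(u, v)
            part = detect_communities(g, weighted=False)
            if set(part.clusters()) == {tuple(sorted(nodes[:6])), tuple(sorted(nodes[6:]))}:
                recovered += 1
        assert recovered >= 0.95 * n_seeds

    def test_deterministic(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        assert detect_communities(g) == detect_communities(g)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(nx.Graph())

    def test_agrees_with_igraph_fast_greedy(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(8)
        for s in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            part = detect_communities(g, weighted=False)
            ig = igraph.Graph.from_networkx(g)
            ref = ig.community_fastgreedy().as_clustering()
            assert part.modularity == pytest.approx(ref.modularity, abs=0.02)


class TestModularity:
    def test_one_cluster_is_zero(self):
        g = nx.gnp_random_graph(10, 0.5, seed=1)
        assert modularity(g, {u: 0 for u in g.nodes}) == pytest.approx(0.0)

    def test_two_clique_value(self):
        g = two_cliques()
        part = {u: (0 if int(u[1]) < 4 else 1) for u in g.nodes}
        assert modularity(g, part, weighted=False) == pytest.approx(0.5)

    def test_strictly_below_one(self):
        g = two_cliques(6)
        part = {u: (0 if int(u[1]) < 6 else 1) for u in g.nodes}
        assert modularity(g, part, weighted=False) < 1.0

    def test_missing_node_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError, match="missing"):
            modularity(g, {"A": 0})

    def test_matches_networkx_on_random_partitions(self):
        import networkx.algorithms.community as nxc

        rng = np.random.default_rng(2)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            labels = rng.integers(0, 3, 10)
            part = {u: int(labels[u]) for u in g.nodes}
            groups = [set(u for u in g.nodes if part[u] == c) for c in range(3)]
            groups = [s for s in groups if s]
            assert modularity(g, part, weighted=False) == pytest.approx(
                nxc.modularity(g, groups, weight=None)
            )


class TestExport:
    @pytest.mark.parametrize("fmt", ["graphml", "json", "csv"])
    def test_round_trip(self, tmp_path, fmt):
        g = nx.Graph()
        g.add_edge("AU1", "AU2", weight=0.5)
        g.add_edge("AU2", "AU4", weight=0.25)
        path = str(tmp_path / f"g.{fmt}")
        export_graph(g, fmt, path)
        back = read_graph(fmt, path)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for a, b in g.edges:
            assert float(back.edges[a, b]["weight"]) == g.edges[a, b]["weight"]

    def test_bipartite_csv_carries_node_classes(self, tmp_path):
        t = two_condition_table()
        spec = specificity(t)
        tests = {"X": [result(("B",), 0.001)], "Y": [result(("C",), 0.001)]}
        g = build_bipartite_graph(spec, tests)
        path = str(tmp_path / "bip.csv")
        export_graph(g, "csv", path)
        import pandas as pd

        df = pd.read_csv(path)
        assert {"source_kind", "target_kind"} <= set(df.columns)
        assert set(df["source_kind"]) | set(df["target_kind"]) == {"unit", "condition"}

    def test_empty_graph_exports(self, tmp_path):
        g = nx.Graph()
        g.add_node("AU1")
        for fmt in ("graphml", "json", "csv"):
            export_graph(g, fmt, str(tmp_path / f"e.{fmt}"))

    def test_deterministic_bytes(self, tmp_path):
        g = nx.Graph()
        g.add_edge("B", "A", weight=0.3)
        g.add_edge("C", "A", weight=0.7)
        p1, p2 = str(tmp_path / "a.graphml"), str(tmp_path / "b.graphml")
        export_graph(g, "graphml", p1)
        export_graph(g, "graphml", p2)
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_graph(nx.Graph(), "gexf", str(tmp_path / "x"))
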