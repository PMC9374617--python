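"""Graphs over units and conditions, graph-level metrics, communities.

Four graph types are built from probability and test outputs:

* bipartite unit-condition graphs, edges gated by significance and weighted
  by occurrence probability P(unit|condition) or context specificity
  P(condition|unit);
* directed conditional-probability graphs between units (edge A->B weighted
  by P(B|A), thresholded on probability and joint count);
* undirected unweighted significance graphs per condition (an edge means the
  dyad co-occurs significantly more than in the comparison data);
* weighted undirected co-occurrence graphs over the whole dataset, the input
  to blind community detection.

Graphs are plain :mod:`networkx` objects so the whole networkx toolbox
applies; the helpers here add the domain conventions (node classes, weight
semantics, deterministic exports) and the metrics reported in analyses:
density, transitivity (global clustering coefficient), degree, strength, and
greedy modularity-based community structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .probability import (
    CombinationKey,
    ConditionalTable,
    ProbabilityTable,
    SpecificityTable,
    format_key,
)
from .resampling import TestResult

__all__ = [
    "CommunityPartition",
    "GraphMetrics",
    "build_bipartite_graph",
    "build_conditional_graph",
    "build_significance_graph",
    "build_cooccurrence_graph",
    "graph_metrics",
    "detect_communities",
    "modularity",
    "export_graph",
    "read_graph",
]

EXPORT_FORMATS = ("graphml", "csv", "json")


@dataclass(frozen=True)
class CommunityPartition:
    """Node-to-cluster assignment with the partition's modularity."""

    assignment: dict[str, int]
    modularity: float

    def clusters(self) -> list[tuple[str, ...]]:
        """Cluster memberships as sorted tuples, ordered by cluster id."""
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return [tuple(sorted(out[cid])) for cid in sorted(out)]


@dataclass(frozen=True)
class GraphMetrics:
    """Graph-level and node-level summary metrics.

    ``transitivity_defined`` is False when the graph has no connected triple
    (fewer than 3 nodes or no path of length 2), in which case transitivity
    is reported as 0.
    """

    n_nodes: int
    n_edges: int
    density: float
    transitivity: float
    transitivity_defined: bool
    degree: dict[str, int]
    strength: dict[str, float]

    def to_row(self) -> dict[str, float]:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "density": self.density,
            "transitivity": self.transitivity,
        }


# -- builders ---------------------------------------------------------------


def _single_unit_p_increase(tests: Sequence[TestResult]) -> dict[str, float]:
    return {r.element[0]: r.p_increase for r in tests if len(r.element) == 1}


def build_bipartite_graph(
    spec: SpecificityTable,
    tests: Mapping[str, Sequence[TestResult]],
    mode: str = "occurrence",
    alpha: float = 0.01,
) -> nx.Graph:
    """Bipartite unit-condition graph gated by between-condition significance.

    ``tests`` maps each condition label to the results of comparing that
    condition against all others.  An edge (unit, condition) exists iff the
    unit occurred significantly more often in the condition than the
    comparison bootstrap predicts (``p_increase <= alpha``); its weight is
    P(unit|condition) in ``occurrence`` mode or P(condition|unit) in
    ``specificity`` mode.  Unit nodes carry ``bipartite=0``, condition nodes
    ``bipartite=1``; edges never run within a node class.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if mode not in ("occurrence", "specificity"):
        raise ValueError(f"unknown mode {mode!r}; expected 'occurrence' or 'specificity'")
    units = sorted({k[0] for (k, _c) in spec.entries if len(k) == 1})
    g = nx.Graph(mode=mode, alpha=alpha)
    for u in units:
        g.add_node(u, bipartite=0, kind="unit")
    for c in spec.conditions:
        g.add_node(c, bipartite=1, kind="condition")
    for c in spec.conditions:
        if c not in tests:
            raise ValueError(f"no test results supplied for condition {c!r}")
        p_inc = _single_unit_p_increase(tests[c])
        for u in units:
            if ((u,), c) not in spec.entries:
                continue
            if p_inc.get(u, 1.0) <= alpha:
                sp, occ, cic, _tot = spec.entries[((u,), c)]
                weight = occ if mode == "occurrence" else sp
                g.add_edge(u, c, weight=float(weight), p_increase=p_inc[u], count=cic)
    return g


def build_conditional_graph(
    cond: ConditionalTable,
    min_probability: float = 0.3,
    min_count: int = 3,
) -> nx.DiGraph:
    """Directed weighted graph of pairwise conditional probabilities.

    Edge A->B with weight P(B|A) exists iff P(B|A) strictly exceeds
    ``min_probability`` and the units co-occur at least ``min_count`` times.
    The default thresholds (0.3, 3) suppress edges driven by one or two
    shared events.  Node attribute ``n_connections`` counts in- plus
    out-going edges (used as node size in displays).
    """
    if min_probability < 0 or min_count < 0:
        raise ValueError("thresholds must be >= 0")
    g = nx.DiGraph(min_probability=min_probability, min_count=min_count)
    units = sorted({u for pair in cond.entries for u in pair})
    g.add_nodes_from(units)
    for (a, b), (jc, ca, p) in sorted(cond.entries.items()):
        if p > min_probability and jc >= min_count:
            g.add_edge(a, b, weight=float(p), joint_count=jc)
    for u in g.nodes:
        g.nodes[u]["n_connections"] = g.in_degree(u) + g.out_degree(u)
    return g


def build_significance_graph(
    tests: Sequence[TestResult],
    alpha: float = 0.01,
) -> nx.Graph:
    """Undirected unweighted graph of significantly associated dyads.

    Nodes are the units observed in the condition (test results exist only
    for observed elements, so never-observed units are absent).  An edge
    {A, B} means the dyad's probability in this condition exceeded the null
    expectation at ``p_increase <= alpha``; the node attribute
    ``significant`` marks single units that individually exceeded it.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    g = nx.Graph(alpha=alpha)
    for r in tests:
        if len(r.element) == 1:
            g.add_node(
                r.element[0],
                significant=bool(r.p_increase <= alpha),
                observed_prob=r.observed,
                count=r.observed_count,
            )
    for r in tests:
        if len(r.element) == 2 and r.p_increase <= alpha:
            a, b = r.element
            g.add_edge(a, b, p_increase=r.p_increase, observed_prob=r.observed)
    return g


def build_cooccurrence_graph(
    probs: ProbabilityTable,
    min_count: int = 1,
) -> nx.Graph:
    """Weighted undirected graph of raw co-occurrence probabilities.

    Edge {A, B} weighted by the joint probability P(A and B); dyads observed
    fewer than ``min_count`` times are skipped.  This is the blind,
    condition-free view of the data used for community detection.
    """
    g = nx.Graph()
    for key, count in sorted(probs.counts.items()):
        if len(key) == 1:
            g.add_node(key[0], count=count, observed_prob=count / probs.n_events)
    for key, count in sorted(probs.counts.items()):
        if len(key) == 2 and count >= min_count:
            a, b = key
            g.add_edge(a, b, weight=count / probs.n_events, joint_count=count)
    return g


# -- metrics ----------------------------------------------------------------


def graph_metrics(graph: nx.Graph | nx.DiGraph, weight: str = "weight") -> GraphMetrics:
    """Density, transitivity, degree and strength of a graph.

    Directed graphs are symmetrized first (an edge in either direction
    becomes one undirected edge), since density and transitivity are defined
    here on simple undirected graphs.  Density is existing edges over
    ``n (n - 1) / 2`` possible; transitivity is the global clustering
    coefficient, 3 x triangles / connected triples.  Strength is the *mean*
    weight of a node's edges (0 for isolated nodes); degree the plain edge
    count.
    """
    g = graph.to_undirected() if graph.is_directed() else graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    density = float(nx.density(g)) if n > 1 else 0.0
    triples = sum(d * (d - 1) // 2 for _n, d in g.degree())
    defined = n >= 3 and triples > 0
    transitivity = float(nx.transitivity(g)) if defined else 0.0
    degree = {str(u): int(d) for u, d in g.degree()}
    strength = {}
    for u in g.nodes:
        ws = [g.edges[u, v].get(weight, 1.0) for v in g.neighbors(u)]
        strength[str(u)] = float(np.mean(ws)) if ws else 0.0
    return GraphMetrics(
        n_nodes=n,
        n_edges=m,
        density=density,
        transitivity=transitivity,
        transitivity_defined=defined,
        degree=degree,
        strength=strength,
    )


def metrics_table(per_condition: Mapping[str, GraphMetrics]) -> pd.DataFrame:
    """One row per condition: nodes, edges, density, transitivity."""
    rows = [
        {"condition": c, **per_condition[c].to_row()} for c in sorted(per_condition)
    ]
    return pd.DataFrame(rows, columns=["condition", "nodes", "edges", "density", "transitivity"])


# -- modularity & communities ----------------------------------------------


def modularity(
    graph: nx.Graph,
    partition: Mapping[str, int] | CommunityPartition,
    weighted: bool = True,
) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2).

    ``e_cc`` is the fraction of total edge weight inside cluster c and
    ``a_c`` the fraction of edge endpoints attached to c.  Q is 0 for the
    one-cluster partition of any graph, near 0 when edges fall between
    clusters as a random graph would place them, and approaches (but never
    reaches) 1 for strong separation; values above 0.3 are conventionally
    read as meaningful community structure.
    """
    assignment = partition.assignment if isinstance(partition, CommunityPartition) else dict(partition)
    missing = [str(u) for u in graph.nodes if u not in assignment]
    if missing:
        raise ValueError(f"partition is missing nodes: {sorted(missing)[:5]}")
    w = "weight" if weighted else None

    def edge_w(a, b):
        return graph.edges[a, b].get(w, 1.0) if w else 1.0

    total = sum(edge_w(a, b) for a, b in graph.edges)
    if total == 0:
        return 0.0
    e = {}  # within-cluster weight fraction
    a = {}  # endpoint weight fraction
    for u, v in graph.edges:
        wgt = edge_w(u, v) / total
        cu, cv = assignment[u], assignment[v]
        a[cu] = a.get(cu, 0.0) + wgt / 2
        a[cv] = a.get(cv, 0.0) + wgt / 2
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + wgt
    return float(sum(e.get(c, 0.0) - a[c] ** 2 for c in a))


def detect_communities(graph: nx.Graph, weighted: bool = True) -> CommunityPartition:
    """Greedy agglomerative modularity maximisation (fast-greedy style).

    Starts from singleton communities and repeatedly merges the pair of
    connected communities giving the largest modularity gain, recording the
    whole merge path; the returned partition is the cut of the dendrogram
    with maximal modularity.  Ties in gain are broken by the
    lexicographically smallest pair of community representatives, so the
    result is deterministic.  Isolated nodes remain singleton communities.
    Directed or bipartite graphs are treated as plain (weighted) undirected
    graphs.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty graph")
    g = graph.to_undirected() if graph.is_directed() else graph
    nodes = sorted(str(u) for u in g.nodes)
    w = "weight" if weighted else None

    total = 0.0
    adj: dict[str, dict[str, float]] = {u: {} for u in nodes}
    for a, b in g.edges:
        if a == b:
            continue  # self-loops carry no between-unit information
        wgt = g.edges[a, b].get(w, 1.0) if w else 1.0
        a, b = str(a), str(b)
        adj[a][b] = adj[a].get(b, 0.0) + wgt
        adj[b][a] = adj[b].get(a, 0.0) + wgt
        total += wgt

    if total == 0:
        return CommunityPartition(assignment={u: i for i, u in enumerate(nodes)}, modularity=0.0)

    # community state: representative = lexicographically smallest member
    members: dict[str, list[str]] = {u: [u] for u in nodes}
    # e[c][d]: fraction of edge weight between communities c and d
    e: dict[str, dict[str, float]] = {
        u: {v: wgt / total for v, wgt in adj[u].items()} for u in nodes
    }
    deg = {u: sum(adj[u].values()) / (2 * total) for u in nodes}  # a_c = d_c / 2m

    q = -sum(d * d for d in deg.values())  # singleton partition Q (no self-loops)
    best_q = q
    best_partition = {u: [u] for u in nodes}
    within = 0.0  # sum of e_cc

    while len(members) > 1:
        best = None  # (gain, rep_pair, c1, c2)
        for c1 in sorted(members):
            for c2 in sorted(e[c1]):
                if c2 <= c1:
                    continue
                gain = 2 * (e[c1][c2] / 2 - deg[c1] * deg[c2])
                pair = (c1, c2)
                if best is None or gain > best[0] + 1e-12 or (
                    abs(gain - best[0]) <= 1e-12 and pair < best[1]
                ):
                    best = (gain, pair, c1, c2)
        if best is None:
            break  # only disconnected communities remain
        gain, _pair, c1, c2 = best
        # merge c2 into c1 (c1 < c2 lexicographically, stays representative)
        within += e[c1][c2]
        q += gain
        members[c1].extend(members.pop(c2))
        for d, wgt in e.pop(c2).items():
            if d == c1:
                continue
            e[d].pop(c2, None)
            e[c1][d] = e[c1].get(d, 0.0) + wgt
            e[d][c1] = e[c1][d]
        e[c1].pop(c2, None)
        deg[c1] += deg.pop(c2)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = {c: list(ms) for c, ms in members.items()}

    assignment: dict[str, int] = {}
    for cid, rep in enumerate(sorted(best_partition)):
        for u in best_partition[rep]:
            assignment[u] = cid
    part = CommunityPartition(assignment=assignment, modularity=float(best_q))
    return part


# -- serialization ----------------------------------------------------------


def _edge_frame(graph: nx.Graph | nx.DiGraph) -> pd.DataFrame:
    has_kind = any("kind" in graph.nodes[u] for u in graph.nodes)
    rows = []
    for a, b in graph.edges:
        row = {"source": str(a), "target": str(b)}
        if has_kind:
            row["source_kind"] = graph.nodes[a].get("kind", "")
            row["target_kind"] = graph.nodes[b].get("kind", "")
        row.update({k: v for k, v in graph.edges[a, b].items()})
        rows.append(row)
    rows.sort(key=lambda r: (r["source"], r["target"]))
    return pd.DataFrame(rows)


def export_graph(graph: nx.Graph | nx.DiGraph, fmt: str, path: str) -> None:
    """Write a graph as GraphML, edge-list CSV, or JSON (node-link).

    Exports are deterministic: nodes and edges are written in sorted order,
    at full precision, so fixed inputs give byte-stable files.  The CSV
    export holds edges only (plus a ``directed`` column and, where nodes
    carry a ``kind`` attribute, the node class of each endpoint); use
    GraphML or JSON when isolated nodes or node attributes must round-trip.
    """
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {EXPORT_FORMATS}")
    ordered = nx.DiGraph(**graph.graph) if graph.is_directed() else nx.Graph(**graph.graph)
    for u in sorted(graph.nodes, key=str):
        ordered.add_node(u, **graph.nodes[u])
    for a, b in sorted(graph.edges, key=lambda ab: (str(ab[0]), str(ab[1]))):
        ordered.add_edge(a, b, **graph.edges[a, b])
    if fmt == "graphml":
        nx.write_graphml(ordered, path)
    elif fmt == "csv":
        df = _edge_frame(ordered)
        df.insert(0, "directed", int(graph.is_directed()))
        df.to_csv(path, index=False)
    else:
        data = nx.node_link_data(ordered, edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


def read_graph(fmt: str, path: str) -> nx.Graph | nx.DiGraph:
    """Read back a graph written by :func:`export_graph`."""
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "json":
        with open(path) as fh:
            return nx.node_link_graph(json.load(fh), edges="edges")
    if fmt == "csv":
        df = pd.read_csv(path)
        directed = bool(df["directed"].iloc[0]) if len(df) else False
        g = nx.DiGraph() if directed else nx.Graph()
        for _, row in df.iterrows():
            attrs = {
                k: row[k]
                for k in df.columns
                if k not in ("source", "target", "directed", "source_kind", "target_kind")
                and pd.notna(row[k])
            }
            g.add_edge(str(row["source"]), str(row["target"]), **attrs)
        return g
    raise ValueError(f"unknown format {fmt!r}; expected one of {EXPORT_FORMATS}")
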