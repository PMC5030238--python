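"""Directed connectivity multigraph built from extracted relations.

Each extracted connectivity mention contributes one directed edge between
canonical region nodes, so parallel edges encode how often a pair is
described in the literature.  Edge betweenness — the number of all-pairs
shortest paths running along an edge, with equal-length paths splitting the
count — is computed on the collapsed undirected simple graph (the
Girvan–Newman convention), while the stored graph remains a directed
multigraph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .extraction import DirectedRelation

__all__ = [
    "RegionDegreeRow",
    "build_graph",
    "edge_betweenness",
    "top_regions",
    "top_relations",
    "assign_color_bins",
    "export_graph",
]

EXPORT_FORMATS = ("graphml", "dot", "tsv", "json")

#: low→high color ramp used for quartile bins of a mapped attribute
COLOR_RAMP = ("green", "yellow", "orange", "red")


@dataclass(frozen=True)
class RegionDegreeRow:
    region: str
    agent: int  # out-mentions
    target: int  # in-mentions

    @property
    def total(self) -> int:
        return self.agent + self.target


def build_graph(relations: Iterable[DirectedRelation]) -> nx.MultiDiGraph:
    """One node per canonical region, one directed edge per mention.

    Deduplicated relations carrying a ``mention_count`` contribute that many
    parallel edges.  Node attribute ``mention_degree`` is the incident edge
    count.
    """
    g = nx.MultiDiGraph()
    for rel in relations:
        for _ in range(max(1, rel.mention_count)):
            g.add_edge(
                rel.agent,
                rel.target,
                doc_id=rel.doc_id,
                sent_index=rel.sent_index,
                pattern=rel.pattern,
            )
    for node in g.nodes:
        g.nodes[node]["mention_degree"] = g.degree(node)
    return g


def edge_betweenness(
    g: nx.MultiDiGraph | nx.Graph, ordered_pairs: bool = False
) -> dict[tuple[str, str], float]:
    """Shortest-path counts per collapsed edge.

    Parallel edges are collapsed and direction is ignored for the path
    finding; the score is attributed to the collapsed undirected edge, keyed
    by the sorted node pair.  ``ordered_pairs=True`` counts each node pair in
    both directions (doubling every score on an undirected graph).
    """
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes)
    simple.add_edges_from((u, v) for u, v in g.edges() if u != v)
    raw = nx.edge_betweenness_centrality(simple, normalized=False)
    factor = 2.0 if ordered_pairs else 1.0
    return {tuple(sorted((u, v))): score * factor for (u, v), score in raw.items()}


def top_regions(g: nx.MultiDiGraph, k: int) -> list[RegionDegreeRow]:
    """Regions ranked by total mention degree (ties broken lexicographically)."""
    if k <= 0:
        return []
    rows = [
        RegionDegreeRow(region=node, agent=g.out_degree(node), target=g.in_degree(node))
        for node in g.nodes
    ]
    rows.sort(key=lambda r: (-r.total, r.region))
    return rows[:k]


def top_relations(g: nx.MultiDiGraph, k: int) -> list[tuple[str, str, int]]:
    """Directed region pairs ranked by mention count."""
    if k <= 0:
        return []
    counts: dict[tuple[str, str], int] = {}
    for u, v in g.edges():
        counts[(u, v)] = counts.get((u, v), 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(u, v, n) for (u, v), n in ranked[:k]]


def assign_color_bins(values: dict) -> dict:
    """Map each value to a color by empirical quartile (green→yellow→orange→red)."""
    if not values:
        return {}
    ordered = sorted(values.values())

    def bin_of(x: float) -> str:
        rank = sum(1 for v in ordered if v <= x) / len(ordered)
        if rank <= 0.25:
            return COLOR_RAMP[0]
        if rank <= 0.5:
            return COLOR_RAMP[1]
        if rank <= 0.75:
            return COLOR_RAMP[2]
        return COLOR_RAMP[3]

    return {key: bin_of(v) for key, v in values.items()}


def _annotate(g: nx.MultiDiGraph, betweenness: Optional[dict]) -> nx.MultiDiGraph:
    g = g.copy()
    node_colors = assign_color_bins(
        {n: g.nodes[n].get("mention_degree", g.degree(n)) for n in g.nodes}
    )
    for node, color in node_colors.items():
        g.nodes[node]["color"] = color
    if betweenness:
        edge_colors = assign_color_bins(betweenness)
        for u, v, key in g.edges(keys=True):
            pair = tuple(sorted((u, v)))
            if pair in betweenness:
                g.edges[u, v, key]["betweenness"] = betweenness[pair]
                g.edges[u, v, key]["color"] = edge_colors[pair]
    return g


def export_graph(
    g: nx.MultiDiGraph,
    fmt: str,
    path: str | Path,
    betweenness: Optional[dict] = None,
) -> None:
    """Write the annotated graph as GraphML, DOT, a TSV edge list, or JSON."""
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r} (use one of {EXPORT_FORMATS})")
    annotated = _annotate(g, betweenness)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(annotated, path)
    elif fmt == "dot":
        path.write_text(_to_dot(annotated), encoding="utf-8")
    elif fmt == "tsv":
        lines = ["agent\ttarget\tpattern\tdoc_id\tsentence_idx\tbetweenness"]
        for u, v, data in annotated.edges(data=True):
            lines.append(
                f"{u}\t{v}\t{data.get('pattern', '')}\t{data.get('doc_id', '')}"
                f"\t{data.get('sent_index', '')}\t{data.get('betweenness', '')}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "json":
        data = nx.node_link_data(annotated, edges="links")
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")


def _quote(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def _to_dot(g: nx.MultiDiGraph) -> str:
    lines = ["digraph connectivity {"]
    for node, data in g.nodes(data=True):
        attrs = f' [color={data["color"]}]' if "color" in data else ""
        lines.append(f"  {_quote(node)}{attrs};")
    for u, v, data in g.edges(data=True):
        attrs = []
        if "color" in data:
            attrs.append(f"color={data['color']}")
        if "betweenness" in data:
            attrs.append(f'betweenness="{data["betweenness"]}"')
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(u)} -> {_quote(v)}{suffix};")
    lines.append("}")
    return "\n".join(lines) + "\n"
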