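"""Independent brute-force oracles used to cross-check the implementation.

These are naive transliterations of the rule descriptions, written as flat
set comprehensions over the edge list (no dispatch, no shared helpers), and
an explicit all-shortest-paths enumeration for edge betweenness.  They stay
deliberately separate from the library code paths they validate.
"""

from __future__ import annotations

import itertools

import networkx as nx

SUBJ = {"nsubj", "nsubjpass", "xsubj", "nn"}


def _span(tokens, kw_pos):
    uniq = {pos: surface for surface, pos in tokens if pos != kw_pos}
    return tuple((uniq[p], p) for p in sorted(uniq))


def oracle_subject_group(edges, kw):
    pos = kw[1]
    out = []
    out += [e.dep for e in edges if e.label in SUBJ and e.gov[1] == pos]
    out += [
        x.dep
        for e in edges
        if e.label in SUBJ and e.gov[1] == pos
        for x in edges
        if x.gov[1] == e.dep[1]
    ]
    preps = [
        p
        for e in edges
        if e.label in SUBJ and e.dep[1] == pos
        for p in edges
        if p.label.startswith("prep") and p.gov[1] == e.gov[1]
    ]
    out += [p.dep for p in preps]
    out += [
        x.dep
        for p in preps
        for x in edges
        if x.label in {"amod", "nn"} and x.gov[1] == p.dep[1]
    ]
    return _span(out, pos)


def oracle_dobj_nsubj(edges, kw):
    pos = kw[1]
    subs = [
        n.dep
        for d in edges
        if d.label == "dobj" and d.dep[1] == pos
        for n in edges
        if n.label == "nsubj" and n.gov[1] == d.gov[1]
    ]
    out = list(subs)
    mods = [
        m
        for s in subs
        for m in edges
        if m.gov[1] == s[1]
        and (m.label in {"amod", "nn"} or m.label.startswith("prep"))
    ]
    out += [m.dep for m in mods]
    out += [
        x.dep
        for m in mods
        if m.label.startswith("prep")
        for x in edges
        if x.label in {"amod", "nn"} and x.gov[1] == m.dep[1]
    ]
    return _span(out, pos)


def oracle_vmod(edges, kw):
    pos = kw[1]
    heads = [v.gov for v in edges if v.label == "vmod" and v.dep[1] == pos]
    out = list(heads)
    out += [
        x.dep
        for h in heads
        for x in edges
        if x.label in {"amod", "nn"} and x.gov[1] == h[1]
    ]
    return _span(out, pos)


def oracle_second_dependent(edges, kw):
    for fn in (oracle_subject_group, oracle_dobj_nsubj, oracle_vmod):
        span = fn(edges, kw)
        if span:
            return span
    return ()


def oracle_edge_betweenness(g: nx.Graph, ordered_pairs: bool = False):
    """Explicit enumeration of all shortest paths between node pairs."""
    scores = {tuple(sorted(e)): 0.0 for e in g.edges()}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        weight = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[tuple(sorted((u, v)))] += weight
    if ordered_pairs:
        scores = {k: 2.0 * v for k, v in scores.items()}
    return scores
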