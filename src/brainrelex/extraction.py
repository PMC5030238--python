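"""Orchestration of trigger patterns, syntactic rules and the dictionary
into directed connectivity relations.

For every trigger match in a candidate sentence the argument following the
pattern is read off the constituency parse (first NP after the trigger, plus
a trailing "including"-PP) and the other argument off the dependency parse
(three rule groups).  Dual-slot patterns take both arguments from their
preposition slots instead.  Both argument texts are normalized through the
brain-region dictionary; each (agent region, target region) combination
yields one directed relation, with roles read from the pattern and flipped
in passive voice.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus_io import Document, Sentence
from .lexicon import Dictionary, RegionMatch, match_text
from .patterns import (
    AGENT,
    TARGET,
    PatternDef,
    PatternMatch,
    find_pattern_matches,
)
from .syntax import (
    CandidateSpan,
    ConstituencyTree,
    DependencyEdge,
    detect_voice,
    extend_with_including_pp,
    first_np_after,
    second_dependent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedRelation",
    "extract_from_sentence",
    "extract_document",
    "assign_direction",
    "dedup_document",
    "write_relations_tsv",
    "read_relations_tsv",
]

_TSV_COLUMNS = (
    "doc_id", "sentence_idx", "agent", "direction", "target", "pattern",
    "agent_match_kind", "target_match_kind", "sentence_text",
)


@dataclass(frozen=True)
class DirectedRelation:
    """A directed connectivity statement: agent region → target region."""

    agent: str
    target: str
    doc_id: str
    sent_index: int
    pattern: str
    agent_surface: str = ""
    target_surface: str = ""
    agent_kind: str = "full"
    target_kind: str = "full"
    agent_first: bool = True  # agent mention precedes target mention in text
    mention_count: int = 1
    sentence_text: str = ""
    unannotated_candidate: bool = False

    def pair(self) -> tuple[str, str]:
        return (self.agent, self.target)


def assign_direction(pattern: PatternDef, voice: str = "active") -> dict[str, str]:
    """Slot→role assignment for a pattern, flipped in passive voice.

    Returns a mapping with keys ``after`` (text following the pattern) and
    ``other`` (the dependency-derived argument); for dual-slot patterns the
    key ``slot`` (mid-pattern preposition slot) replaces ``other``.
    """
    if voice not in ("active", "passive"):
        raise ValueError(f"unknown voice {voice!r}")
    if pattern.slots == "dual":
        return {"after": pattern.role_after, "slot": pattern.role_slot}
    after, other = pattern.role_after, pattern.role_other
    if voice == "passive" and pattern.passive_flips:
        after, other = other, after
    return {"after": after, "other": other}


def _span_char_start(sentence: Sentence, span: CandidateSpan) -> int:
    first_pos = span.positions[0]
    for tok in sentence.tokens:
        if tok.position == first_pos:
            return tok.start
    return 0


def _slot_span(sentence: Sentence, match: PatternMatch) -> Optional[CandidateSpan]:
    if match.slot_span is None:
        return None
    tokens = sentence.tokens_in_char_span(*match.slot_span)
    tokens = [
        t
        for t in tokens
        if any(c.isalnum() for c in t.surface) or t.surface in (",", ";")
    ]
    if not tokens:
        return None
    return CandidateSpan(
        tuple((t.surface, t.position) for t in tokens), source="dual_slot"
    )


def _np_after(
    sentence: Sentence, tree: ConstituencyTree, match: PatternMatch
) -> Optional[CandidateSpan]:
    span = first_np_after(tree, match.last_position)
    if span is None:
        return None
    return extend_with_including_pp(tree, span)


def _relations_for_spans(
    sentence: Sentence,
    match: PatternMatch,
    agent_span: CandidateSpan,
    target_span: CandidateSpan,
    dictionary: Dictionary,
) -> list[DirectedRelation]:
    agents = match_text(agent_span.text, dictionary)
    targets = match_text(target_span.text, dictionary)
    if not agents or not targets:
        logger.debug(
            "no dictionary hit for %r in %s.s%d",
            (agent_span.text, target_span.text), sentence.doc_id, sentence.index,
        )
        return []
    agent_base = _span_char_start(sentence, agent_span)
    target_base = _span_char_start(sentence, target_span)
    out: list[DirectedRelation] = []
    for agent in _unique_by_canonical(agents):
        for target in _unique_by_canonical(targets):
            if agent.canonical == target.canonical:
                continue  # self-relations are artifacts, suppressed
            out.append(
                DirectedRelation(
                    agent=agent.canonical,
                    target=target.canonical,
                    doc_id=sentence.doc_id,
                    sent_index=sentence.index,
                    pattern=match.name,
                    agent_surface=agent.surface,
                    target_surface=target.surface,
                    agent_kind=agent.kind,
                    target_kind=target.kind,
                    agent_first=(agent_base + agent.start)
                    <= (target_base + target.start),
                    sentence_text=sentence.text,
                )
            )
    return out


def _unique_by_canonical(matches: Sequence[RegionMatch]) -> list[RegionMatch]:
    seen: dict[str, RegionMatch] = {}
    for m in matches:
        if m.canonical not in seen or (
            m.kind == "full" and seen[m.canonical].kind != "full"
        ):
            seen[m.canonical] = m
    return list(seen.values())


def extract_from_sentence(
    sentence: Sentence,
    tree: Optional[ConstituencyTree],
    edges: Optional[Sequence[DependencyEdge]],
    dictionary: Dictionary,
    patterns: Optional[Sequence[PatternDef]] = None,
) -> list[DirectedRelation]:
    """Extract all directed relations from one parsed sentence.

    Requires the constituency tree for the post-pattern argument and the
    dependency edges for the other one (dual-slot patterns need only the
    tree).  Missing parses raise ValueError; a trigger whose arguments find
    no dictionary region yields no relation.
    """
    matches = find_pattern_matches(sentence, patterns)
    relations: list[DirectedRelation] = []
    for match in matches:
        if tree is None:
            raise ValueError(
                f"missing constituency parse for {sentence.doc_id}.s{sentence.index}"
            )
        after_span = _np_after(sentence, tree, match)
        if after_span is None:
            continue
        if match.pattern.slots == "dual":
            slot_span = _slot_span(sentence, match)
            if slot_span is None:
                continue
            roles = assign_direction(match.pattern)
            spans = {roles["after"]: after_span, roles["slot"]: slot_span}
        else:
            if edges is None:
                raise ValueError(
                    f"missing dependency parse for {sentence.doc_id}.s{sentence.index}"
                )
            other_span = second_dependent(edges, match.keyword)
            if not other_span:
                continue
            voice = detect_voice(edges, match.keyword)
            roles = assign_direction(match.pattern, voice)
            spans = {roles["after"]: after_span, roles["other"]: other_span}
        relations.extend(
            _relations_for_spans(
                sentence, match, spans[AGENT], spans[TARGET], dictionary
            )
        )
    return _dedup_sentence(relations)


def _dedup_sentence(relations: list[DirectedRelation]) -> list[DirectedRelation]:
    """Merge duplicate (agent, target) pairs produced by co-occurring patterns."""
    seen: dict[tuple[str, str], DirectedRelation] = {}
    for rel in relations:
        seen.setdefault(rel.pair(), rel)
    return list(seen.values())


def extract_document(
    document: Document,
    provider,
    dictionary: Dictionary,
    patterns: Optional[Sequence[PatternDef]] = None,
) -> list[DirectedRelation]:
    """Run sentence-level extraction over a document via a parse provider.

    ``provider`` exposes ``constituency(sentence)`` and
    ``dependencies(sentence)`` (the contract of
    :class:`~brainrelex.corpus_io.FixtureParseProvider`).  Sentences without
    any trigger are skipped before asking for parses.
    """
    out: list[DirectedRelation] = []
    for sentence in document.sentences:
        if not find_pattern_matches(sentence, patterns):
            continue
        tree = provider.constituency(sentence)
        edges = provider.dependencies(sentence)
        out.extend(
            extract_from_sentence(sentence, tree, edges, dictionary, patterns)
        )
    return out


def dedup_document(relations: Iterable[DirectedRelation]) -> list[DirectedRelation]:
    """One relation per directed (agent, target) pair per document.

    The first occurrence is kept as representative and its ``mention_count``
    accumulates the merged mentions, preserving the information needed for
    edge multiplicities in the connectivity graph.
    """
    kept: dict[tuple[str, str, str], DirectedRelation] = {}
    for rel in relations:
        key = (rel.doc_id, rel.agent, rel.target)
        if key in kept:
            kept[key] = replace(
                kept[key], mention_count=kept[key].mention_count + rel.mention_count
            )
        else:
            kept[key] = rel
    return list(kept.values())


def write_relations_tsv(relations: Iterable[DirectedRelation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for rel in relations:
            writer.writerow(
                (
                    rel.doc_id, rel.sent_index, rel.agent, "->", rel.target,
                    rel.pattern, rel.agent_kind, rel.target_kind, rel.sentence_text,
                )
            )


def read_relations_tsv(path: str | Path) -> list[DirectedRelation]:
    out: list[DirectedRelation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                DirectedRelation(
                    agent=row["agent"],
                    target=row["target"],
                    doc_id=row["doc_id"],
                    sent_index=int(row["sentence_idx"]),
                    pattern=row["pattern"],
                    agent_kind=row.get("agent_match_kind", "full"),
                    target_kind=row.get("target_match_kind", "full"),
                    sentence_text=row.get("sentence_text", ""),
                )
            )
    return out
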