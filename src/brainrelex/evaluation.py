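"""Scoring of predicted relations against gold annotations.

Three evaluation modes mirror how literature-mined relations are usually
audited.  *Strict* counts a predicted pair as correct only when both of its
region strings equal the gold mentions; *lenient* also accepts partial
(word-boundary substring) matches, e.g. "thalamus" against the annotated
"dorsal midline thalamus"; *nlp* additionally credits dictionary-validated
predictions explicitly flagged as unannotated candidates — pairs the system
located with both regions in the dictionary but that the annotators chose
not to mark.

Gold pairs are matched orderlessly (corpus annotations record an undirected
interaction); directionality is scored separately, over the true-positive
relations whose gold annotation carries a direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .corpus_io import GoldCorpus
from .extraction import DirectedRelation
from .lexicon import classify_against_gold

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "DirectionEval",
    "GoldRelation",
    "MatchedRelation",
    "gold_relations",
    "score",
    "f_measure",
    "direction_accuracy",
    "majority_direction_baseline",
    "recall_ceiling",
    "pct",
]

MODES = ("strict", "lenient", "nlp")


def pct(value: float, places: int = 2) -> float:
    """Round a percentage half-up to the printed precision."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GoldRelation:
    """A gold pairwise relation localized to a document sentence."""

    doc_id: str
    sent_index: int
    mention1: str
    mention2: str
    direction: Optional[str] = None  # "m1_to_m2" | "m2_to_m1" | None


@dataclass(frozen=True)
class MatchedRelation:
    """A predicted relation aligned with a gold relation."""

    predicted: DirectedRelation
    gold: GoldRelation
    agent_side: str  # which gold mention ("m1"|"m2") the predicted agent matched
    quality: str  # "full" | "partial"

    @property
    def direction_correct(self) -> Optional[bool]:
        if self.gold.direction is None:
            return None
        expected_agent = "m1" if self.gold.direction == "m1_to_m2" else "m2"
        return self.agent_side == expected_agent


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    mode: str
    matches: list[MatchedRelation] = field(default_factory=list)
    zero_retrieved: bool = False

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 0.0
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def f(self) -> float:
        return f_measure(self.precision, self.recall)

    def rounded(self) -> tuple[float, float, float]:
        return pct(self.precision), pct(self.recall), pct(self.f)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, mode: str = "strict") -> "EvalResult":
        return cls(tp=tp, fp=fp, fn=fn, mode=mode, zero_retrieved=(tp + fp == 0))


@dataclass
class DirectionEval:
    examined: int
    correct: int

    @property
    def accuracy(self) -> float:
        return 100.0 * self.correct / self.examined if self.examined else 0.0


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def gold_relations(corpus: GoldCorpus) -> list[GoldRelation]:
    """Flatten a gold corpus into localized pairwise relations.

    Only pairs with ``interaction="True"`` become gold relations.  Sentence
    ids of the form ``<doc>.s<k>`` supply the sentence index.
    """
    out: list[GoldRelation] = []
    for doc in corpus.documents:
        for idx, sent in enumerate(doc.sentences):
            sent_index = idx
            if ".s" in sent.id:
                tail = sent.id.rsplit(".s", 1)[1]
                if tail.isdigit():
                    sent_index = int(tail)
            for pair in sent.pairs:
                if not pair.interaction:
                    continue
                out.append(
                    GoldRelation(
                        doc_id=doc.id,
                        sent_index=sent_index,
                        mention1=sent.entity_by_id(pair.e1).text,
                        mention2=sent.entity_by_id(pair.e2).text,
                        direction={
                            "e1_to_e2": "m1_to_m2",
                            "e2_to_e1": "m2_to_m1",
                        }.get(pair.direction or ""),
                    )
                )
    return out


def _pair_quality(pred: DirectedRelation, gold: GoldRelation) -> Optional[MatchedRelation]:
    """Best orderless alignment of a predicted pair against a gold pair."""
    best: Optional[MatchedRelation] = None
    for agent_side, (gm_a, gm_t) in (
        ("m1", (gold.mention1, gold.mention2)),
        ("m2", (gold.mention2, gold.mention1)),
    ):
        ka = classify_against_gold(pred.agent_surface or pred.agent, gm_a)
        kt = classify_against_gold(pred.target_surface or pred.target, gm_t)
        if "miss" in (ka, kt):
            continue
        quality = "full" if (ka, kt) == ("full", "full") else "partial"
        cand = MatchedRelation(pred, gold, agent_side, quality)
        if best is None or (quality == "full" and best.quality != "full"):
            best = cand
    return best


def score(
    predicted: Sequence[DirectedRelation],
    gold: Sequence[GoldRelation] | GoldCorpus,
    mode: str = "strict",
) -> EvalResult:
    """Score predictions against gold pairwise relations.

    Alignment is greedy in two passes within each (document, sentence)
    group: full-quality alignments first, then — outside strict mode —
    partial ones, so that the strict true positives are always a subset of
    the lenient ones.  False negatives are the gold relations left
    unmatched; in nlp mode flagged unannotated candidates count as true
    positives and are subtracted from the false-negative budget, matching
    the usual bookkeeping for relations the annotators skipped.
    """
    if mode not in MODES:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if isinstance(gold, GoldCorpus):
        gold = gold_relations(gold)
    n_gold = len(gold)
    free_gold: dict[tuple[str, int], list[GoldRelation]] = {}
    for g in gold:
        free_gold.setdefault((g.doc_id, g.sent_index), []).append(g)

    matches: list[MatchedRelation] = []
    unmatched_preds: list[DirectedRelation] = list(predicted)

    def run_pass(quality_wanted: str) -> None:
        still: list[DirectedRelation] = []
        for pred in unmatched_preds:
            pool = free_gold.get((pred.doc_id, pred.sent_index), [])
            chosen = None
            for g in pool:
                m = _pair_quality(pred, g)
                if m is not None and m.quality == quality_wanted:
                    chosen = m
                    break
            if chosen is None:
                still.append(pred)
            else:
                matches.append(chosen)
                pool.remove(chosen.gold)
        unmatched_preds[:] = still

    run_pass("full")
    if mode in ("lenient", "nlp"):
        run_pass("partial")

    tp = len(matches)
    if mode == "nlp":
        flagged = [p for p in unmatched_preds if p.unannotated_candidate]
        tp += len(flagged)
        unmatched_preds = [p for p in unmatched_preds if not p.unannotated_candidate]
    fp = len(unmatched_preds)
    fn = max(0, n_gold - tp)
    return EvalResult(
        tp=tp, fp=fp, fn=fn, mode=mode, matches=matches,
        zero_retrieved=(tp + fp == 0),
    )


def direction_accuracy(
    matches: Iterable[MatchedRelation],
) -> DirectionEval:
    """Direction accuracy over true-positive relations with a gold direction.

    Relations whose gold annotation lacks a direction are excluded with a
    warning; false positives never enter the computation.
    """
    examined = 0
    correct = 0
    for m in matches:
        verdict = m.direction_correct
        if verdict is None:
            logger.warning(
                "gold relation %s/%s has no direction; excluded from accuracy",
                m.gold.doc_id, (m.gold.mention1, m.gold.mention2),
            )
            continue
        examined += 1
        correct += int(verdict)
    return DirectionEval(examined=examined, correct=correct)


def majority_direction_baseline(
    true_positives: Sequence[DirectedRelation],
) -> float:
    """Accuracy (percent) of always predicting first mention → second mention.

    A true relation is counted correct for the baseline when its agent is
    the textually first of the two mentions.
    """
    if not true_positives:
        return 0.0
    forward = sum(1 for rel in true_positives if rel.agent_first)
    return 100.0 * forward / len(true_positives)


def recall_ceiling(n_gold_in_trigger_sentences: int, n_gold_total: int) -> float:
    """Upper bound on recall given trigger coverage of the gold relations."""
    if n_gold_total == 0:
        return 0.0
    return 100.0 * n_gold_in_trigger_sentences / n_gold_total
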