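"""Scoring modes, metric identities, direction accuracy and baselines."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from brainrelex.evaluation import (
    DirectionEval,
    EvalResult,
    GoldRelation,
    f_measure,
    majority_direction_baseline,
    pct,
    recall_ceiling,
    score,
)
from brainrelex.extraction import DirectedRelation


def _pred(agent, target, doc="d", sent=0, a_surf=None, t_surf=None, flag=False,
          agent_first=True):
    return DirectedRelation(
        agent=agent, target=target, doc_id=doc, sent_index=sent,
        pattern="project to",
        agent_surface=a_surf if a_surf is not None else agent,
        target_surface=t_surf if t_surf is not None else target,
        unannotated_candidate=flag, agent_first=agent_first,
    )


class TestFMeasure:
    def test_printed_value(self):
        # the harmonic mean of 76.94% precision and 14.59% recall
        assert pct(f_measure(76.94, 14.59)) == 24.53

    def test_symmetry_fixed_point(self):
        for x in (0.1, 33.3, 100.0):
            assert f_measure(x, x) == pytest.approx(x)

    def test_degenerate(self):
        assert f_measure(100.0, 0.0) == 0.0
        assert f_measure(0.0, 0.0) == 0.0

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_min_max(self, p, r):
        if p + r == 0:
            return
        f = f_measure(p, r)
        assert min(p, r) - 1e-9 <= f <= max(p, r) + 1e-9


class TestCountIdentities:
    def test_strict_bookkeeping(self):
        # 161 retrieved, 107 full matches, 322 gold
        result = EvalResult.from_counts(tp=107, fp=161 - 107, fn=322 - 107)
        precision, recall, f = result.rounded()
        assert recall == 33.23
        assert precision == 66.46  # 107/161; see methods note on rounding
        assert f == 44.31

    def test_lenient_bookkeeping(self):
        result = EvalResult.from_counts(tp=122, fp=161 - 122, fn=322 - 122)
        assert result.rounded() == (75.78, 37.89, 50.52)

    def test_nlp_bookkeeping(self):
        result = EvalResult.from_counts(tp=141, fp=161 - 141, fn=322 - 141)
        assert result.rounded() == (87.58, 43.79, 58.39)


class TestScore:
    def _gold(self):
        return [
            GoldRelation("d", 0, "dorsal midline thalamus", "SCN"),
            GoldRelation("d", 1, "PVT", "amygdala"),
        ]

    def test_perfect_predictions(self):
        preds = [
            _pred("X", "Y", sent=0, a_surf="dorsal midline thalamus", t_surf="SCN"),
            _pred("X", "Y", sent=1, a_surf="PVT", t_surf="amygdala"),
        ]
        result = score(preds, self._gold(), mode="strict")
        assert (result.tp, result.fp, result.fn) == (2, 0, 0)
        assert result.rounded() == (100.0, 100.0, 100.0)

    def test_partial_counts_only_in_lenient(self):
        preds = [_pred("X", "Y", sent=0, a_surf="thalamus", t_surf="SCN")]
        strict = score(preds, self._gold(), mode="strict")
        lenient = score(preds, self._gold(), mode="lenient")
        assert (strict.tp, strict.fp) == (0, 1)
        assert (lenient.tp, lenient.fp) == (1, 0)

    def test_orderless_gold_matching(self):
        preds = [_pred("X", "Y", sent=0, a_surf="SCN", t_surf="dorsal midline thalamus")]
        assert score(preds, self._gold(), mode="strict").tp == 1

    def test_empty_predictions_degenerate(self):
        result = score([], self._gold(), mode="strict")
        assert result.zero_retrieved
        assert result.rounded() == (0.0, 0.0, 0.0)

    def test_nlp_mode_credits_flagged_candidates(self):
        preds = [_pred("PVT", "PFC", sent=5, flag=True)]
        lenient = score(preds, self._gold(), mode="lenient")
        nlp = score(preds, self._gold(), mode="nlp")
        assert (lenient.tp, lenient.fp) == (0, 1)
        assert (nlp.tp, nlp.fp) == (1, 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            score([], [], mode="fuzzy")


_VOCAB = ("dorsal midline thalamus", "midline thalamus", "SCN", "amygdala", "PVT")


@given(st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_mode_monotonicity_on_random_sets(data):
    """TP/precision/recall never decrease from strict to lenient to nlp."""
    rng = random.Random(data.draw(st.integers(0, 10_000)))
    gold = [
        GoldRelation("d", s, rng.choice(_VOCAB), rng.choice(_VOCAB))
        for s in range(rng.randint(0, 5))
    ]
    preds = []
    for _ in range(rng.randint(0, 6)):
        mention = rng.choice(_VOCAB)
        surf = rng.choice((mention, mention.split()[-1], "cerebellum"))
        preds.append(
            _pred("A", "B", sent=rng.randint(0, 5), a_surf=surf,
                  t_surf=rng.choice(_VOCAB), flag=rng.random() < 0.3)
        )
    results = {m: score(preds, gold, mode=m) for m in ("strict", "lenient", "nlp")}
    assert results["strict"].tp <= results["lenient"].tp <= results["nlp"].tp
    assert results["strict"].recall <= results["lenient"].recall <= results["nlp"].recall
    assert results["strict"].precision <= results["lenient"].precision <= results["nlp"].precision


class TestDirection:
    def test_printed_accuracy(self):
        assert pct(DirectionEval(examined=122, correct=119).accuracy) == 97.54

    def test_all_correct(self):
        assert DirectionEval(examined=7, correct=7).accuracy == 100.0

    def test_flipped_role_table_scores_zero(self, corpus50, fixture_dict):
        """With agent/target deliberately swapped, no direction is correct."""
        from brainrelex import extraction, evaluation

        provider = corpus50.provider()
        rels = []
        for doc in corpus50.documents[:10]:
            for rel in extraction.extract_document(doc, provider, fixture_dict):
                rels.append(
                    DirectedRelation(
                        agent=rel.target, target=rel.agent, doc_id=rel.doc_id,
                        sent_index=rel.sent_index, pattern=rel.pattern,
                        agent_surface=rel.target_surface,
                        target_surface=rel.agent_surface,
                    )
                )
        result = score(rels, evaluation.gold_relations(corpus50.gold), mode="strict")
        assert result.tp > 0  # pairs still match orderlessly
        acc = evaluation.direction_accuracy(result.matches)
        assert acc.examined == result.tp and acc.correct == 0

    def test_missing_gold_direction_excluded(self):
        gold = [GoldRelation("d", 0, "PVT", "SCN", direction=None)]
        preds = [_pred("X", "Y", a_surf="PVT", t_surf="SCN")]
        result = score(preds, gold, mode="strict")
        from brainrelex.evaluation import direction_accuracy

        assert direction_accuracy(result.matches).examined == 0


class TestMajorityBaseline:
    def test_printed_value(self):
        rels = [_pred("A", "B", agent_first=(i < 205)) for i in range(277)]
        assert pct(majority_direction_baseline(rels)) == 74.01

    def test_all_forward(self):
        rels = [_pred("A", "B", agent_first=True) for _ in range(5)]
        assert majority_direction_baseline(rels) == 100.0

    def test_brute_force_recount(self):
        rng = random.Random(11)
        rels = [_pred("A", "B", agent_first=rng.random() < 0.7) for _ in range(200)]
        manual = 100.0 * sum(r.agent_first for r in rels) / len(rels)
        assert majority_direction_baseline(rels) == pytest.approx(manual)

    def test_empty(self):
        assert majority_direction_baseline([]) == 0.0


def test_recall_ceiling_matches_trigger_coverage():
    assert pct(recall_ceiling(225, 322)) == 69.88
    assert recall_ceiling(0, 10) == 0.0
    assert recall_ceiling(5, 0) == 0.0
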