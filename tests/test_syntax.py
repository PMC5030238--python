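"""Constituency/dependency rules, worked examples and oracle equivalence."""

import random

import pytest

from brainrelex.examples import DEPENDENCY_RULE_EXAMPLES, NP_AFTER_EXAMPLE
from brainrelex.syntax import (
    CandidateSpan,
    DependencyEdge,
    detect_voice,
    extend_with_including_pp,
    first_np_after,
    map_dependency_labels,
    parse_bracketed_tree,
    parse_dependency_triples,
    rule_dobj_nsubj,
    rule_subject_group,
    rule_vmod,
    second_dependent,
)

from oracles import oracle_second_dependent

_RULES = {
    "subj_group": rule_subject_group,
    "dobj_nsubj": rule_dobj_nsubj,
    "vmod": rule_vmod,
}


class TestWorkedExamples:
    @pytest.mark.parametrize("ex", DEPENDENCY_RULE_EXAMPLES, ids=lambda e: e.name)
    def test_rule_groups_reproduce_printed_candidates(self, ex):
        edges = parse_dependency_triples(ex.deps)
        span = second_dependent(edges, ex.keyword)
        assert span.tokens == ex.expected
        assert span.source == ex.rule
        # the specific rule alone agrees with the dispatcher
        assert _RULES[ex.rule](edges, ex.keyword).tokens == ex.expected

    def test_first_np_after_pa_in_rats(self):
        tree = parse_bracketed_tree(NP_AFTER_EXAMPLE.tree)
        # trigger "project densely to" ends at token 10
        span = first_np_after(tree, 10)
        assert span.text == "Pa in rats"
        assert span.positions == (11, 12, 13)


class TestFirstNpAfter:
    def test_hand_computed_preorder(self):
        tree = parse_bracketed_tree(
            "(S (NP (NN A)) (VP (VBZ projects) (PP (TO to) (NP (DT the) (NN amygdala)))))"
        )
        span = first_np_after(tree, 2)
        assert span.text == "the amygdala"

    def test_no_np_after_pattern(self):
        tree = parse_bracketed_tree("(S (NP (NN A)) (VP (VBZ projects)))")
        assert first_np_after(tree, 2) is None

    def test_outermost_np_wins(self):
        tree = parse_bracketed_tree(
            "(S (VBZ innervates) (NP (NP (DT the) (NN PFC)) (CC and) (NP (NN NAS))))"
        )
        span = first_np_after(tree, 1)
        assert span.text == "the PFC and NAS"


class TestIncludingPp:
    def test_pp_with_including_extends_span(self):
        tree = parse_bracketed_tree(
            "(VP (VBZ projects) (PP (TO to) (NP (JJ limbic) (NNS structures)) "
            "(PP (VBG including) (NP (DT the) (NN amygdala)))))"
        )
        span = first_np_after(tree, 2)
        assert span.text == "limbic structures"
        extended = extend_with_including_pp(tree, span)
        assert extended.text == "limbic structures including the amygdala"

    def test_pp_without_keyword_unchanged(self):
        tree = parse_bracketed_tree(
            "(VP (VB project) (PP (TO to) (NP (NNP Pa)) (PP (IN in) (NP (NNS rats)))))"
        )
        span = first_np_after(tree, 2)
        assert extend_with_including_pp(tree, span).tokens == span.tokens

    def test_np_without_sibling_unchanged(self):
        tree = parse_bracketed_tree("(S (NP (NN amygdala)))")
        span = first_np_after(tree, 0)
        assert extend_with_including_pp(tree, span).tokens == span.tokens


class TestRuleEdgeCases:
    def test_keyword_absent_from_all_relations(self):
        edges = parse_dependency_triples("nsubj(projects-5, nucleus-2)")
        assert not second_dependent(edges, ("innervates", 9))

    def test_dobj_without_sibling_nsubj_empty(self):
        edges = parse_dependency_triples("dobj(revealed-10, projections-12)")
        assert not rule_dobj_nsubj(edges, ("projections", 12))

    def test_vmod_keyword_as_governor_empty(self):
        edges = parse_dependency_triples("vmod(projecting-31, neurons-30)")
        assert not rule_vmod(edges, ("projecting", 31))

    def test_span_never_contains_keyword(self):
        edges = parse_dependency_triples(
            "nsubj(projects-5, projects-5)\nnn(projects-5, orexin-4)"
        )
        span = second_dependent(edges, ("projects", 5))
        assert 5 not in span.positions

    def test_voice_detection(self):
        passive = parse_dependency_triples("nsubjpass(innervated-11, aPVT-8)")
        active = parse_dependency_triples("nsubj(innervates-3, PVT-2)")
        assert detect_voice(passive, ("innervated", 11)) == "passive"
        assert detect_voice(active, ("innervates", 3)) == "active"


_LABELS = (
    "nsubj", "nsubjpass", "xsubj", "nn", "dobj", "vmod",
    "amod", "det", "prep_into", "prep_from", "appos",
)


def _random_edges(rng: random.Random):
    n_tokens = rng.randint(2, 10)
    edges = []
    for _ in range(rng.randint(0, 8)):
        g, d = rng.sample(range(1, n_tokens + 1), 2)  # dependencies never self-loop
        edges.append(DependencyEdge(rng.choice(_LABELS), (f"w{g}", g), (f"w{d}", d)))
    kw_pos = rng.randint(1, n_tokens)
    return edges, (f"w{kw_pos}", kw_pos)


@pytest.mark.parametrize("seed", range(20))
def test_rule_groups_match_brute_force_oracle(seed):
    """Equivalence with a naive enumeration oracle on random small edge sets."""
    rng = random.Random(seed)
    for _ in range(200):
        edges, keyword = _random_edges(rng)
        got = second_dependent(edges, keyword)
        expected = oracle_second_dependent(edges, keyword)
        assert got.tokens == tuple(expected), (edges, keyword)


class TestLabelMapping:
    def test_ud_compound_becomes_nn(self):
        edges = [DependencyEdge("compound", ("nucleus", 3), ("trigeminal", 2))]
        (mapped,) = map_dependency_labels(edges)
        assert mapped.label == "nn"

    def test_nmod_case_collapses_to_prep(self):
        edges = [
            DependencyEdge("nmod", ("injection", 4), ("thalamus", 9)),
            DependencyEdge("case", ("thalamus", 9), ("into", 5)),
        ]
        (mapped,) = map_dependency_labels(edges)
        assert mapped.label == "prep_into"

    def test_empty_and_passthrough(self):
        assert map_dependency_labels([]) == []
        edges = [DependencyEdge("punct", ("a", 1), ("b", 2))]
        assert map_dependency_labels(edges)[0].label == "punct"

    def test_nsubj_pass_maps(self):
        edges = [DependencyEdge("nsubj:pass", ("innervated", 5), ("PVT", 2))]
        assert map_dependency_labels(edges)[0].label == "nsubjpass"


class TestTreeParsing:
    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            parse_bracketed_tree("(S (NP (NN A))")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_bracketed_tree("   ")

    def test_leaf_positions_strictly_increasing(self):
        tree = parse_bracketed_tree(NP_AFTER_EXAMPLE.tree)
        positions = [leaf.position for leaf in tree.leaves()]
        assert positions == sorted(positions) == list(range(1, len(positions) + 1))
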