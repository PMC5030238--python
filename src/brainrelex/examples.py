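"""Hand-checked worked examples: sentences with transcribed parses.

Each example bundles a sentence from the neuroanatomical literature, its
constituency and/or dependency analysis (Stanford-typed, collapsed
prepositions, 1-based positions counting punctuation), and the output the
extraction rules are expected to produce.  They document the behavior of
every rule group on real sentence structures and double as validation
inputs: the bundled fixture dictionary covers all regions they mention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "RuleExample",
    "ExtractionExample",
    "NP_AFTER_EXAMPLE",
    "DEPENDENCY_RULE_EXAMPLES",
    "EXTRACTION_EXAMPLES",
]


@dataclass(frozen=True)
class RuleExample:
    """A dependency rule-group example: edges, keyword, expected candidate list."""

    name: str
    deps: str
    keyword: tuple[str, int]
    expected: tuple[tuple[str, int], ...]
    rule: str  # subj_group | dobj_nsubj | vmod


@dataclass(frozen=True)
class ExtractionExample:
    """An end-to-end example: sentence, parses, expected directed pairs.

    ``expected_pairs`` holds (agent, target) canonical names per the bundled
    fixture dictionary.
    """

    name: str
    text: str
    tree: str
    deps: str
    expected_pairs: tuple[tuple[str, str], ...]
    np_after: Optional[str] = None  # expected post-trigger NP text, if notable


#: "The suprachiasmatic nucleus is well known to project densely to Pa in rats."
#: The first noun phrase after the trigger "project densely to" is "Pa in rats".
NP_AFTER_EXAMPLE = ExtractionExample(
    name="np_after_pa_in_rats",
    text="The suprachiasmatic nucleus is well known to project densely to Pa in rats.",
    tree=(
        "(S (NP (DT The) (JJ suprachiasmatic) (NN nucleus)) (VP (VBZ is) "
        "(ADJP (RB well) (VBN known) (S (VP (TO to) (VP (VB project) "
        "(ADVP (RB densely)) (PP (TO to) (NP (NP (NNP Pa)) (PP (IN in) "
        "(NP (NNS rats)))))))))) (. .))"
    ),
    deps="\n".join(
        (
            "xsubj(project-8, nucleus-3)",
            "det(nucleus-3, The-1)",
            "amod(nucleus-3, suprachiasmatic-2)",
        )
    ),
    expected_pairs=(("Suprachiasmatic nucleus", "Pa"),),
    np_after="Pa in rats",
)


DEPENDENCY_RULE_EXAMPLES: tuple[RuleExample, ...] = (
    # "… the external lateral parabrachial subnucleus projects strongly to …"
    RuleExample(
        name="subject_group_parabrachial",
        deps="\n".join(
            (
                "nsubj(projects-17, subnucleus-16)",
                "det(subnucleus-16, the-12)",
                "amod(subnucleus-16, external-13)",
                "amod(subnucleus-16, lateral-14)",
                "nn(subnucleus-16, parabrachial-15)",
            )
        ),
        keyword=("projects", 17),
        expected=(
            ("the", 12),
            ("external", 13),
            ("lateral", 14),
            ("parabrachial", 15),
            ("subnucleus", 16),
        ),
        rule="subj_group",
    ),
    # "An anterograde tracer injection into the dorsal midline thalamus
    #  revealed strong projections to …"
    RuleExample(
        name="dobj_nsubj_tracer_injection",
        deps="\n".join(
            (
                "dobj(revealed-10, projections-12)",
                "nsubj(revealed-10, injection-4)",
                "amod(injection-4, anterograde-2)",
                "nn(injection-4, tracer-3)",
                "prep_into(injection-4, thalamus-9)",
                "amod(thalamus-9, dorsal-7)",
                "amod(thalamus-9, midline-8)",
            )
        ),
        keyword=("projections", 12),
        expected=(
            ("anterograde", 2),
            ("tracer", 3),
            ("injection", 4),
            ("dorsal", 7),
            ("midline", 8),
            ("thalamus", 9),
        ),
        rule="dobj_nsubj",
    ),
    # "… orexin neurons projecting to the basal forebrain or PVT."
    RuleExample(
        name="vmod_orexin_neurons",
        deps="\n".join(
            (
                "vmod(neurons-30, projecting-31)",
                "nn(neurons-30, orexin-29)",
            )
        ),
        keyword=("projecting", 31),
        expected=(("orexin", 29), ("neurons", 30)),
        rule="vmod",
    ),
)


EXTRACTION_EXAMPLES: tuple[ExtractionExample, ...] = (
    # dual-slot "projections from … to …" with a conjunction of agents
    ExtractionExample(
        name="dual_slot_pa_pt_amygdala",
        text=(
            "These experiments confirm projections from Pa, Pt, and other "
            "midline nuclei to the amygdala."
        ),
        tree=(
            "(S (NP (DT These) (NNS experiments)) (VP (VBP confirm) "
            "(NP (NP (NNS projections)) (PP (IN from) (NP (NP (NNP Pa)) (, ,) "
            "(NP (NNP Pt)) (, ,) (CC and) (NP (JJ other) (JJ midline) "
            "(NNS nuclei)))) (PP (TO to) (NP (DT the) (NN amygdala))))) (. .))"
        ),
        deps="nsubj(confirm-3, experiments-2)",
        expected_pairs=(("Pa", "Amygdala"), ("Pt", "Amygdala")),
    ),
    # passive voice flips the roles: the by-phrase names the agent
    ExtractionExample(
        name="passive_apvt_ventral_subiculum",
        text=(
            "In addition, we found that the aPVT was strongly innervated by "
            "the ventral subiculum but this projection largely did not "
            "involve the pPVT."
        ),
        tree=(
            "(S (PP (IN In) (NP (NN addition))) (, ,) (NP (PRP we)) "
            "(VP (VBD found) (SBAR (IN that) (S (S (NP (DT the) (NN aPVT)) "
            "(VP (VBD was) (ADVP (RB strongly)) (VP (VBN innervated) "
            "(PP (IN by) (NP (DT the) (JJ ventral) (NN subiculum)))))) "
            "(CC but) (S (NP (DT this) (NN projection)) (ADVP (RB largely)) "
            "(VP (VBD did) (RB not) (VP (VB involve) (NP (DT the) "
            "(NN pPVT)))))))) (. .))"
        ),
        deps="\n".join(
            (
                "nsubjpass(innervated-11, aPVT-8)",
                "det(aPVT-8, the-7)",
                "auxpass(innervated-11, was-9)",
            )
        ),
        expected_pairs=(
            ("Ventral subiculum", "Anterior paraventricular nucleus of the thalamus"),
        ),
    ),
    # nominal trigger with an appositive subject
    ExtractionExample(
        name="receive_innervations_orexin",
        text=(
            "The paraventricular thalamus (PVT), a midline thalamic nucleus, "
            "receives dense innervations from lateral hypothalamic orexin "
            "neurons."
        ),
        tree=(
            "(S (NP (NP (DT The) (JJ paraventricular) (NN thalamus)) "
            "(PRN (-LRB- -LRB-) (NP (NNP PVT)) (-RRB- -RRB-)) (, ,) "
            "(NP (DT a) (JJ midline) (JJ thalamic) (NN nucleus)) (, ,)) "
            "(VP (VBZ receives) (NP (JJ dense) (NNS innervations)) "
            "(PP (IN from) (NP (JJ lateral) (JJ hypothalamic) (NN orexin) "
            "(NNS neurons)))) (. .))"
        ),
        deps="\n".join(
            (
                "nsubj(receives-13, thalamus-3)",
                "det(thalamus-3, The-1)",
                "amod(thalamus-3, paraventricular-2)",
                "appos(thalamus-3, PVT-5)",
                "appos(thalamus-3, nucleus-11)",
                "prep_from(receives-13, neurons-20)",
                "amod(neurons-20, lateral-17)",
                "amod(neurons-20, hypothalamic-18)",
                "nn(neurons-20, orexin-19)",
            )
        ),
        expected_pairs=(
            ("Hypothalamic orexin neurons", "Paraventricular nucleus of the thalamus"),
        ),
    ),
    # conjunction of three targets after an "innervate" trigger
    ExtractionExample(
        name="innervate_pfc_nas_amg",
        text=(
            "It appears likely that there are no substantial differences in "
            "the degree to which stress activates PVT neurons that innervate "
            "the PFC, NAS and AMG."
        ),
        tree=(
            "(S (NP (PRP It)) (VP (VBZ appears) (ADJP (JJ likely)) "
            "(SBAR (IN that) (S (NP (EX there)) (VP (VBP are) "
            "(NP (NP (DT no) (JJ substantial) (NNS differences)) "
            "(PP (IN in) (NP (NP (DT the) (NN degree)) "
            "(SBAR (WHPP (TO to) (WHNP (WDT which))) (S (NP (NN stress)) "
            "(VP (VBZ activates) (NP (NP (NN PVT) (NNS neurons)) "
            "(SBAR (WHNP (WDT that)) (S (VP (VB innervate) "
            "(NP (NP (DT the) (NN PFC)) (, ,) (NP (NN NAS)) (CC and) "
            "(NP (NN AMG))))))))))))))))) (. .))"
        ),
        deps="\n".join(
            (
                "nsubj(activates-16, stress-15)",
                "dobj(activates-16, neurons-18)",
                "nn(neurons-18, PVT-17)",
                "nsubj(innervate-20, neurons-18)",
            )
        ),
        expected_pairs=(
            ("Paraventricular nucleus of the thalamus", "Prefrontal cortex"),
            ("Paraventricular nucleus of the thalamus", "Nucleus accumbens"),
            ("Paraventricular nucleus of the thalamus", "Amygdala"),
        ),
    ),
    # "including" list attached to the post-trigger noun phrase
    ExtractionExample(
        name="including_amygdala_hippocampus",
        text=(
            "Studies in rats show that the caudal DR projects strongly to "
            "limbic structures including the amygdala and hippocampus."
        ),
        tree=(
            "(S (NP (NP (NNS Studies)) (PP (IN in) (NP (NNS rats)))) "
            "(VP (VBP show) (SBAR (IN that) (S (NP (DT the) (JJ caudal) "
            "(NN DR)) (VP (VBZ projects) (ADVP (RB strongly)) (PP (TO to) "
            "(NP (JJ limbic) (NNS structures)) (PP (VBG including) "
            "(NP (NP (DT the) (NN amygdala)) (CC and) "
            "(NP (NN hippocampus))))))))) (. .))"
        ),
        deps="\n".join(
            (
                "nsubj(projects-9, DR-8)",
                "det(DR-8, the-6)",
                "amod(DR-8, caudal-7)",
            )
        ),
        expected_pairs=(
            ("Dorsal raphe", "Amygdala"),
            ("Dorsal raphe", "Hippocampus"),
        ),
    ),
)
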