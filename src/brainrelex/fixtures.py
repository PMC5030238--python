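"""Synthetic fixture corpora with known gold relations and shipped parses.

The generator instantiates sentences from templates aligned with the trigger
patterns — active voice, passive voice, the dual-slot "projections from X to
Y" construction, conjunction lists of targets, "including" lists — plus
distractor sentences with no trigger and trigger sentences whose arguments
name no dictionary region.  Every sentence comes with a deterministic,
template-derived constituency tree and dependency triples, so the extraction
rules run on the fixtures exactly as they would on live parser output.

Fixture sentences emulate the *syntactic* variety the rules must handle, not
the lexical messiness of real abstracts (no tagger/parser errors, no
unexpected region spellings), so recovery rates on fixtures are an upper
bound on real-corpus behavior.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus_io import (
    Document,
    GoldCorpus,
    GoldDocument,
    GoldEntity,
    GoldPair,
    GoldSentence,
    Sentence,
    tokenize,
    write_interaction_xml,
)
from .lexicon import Dictionary, load_dictionary
from .syntax import ConstituencyTree, DependencyEdge, parse_bracketed_tree, parse_dependency_triples

__all__ = [
    "FixtureSpec",
    "FixtureCorpus",
    "fixture_dictionary_path",
    "load_fixture_dictionary",
    "generate_fixture_corpus",
    "write_fixture_corpus",
    "InMemoryParseProvider",
]

#: canonical names usable in templates (single-token words, no stop words)
_REGION_POOL = (
    "Amygdala",
    "Basal amygdala",
    "Hippocampus",
    "Suprachiasmatic nucleus",
    "Nucleus accumbens",
    "Prefrontal cortex",
    "Medial prefrontal cortex",
    "Ventral subiculum",
    "Hypothalamus",
    "Lateral septum",
    "Locus coeruleus",
    "Parabrachial nucleus",
    "Dorsal raphe",
    "Infralimbic cortex",
    "Prelimbic cortex",
)


def fixture_dictionary_path() -> Path:
    """Path of the bundled fixture brain-region dictionary."""
    return Path(str(resources.files("brainrelex").joinpath("data/fixture_dictionary.tsv")))


def load_fixture_dictionary() -> Dictionary:
    return load_dictionary(fixture_dictionary_path())


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``regions_per_list`` is the distribution of how many regions appear in a
    list slot (conjunction targets, dual-slot agents); fractions must lie in
    [0, 1] and the seed fixes the output bit-exactly.
    """

    n_docs: int = 20
    seed: int = 0
    distractor_fraction: float = 0.2
    passive_fraction: float = 0.25
    regions_per_list: tuple[tuple[int, float], ...] = ((1, 0.6), (2, 0.3), (3, 0.1))
    sentences_per_doc: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        for frac in (self.distractor_fraction, self.passive_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if abs(sum(w for _, w in self.regions_per_list) - 1.0) > 1e-9:
            raise ValueError("regions_per_list weights must sum to 1")


@dataclass
class FixtureCorpus:
    documents: list[Document]
    gold: GoldCorpus
    parses: dict[tuple[str, int], tuple[str, str]]  # (doc, sent) -> (ptb, deps)

    def provider(self) -> "InMemoryParseProvider":
        return InMemoryParseProvider(self.parses)


class InMemoryParseProvider:
    """Parse provider over generator output (same contract as the file-based one)."""

    def __init__(self, parses: dict[tuple[str, int], tuple[str, str]]):
        self.parses = parses

    def constituency(self, sentence: Sentence) -> ConstituencyTree | None:
        entry = self.parses.get((sentence.doc_id, sentence.index))
        return parse_bracketed_tree(entry[0]) if entry else None

    def dependencies(self, sentence: Sentence) -> list[DependencyEdge] | None:
        entry = self.parses.get((sentence.doc_id, sentence.index))
        return parse_dependency_triples(entry[1]) if entry else None


# ---------------------------------------------------------------------------
# template machinery
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates tokens, assigning 1-based positions as they are appended."""

    def __init__(self) -> None:
        self.tokens: list[str] = []

    def add(self, word: str) -> int:
        self.tokens.append(word)
        return len(self.tokens)

    def add_region(self, name: str) -> list[int]:
        return [self.add(w) for w in name.lower().split()]

    def text(self) -> str:
        joined = " ".join(self.tokens)
        return re.sub(r"\s+([,.;:])", r"\1", joined)


def _np(words: list[str], det: str | None = None) -> str:
    parts = []
    if det is not None:
        parts.append(f"(DT {det})")
    parts.extend(f"(NN {w})" for w in words)
    return "(NP " + " ".join(parts) + ")"


def _np_list(groups: list[tuple[list[str], str | None]]) -> str:
    """Coordinate NP: (NP (NP …) (, ,) (NP …) (CC and) (NP …))."""
    if len(groups) == 1:
        words, det = groups[0]
        return _np(words, det)
    inner = []
    for i, (words, det) in enumerate(groups):
        if i == len(groups) - 1:
            inner.append("(CC and)")
        elif i > 0:
            inner.append("(, ,)")
        inner.append(_np(words, det))
    return "(NP " + " ".join(inner) + ")"


def _subject_deps(b_positions: list[int], verb_pos: int, label: str = "nsubj") -> list[str]:
    """Dependencies for a determiner+region subject governed by the verb."""
    head = b_positions[-1]
    det_pos = b_positions[0] - 1
    deps = [f"{label}(v-{verb_pos}, h-{head})", f"det(h-{head}, the-{det_pos})"]
    deps.extend(f"nn(h-{head}, m-{p})" for p in b_positions[:-1])
    return deps


def _render_deps(b: _Builder, deps: list[str]) -> str:
    """Replace placeholder surfaces (v-17, h-3) with the real token at the position."""
    out = []
    for line in deps:
        def sub(m: re.Match) -> str:
            pos = int(m.group(2))
            return f"{b.tokens[pos - 1]}-{pos}"

        out.append(re.sub(r"([A-Za-z]+)-(\d+)", sub, line))
    return "\n".join(out)


@dataclass
class _BuiltSentence:
    text: str
    tree: str
    deps: str
    mentions: list[str]  # region mention strings, textual order
    gold: list[tuple[int, int]]  # (agent mention idx, target mention idx)


def _region_words(name: str) -> list[str]:
    return name.lower().split()


def _build_active(a: str, b: str) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    a_pos = bld.add_region(a)
    v = bld.add("projects")
    bld.add("densely")
    bld.add("to")
    bld.add("the")
    b_pos = bld.add_region(b)
    bld.add(".")
    tree = (
        "(S "
        + _np(_region_words(a), "The")
        + " (VP (VBZ projects) (ADVP (RB densely)) (PP (TO to) "
        + _np(_region_words(b), "the")
        + ")) (. .))"
    )
    deps = _render_deps(bld, _subject_deps(a_pos, v))
    return _BuiltSentence(bld.text(), tree, deps, [a.lower(), b.lower()], [(0, 1)])


def _build_passive(a: str, b: str) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    a_pos = bld.add_region(a)
    bld.add("was")
    bld.add("strongly")
    v = bld.add("innervated")
    bld.add("by")
    bld.add("the")
    bld.add_region(b)
    bld.add(".")
    tree = (
        "(S "
        + _np(_region_words(a), "The")
        + " (VP (VBD was) (ADVP (RB strongly)) (VP (VBN innervated) (PP (IN by) "
        + _np(_region_words(b), "the")
        + "))) (. .))"
    )
    deps = _render_deps(bld, _subject_deps(a_pos, v, label="nsubjpass"))
    # gold direction: the by-phrase names the agent
    return _BuiltSentence(bld.text(), tree, deps, [a.lower(), b.lower()], [(1, 0)])


def _build_dual(agents: list[str], b: str) -> _BuiltSentence:
    bld = _Builder()
    bld.add("These")
    exp = bld.add("experiments")
    v = bld.add("confirm")
    bld.add("projections")
    bld.add("from")
    groups = []
    for i, name in enumerate(agents):
        if i == len(agents) - 1 and i > 0:
            bld.add("and")
        elif i > 0:
            bld.add(",")
        bld.add_region(name)
        groups.append((_region_words(name), None))
    bld.add("to")
    bld.add("the")
    bld.add_region(b)
    bld.add(".")
    tree = (
        "(S (NP (DT These) (NNS experiments)) (VP (VBP confirm) (NP (NP (NNS projections)) "
        + "(PP (IN from) "
        + _np_list(groups)
        + ") (PP (TO to) "
        + _np(_region_words(b), "the")
        + "))) (. .))"
    )
    deps = _render_deps(bld, [f"nsubj(v-{v}, e-{exp})"])
    mentions = [name.lower() for name in agents] + [b.lower()]
    gold = [(i, len(agents)) for i in range(len(agents))]
    return _BuiltSentence(bld.text(), tree, deps, mentions, gold)


def _build_receive(a: str, b: str) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    a_pos = bld.add_region(a)
    v = bld.add("receives")
    bld.add("dense")
    bld.add("input")
    bld.add("from")
    bld.add("the")
    bld.add_region(b)
    bld.add(".")
    tree = (
        "(S "
        + _np(_region_words(a), "The")
        + " (VP (VBZ receives) (NP (JJ dense) (NN input)) (PP (IN from) "
        + _np(_region_words(b), "the")
        + ")) (. .))"
    )
    deps = _render_deps(bld, _subject_deps(a_pos, v))
    return _BuiltSentence(bld.text(), tree, deps, [a.lower(), b.lower()], [(1, 0)])


def _build_conjunction(a: str, targets: list[str]) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    a_pos = bld.add_region(a)
    v = bld.add("innervates")
    groups = []
    for i, name in enumerate(targets):
        if i == len(targets) - 1 and i > 0:
            bld.add("and")
        elif i > 0:
            bld.add(",")
        bld.add("the")
        bld.add_region(name)
        groups.append((_region_words(name), "the"))
    bld.add(".")
    tree = (
        "(S "
        + _np(_region_words(a), "The")
        + " (VP (VBZ innervates) "
        + _np_list(groups)
        + ") (. .))"
    )
    deps = _render_deps(bld, _subject_deps(a_pos, v))
    mentions = [a.lower()] + [name.lower() for name in targets]
    gold = [(0, i + 1) for i in range(len(targets))]
    return _BuiltSentence(bld.text(), tree, deps, mentions, gold)


def _build_including(a: str, targets: list[str]) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    a_pos = bld.add_region(a)
    v = bld.add("projects")
    bld.add("strongly")
    bld.add("to")
    bld.add("limbic")
    bld.add("structures")
    bld.add("including")
    groups = []
    for i, name in enumerate(targets):
        if i == len(targets) - 1 and i > 0:
            bld.add("and")
        elif i > 0:
            bld.add(",")
        bld.add("the")
        bld.add_region(name)
        groups.append((_region_words(name), "the"))
    bld.add(".")
    tree = (
        "(S "
        + _np(_region_words(a), "The")
        + " (VP (VBZ projects) (ADVP (RB strongly)) (PP (TO to) (NP (JJ limbic) (NNS structures)) "
        + "(PP (VBG including) "
        + _np_list(groups)
        + "))) (. .))"
    )
    deps = _render_deps(bld, _subject_deps(a_pos, v))
    mentions = [a.lower()] + [name.lower() for name in targets]
    gold = [(0, i + 1) for i in range(len(targets))]
    return _BuiltSentence(bld.text(), tree, deps, mentions, gold)


def _build_distractor(a: str, b: str) -> _BuiltSentence:
    bld = _Builder()
    bld.add("The")
    bld.add_region(a)
    bld.add("and")
    bld.add("the")
    bld.add_region(b)
    bld.add("are")
    bld.add("adjacent")
    bld.add("structures")
    bld.add(".")
    tree = (
        "(S (NP "
        + _np(_region_words(a), "The")
        + " (CC and) "
        + _np(_region_words(b), "the")
        + ") (VP (VBP are) (NP (JJ adjacent) (NNS structures))) (. .))"
    )
    return _BuiltSentence(bld.text(), tree, "", [a.lower(), b.lower()], [])


def _build_trigger_no_region() -> _BuiltSentence:
    bld = _Builder()
    bld.add("These")
    c = bld.add("cells")
    v = bld.add("project")
    bld.add("to")
    bld.add("the")
    bld.add("ventricular")
    bld.add("zone")
    bld.add(".")
    tree = (
        "(S (NP (DT These) (NNS cells)) (VP (VBP project) (PP (TO to) "
        "(NP (DT the) (JJ ventricular) (NN zone)))) (. .))"
    )
    deps = _render_deps(bld, [f"nsubj(v-{v}, c-{c})"])
    return _BuiltSentence(bld.text(), tree, deps, [], [])


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


def _pick_list_size(rng: random.Random, spec: FixtureSpec) -> int:
    r = rng.random()
    acc = 0.0
    for size, weight in spec.regions_per_list:
        acc += weight
        if r <= acc:
            return size
    return spec.regions_per_list[-1][0]


def _build_sentence(rng: random.Random, spec: FixtureSpec) -> _BuiltSentence:
    if rng.random() < spec.distractor_fraction:
        if rng.random() < 0.5:
            return _build_trigger_no_region()
        a, b = rng.sample(_REGION_POOL, 2)
        return _build_distractor(a, b)
    if rng.random() < spec.passive_fraction:
        a, b = rng.sample(_REGION_POOL, 2)
        return _build_passive(a, b)
    kind = rng.choice(("active", "dual", "receive", "conjunction", "including"))
    if kind == "active":
        a, b = rng.sample(_REGION_POOL, 2)
        return _build_active(a, b)
    if kind == "receive":
        a, b = rng.sample(_REGION_POOL, 2)
        return _build_receive(a, b)
    size = _pick_list_size(rng, spec)
    regions = rng.sample(_REGION_POOL, size + 1)
    if kind == "dual":
        return _build_dual(regions[:-1], regions[-1])
    if kind == "conjunction":
        return _build_conjunction(regions[-1], regions[:-1])
    return _build_including(regions[-1], regions[:-1])


def generate_fixture_corpus(spec: FixtureSpec) -> FixtureCorpus:
    """Generate a deterministic synthetic corpus with gold relations.

    The same spec (including seed) always yields byte-identical documents,
    gold XML structure and serialized parses.
    """
    rng = random.Random(spec.seed)
    documents: list[Document] = []
    gold = GoldCorpus()
    parses: dict[tuple[str, int], tuple[str, str]] = {}
    for d in range(spec.n_docs):
        doc_id = f"fx{d:03d}"
        n_sents = rng.randint(*spec.sentences_per_doc)
        built = [_build_sentence(rng, spec) for _ in range(n_sents)]
        text = " ".join(b.text for b in built)
        doc = Document.from_text(doc_id, text)
        if len(doc.sentences) != n_sents:  # pragma: no cover - template safety net
            raise AssertionError("sentence splitter disagrees with templates")
        gold_doc = GoldDocument(id=doc_id)
        for idx, b in enumerate(built):
            sid = f"{doc_id}.s{idx}"
            sent = GoldSentence(id=sid, text=b.text)
            for j, mention in enumerate(b.mentions):
                sent.entities.append(GoldEntity(id=f"{sid}.e{j}", text=mention))
            for agent_idx, target_idx in b.gold:
                sent.pairs.append(
                    GoldPair(
                        e1=f"{sid}.e{agent_idx}",
                        e2=f"{sid}.e{target_idx}",
                        interaction=True,
                        direction="e1_to_e2",
                    )
                )
            if not b.gold and len(sent.entities) >= 2:
                sent.pairs.append(
                    GoldPair(e1=f"{sid}.e0", e2=f"{sid}.e1", interaction=False)
                )
            gold_doc.sentences.append(sent)
            parses[(doc_id, idx)] = (b.tree, b.deps)
        gold.documents.append(gold_doc)
        documents.append(doc)
    return FixtureCorpus(documents=documents, gold=gold, parses=parses)


def write_fixture_corpus(corpus: FixtureCorpus, outdir: str | Path) -> None:
    """Serialize a fixture corpus as docs/, gold.xml and parses/."""
    outdir = Path(outdir)
    (outdir / "docs").mkdir(parents=True, exist_ok=True)
    (outdir / "parses").mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (outdir / "docs" / f"{doc.doc_id}.txt").write_text(doc.text + "\n", encoding="utf-8")
    write_interaction_xml(corpus.gold, outdir / "gold.xml")
    for (doc_id, idx), (tree, deps) in corpus.parses.items():
        stem = outdir / "parses" / f"{doc_id}.s{idx}"
        stem.parent.joinpath(stem.name + ".ptb").write_text(tree + "\n", encoding="utf-8")
        stem.parent.joinpath(stem.name + ".deps").write_text(deps + "\n", encoding="utf-8")
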