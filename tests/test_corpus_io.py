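"""Documents, tokenization, splitting, abbreviations and gold-corpus IO."""

import pytest
from lxml import etree

from brainrelex import corpus_io
from brainrelex.corpus_io import (
    Document,
    GoldCorpus,
    GoldDocument,
    GoldEntity,
    GoldPair,
    GoldSentence,
    expand_abbreviations,
    find_abbreviation_pairs,
    read_interaction_xml,
    split_sentences,
    tokenize,
    write_interaction_xml,
)
from brainrelex.syntax import parse_dependency_triples


class TestTokenize:
    def test_punctuation_counts_as_token(self):
        # the comma must occupy its own position so that printed dependency
        # indices ("the-12" after "... in rats,") line up
        toks = tokenize("This topography is consistent with findings in rats, in which the")
        surfaces = {t.position: t.surface for t in toks}
        assert surfaces[8] == "rats"
        assert surfaces[9] == ","
        assert surfaces[12] == "the"

    def test_hyphenated_words_stay_single_tokens(self):
        toks = tokenize("neuronal tract-tracing using")
        assert [t.surface for t in toks] == ["neuronal", "tract-tracing", "using"]

    def test_positions_consecutive_and_spans_reconstruct(self):
        text = "The paraventricular thalamus (PVT), a nucleus."
        toks = tokenize(text)
        assert [t.position for t in toks] == list(range(1, len(toks) + 1))
        for t in toks:
            assert text[t.start : t.end] == t.surface


class TestSplitSentences:
    def test_empty_text(self):
        assert split_sentences("") == []

    def test_period_boundary(self):
        sents = split_sentences("A projects to B. C innervates D.")
        assert [s.text for s in sents] == ["A projects to B.", "C innervates D."]

    def test_citation_kept_inside_sentence(self):
        text = (
            "The PVT receives input from the SCN (Krout and Loewy, 1998). "
            "Other tracing work et al. style citations followed."
        )
        sents = split_sentences(text)
        assert len(sents) == 2
        assert sents[0].text.endswith("(Krout and Loewy, 1998).")

    def test_abbreviations_do_not_split(self):
        sents = split_sentences("Tracers, e.g. CTb, were used. Results follow.")
        assert len(sents) == 2

    def test_char_spans_ordered_and_within_text(self):
        text = "First sentence here. Second one. Third statement ends."
        sents = split_sentences(text)
        prev_end = 0
        for s in sents:
            assert s.start >= prev_end
            assert text[s.start : s.start + len(s.text)] == s.text
            prev_end = s.start + len(s.text)

    def test_idempotent_on_single_sentence(self, small_corpus):
        for doc in small_corpus.documents[:3]:
            for sent in doc.sentences:
                again = split_sentences(sent.text)
                assert [s.text for s in again] == [sent.text]


class TestAbbreviations:
    def test_definition_found_and_expanded(self):
        text = "The paraventricular thalamus (PVT) is active. PVT is active."
        assert find_abbreviation_pairs(text) == [("PVT", "paraventricular thalamus")]
        out = expand_abbreviations(text)
        assert out.endswith("paraventricular thalamus (PVT) is active.")

    def test_no_parentheses_is_identity(self):
        text = "The thalamus projects widely."
        assert expand_abbreviations(text) == text

    def test_invalid_short_form_untouched(self):
        # fails the short-form validity tests (too many words / too long)
        text = "As shown before (see Figure 2). Nothing defined."
        assert find_abbreviation_pairs(text) == []
        assert expand_abbreviations(text) == text

    def test_expansion_idempotent(self):
        text = "The suprachiasmatic nucleus (SCN) drives rhythms. SCN also projects."
        once = expand_abbreviations(text)
        assert expand_abbreviations(once) == once

    def test_character_matching_rejects_mismatch(self):
        # "XYZ" shares no characters with the preceding words
        assert find_abbreviation_pairs("the thalamus (XYZ) fires") == []


def _one_pair_corpus() -> GoldCorpus:
    sent = GoldSentence(
        id="d5917.s0",
        text="from the spinal trigeminal nucleus to the cochlear nucleus",
        entities=[
            GoldEntity("WhiteTextUnseenEval.d5917.s0.e0", "spinal trigeminal nucleus"),
            GoldEntity("WhiteTextUnseenEval.d5917.s0.e1", "cochlear nucleus"),
        ],
        pairs=[
            GoldPair(
                e1="WhiteTextUnseenEval.d5917.s0.e1",
                e2="WhiteTextUnseenEval.d5917.s0.e0",
                interaction=True,
            )
        ],
    )
    return GoldCorpus(documents=[GoldDocument(id="d5917", sentences=[sent])])


class TestInteractionXml:
    def test_two_entity_one_pair_snippet(self, tmp_path):
        path = tmp_path / "gold.xml"
        write_interaction_xml(_one_pair_corpus(), path)
        corpus = read_interaction_xml(path)
        assert len(corpus.documents) == 1
        sent = corpus.documents[0].sentences[0]
        assert len(sent.entities) == 2
        assert corpus.n_true_interactions() == 1

    def test_false_interaction_not_gold(self, tmp_path):
        corpus = _one_pair_corpus()
        sent = corpus.documents[0].sentences[0]
        sent.pairs[0] = GoldPair(sent.pairs[0].e1, sent.pairs[0].e2, interaction=False)
        path = tmp_path / "gold.xml"
        write_interaction_xml(corpus, path)
        assert read_interaction_xml(path).n_true_interactions() == 0

    def test_round_trip_identity(self, tmp_path, small_corpus):
        p1 = tmp_path / "a.xml"
        p2 = tmp_path / "b.xml"
        write_interaction_xml(small_corpus.gold, p1)
        again = read_interaction_xml(p1)
        write_interaction_xml(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dangling_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            '<corpus><document id="d0"><sentence id="d0.s0" text="x">'
            '<entity id="d0.s0.e0" text="thalamus"/>'
            '<pair e1="d0.s0.e0" e2="d0.s0.e9" interaction="True"/>'
            "</sentence></document></corpus>"
        )
        with pytest.raises(ValueError, match="undeclared"):
            read_interaction_xml(path)

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<corpus>\n<document>\n")
        with pytest.raises(etree.XMLSyntaxError):
            read_interaction_xml(path)


class TestDependencyTripleFormat:
    @pytest.mark.parametrize(
        "line, label, gov, dep",
        [
            ("nsubj(projects-17, subnucleus-16)", "nsubj", ("projects", 17), ("subnucleus", 16)),
            ("prep_into(injection-4, thalamus-9)", "prep_into", ("injection", 4), ("thalamus", 9)),
            ("nn(tract-tracing-6, neuronal-5)", "nn", ("tract-tracing", 6), ("neuronal", 5)),
        ],
    )
    def test_printed_format_parses_exactly(self, line, label, gov, dep):
        (edge,) = parse_dependency_triples(line)
        assert (edge.label, edge.gov, edge.dep) == (label, gov, dep)

    def test_empty_input(self):
        assert parse_dependency_triples("") == []

    def test_malformed_line_reported(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_dependency_triples("nsubj(a-1, b-2)\nnot a triple")


def test_document_from_text_sentence_spans():
    doc = Document.from_text("d0", "The PVT projects to the SCN. The SCN fires.")
    assert [s.index for s in doc.sentences] == [0, 1]
    for s in doc.sentences:
        assert doc.text[s.start : s.start + len(s.text)] == s.text
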