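"""Documents, sentences, gold corpora and serialized parses.

Position convention: tokens are numbered 1..n per sentence and punctuation
marks count as tokens, so a comma occupies its own position.  All syntactic
analyses (dependency triples, tree leaves) use the same numbering, which is
what lets serialized parses be pasted next to their sentences and line up.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .syntax import (
    ConstituencyTree,
    DependencyEdge,
    parse_bracketed_tree,
    parse_dependency_triples,
)

__all__ = [
    "Token",
    "Sentence",
    "Document",
    "GoldEntity",
    "GoldPair",
    "GoldSentence",
    "GoldDocument",
    "GoldCorpus",
    "tokenize",
    "split_sentences",
    "find_abbreviation_pairs",
    "expand_abbreviations",
    "read_interaction_xml",
    "write_interaction_xml",
    "read_dependency_triples",
    "read_bracketed_tree",
    "FixtureSpec",
    "generate_fixture_corpus",
    "write_fixture_corpus",
    "FixtureParseProvider",
]

# words kept as one token when hyphenated (tract-tracing); other punctuation
# separates into single-character tokens
_TOKEN_RE = re.compile(r"\w+(?:[-–/']\w+)*|[^\w\s]")


@dataclass(frozen=True)
class Token:
    """A sentence token: surface form, 1-based position, char span in the sentence."""

    surface: str
    position: int
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Tokenize on word boundaries, giving punctuation marks their own positions."""
    return [
        Token(m.group(), i, m.start(), m.end())
        for i, m in enumerate(_TOKEN_RE.finditer(text), start=1)
    ]


@dataclass
class Sentence:
    """A tokenized sentence with document provenance.

    ``start`` is the character offset of the sentence within its document.
    """

    doc_id: str
    index: int
    text: str
    start: int = 0
    tokens: list[Token] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = tokenize(self.text)

    def token_at_char(self, offset: int) -> Optional[Token]:
        """The token covering a character offset (or the next one, for spaces)."""
        for tok in self.tokens:
            if tok.end > offset:
                return tok
        return None

    def tokens_in_char_span(self, start: int, end: int) -> list[Token]:
        return [t for t in self.tokens if t.start < end and t.end > start]


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    @classmethod
    def from_text(cls, doc_id: str, text: str) -> "Document":
        return cls(doc_id=doc_id, text=text, sentences=split_sentences(text, doc_id))


# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

# abbreviations after which a period never ends the sentence
_NONBREAKING = (
    "et al.", "e.g.", "i.e.", "cf.", "vs.", "ca.", "approx.",
    "fig.", "figs.", "no.", "nos.", "resp.", "spp.", "sp.",
)

_BOUNDARY_RE = re.compile(r"[.?!]+[\)\]\"']*\s+")


def split_sentences(text: str, doc_id: str = "doc") -> list[Sentence]:
    """Split text into sentences on terminal punctuation.

    Heuristics: a boundary requires following whitespace plus an upper-case
    letter, digit or opening bracket; common abbreviations ("et al.", "e.g.")
    and periods inside parentheses do not split, so citations like
    "(Krout and Loewy, 1998)." stay inside their sentence.  Newlines always
    split.  Empty input yields an empty list.
    """
    sentences: list[Sentence] = []

    def emit(start: int, end: int) -> None:
        chunk = text[start:end]
        stripped = chunk.strip()
        if not stripped:
            return
        lead = len(chunk) - len(chunk.lstrip())
        sentences.append(
            Sentence(doc_id=doc_id, index=len(sentences), text=stripped, start=start + lead)
        )

    start = 0
    for block_match in re.finditer(r"[^\n]+", text):
        block_start, block_end = block_match.span()
        start = block_start
        block = block_match.group()
        depth = 0
        for m in _BOUNDARY_RE.finditer(block):
            boundary = block_start + m.end()
            prefix = block[: m.start()]
            depth = prefix.count("(") - prefix.count(")")
            if depth > 0 and ")" not in m.group():
                continue
            nxt = text[boundary] if boundary < len(text) else ""
            if nxt and not (nxt.isupper() or nxt.isdigit() or nxt in "(["):
                continue
            before = text[start : block_start + m.start() + 1].lower()
            if any(before.endswith(abbr) for abbr in _NONBREAKING):
                continue
            emit(start, boundary)
            start = boundary
        emit(start, block_end)
    return sentences


# ---------------------------------------------------------------------------
# abbreviation definition detection and expansion
# ---------------------------------------------------------------------------


def _is_valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(sf: str, lf: str) -> Optional[str]:
    """Right-to-left character matching of the short form inside the long form."""
    s = len(sf) - 1
    l = len(lf) - 1
    while s >= 0:
        c = sf[s].lower()
        if not c.isalnum():
            s -= 1
            continue
        while (l >= 0 and lf[l].lower() != c) or (
            s == 0 and l > 0 and lf[l - 1].isalnum()
        ):
            l -= 1
        if l < 0:
            return None
        l -= 1
        s -= 1
    l = lf.rfind(" ", 0, l + 1) + 1
    return lf[l:]


def find_abbreviation_pairs(text: str) -> list[tuple[str, str]]:
    """Locate ``long form (SF)`` definitions.

    A parenthesized candidate short form is paired with the preceding words
    by matching its characters right-to-left against the long-form text; the
    first character must begin a long-form word.  Candidate long forms are
    capped at min(|SF|+5, |SF|*2) words, and pairs whose long form is shorter
    than the short form, contains it, or spans too many words are rejected.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for m in re.finditer(r"\(([^()]+)\)", text):
        sf = m.group(1).strip()
        if not _is_valid_short_form(sf) or sf in seen:
            continue
        prefix = text[: m.start()].rstrip()
        words = prefix.split()
        max_words = min(len(sf) + 5, len(sf) * 2)
        candidate = " ".join(words[-max_words:]) if words else ""
        if not candidate:
            continue
        best = _best_long_form(sf, candidate)
        if best is None:
            continue
        n_words = len(re.split(r"[\s\-]+", best.strip()))
        sf_size = sum(1 for c in sf if c.isalnum())
        if (
            len(best) < len(sf)
            or (sf + " ") in best
            or best.endswith(sf)
            or n_words > sf_size * 2
            or n_words > sf_size + 5
            or sf_size > 10
        ):
            continue
        seen.add(sf)
        pairs.append((sf, best))
    return pairs


def expand_abbreviations(text: str) -> str:
    """Replace later occurrences of a defined short form with "long form (short form)".

    The definition site itself is left untouched, and occurrences already
    wrapped in parentheses are skipped, which makes the expansion idempotent
    on its own output.  Text with no valid definitions is returned unchanged.
    """
    pairs = find_abbreviation_pairs(text)
    for sf, lf in pairs:
        def_end = text.find(f"({sf})")
        def_end = def_end + len(sf) + 2 if def_end >= 0 else 0
        pattern = re.compile(r"(?<![\w(])" + re.escape(sf) + r"(?![\w)])")
        head, tail = text[:def_end], text[def_end:]
        text = head + pattern.sub(f"{lf} ({sf})", tail)
    return text


# ---------------------------------------------------------------------------
# gold corpus (interaction XML dialect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoldEntity:
    id: str
    text: str


@dataclass(frozen=True)
class GoldPair:
    e1: str
    e2: str
    interaction: bool
    direction: Optional[str] = None  # "e1_to_e2" | "e2_to_e1" | None


@dataclass
class GoldSentence:
    id: str
    text: str
    entities: list[GoldEntity] = field(default_factory=list)
    pairs: list[GoldPair] = field(default_factory=list)

    def entity_by_id(self, eid: str) -> GoldEntity:
        for entity in self.entities:
            if entity.id == eid:
                return entity
        raise KeyError(eid)


@dataclass
class GoldDocument:
    id: str
    sentences: list[GoldSentence] = field(default_factory=list)


@dataclass
class GoldCorpus:
    documents: list[GoldDocument] = field(default_factory=list)

    def n_true_interactions(self) -> int:
        return sum(
            1
            for doc in self.documents
            for sent in doc.sentences
            for pair in sent.pairs
            if pair.interaction
        )

    def validate(self) -> None:
        """Every pair must reference declared entity ids of its sentence."""
        for doc in self.documents:
            for sent in doc.sentences:
                ids = {e.id for e in sent.entities}
                for pair in sent.pairs:
                    for ref in (pair.e1, pair.e2):
                        if ref not in ids:
                            raise ValueError(
                                f"pair in sentence {sent.id!r} references "
                                f"undeclared entity {ref!r}"
                            )


def _parse_bool(value: str) -> bool:
    return value.strip().lower() == "true"


def read_interaction_xml(path: str | Path) -> GoldCorpus:
    """Read a corpus in the unified interaction-XML dialect.

    Recognized attributes are ``id``/``text`` on entities and ``interaction``/
    ``e1``/``e2`` (plus an optional ``direction``) on pairs; unknown
    attributes are ignored.  Malformed XML raises an lxml syntax error naming
    the line; a pair referencing an undeclared entity raises ValueError.
    """
    tree = etree.parse(str(path))
    corpus = GoldCorpus()
    for doc_el in tree.getroot().iter("document"):
        doc = GoldDocument(id=doc_el.get("id", f"d{len(corpus.documents)}"))
        for sent_el in doc_el.iter("sentence"):
            sent = GoldSentence(
                id=sent_el.get("id", f"{doc.id}.s{len(doc.sentences)}"),
                text=sent_el.get("text", ""),
            )
            for ent_el in sent_el.iter("entity"):
                sent.entities.append(
                    GoldEntity(id=ent_el.get("id", ""), text=ent_el.get("text", ""))
                )
            for pair_el in sent_el.iter("pair"):
                sent.pairs.append(
                    GoldPair(
                        e1=pair_el.get("e1", ""),
                        e2=pair_el.get("e2", ""),
                        interaction=_parse_bool(pair_el.get("interaction", "False")),
                        direction=pair_el.get("direction"),
                    )
                )
            doc.sentences.append(sent)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def write_interaction_xml(corpus: GoldCorpus, path: str | Path) -> None:
    root = etree.Element("corpus")
    for doc in corpus.documents:
        doc_el = etree.SubElement(root, "document", id=doc.id)
        for sent in doc.sentences:
            sent_el = etree.SubElement(doc_el, "sentence", id=sent.id, text=sent.text)
            for entity in sent.entities:
                etree.SubElement(sent_el, "entity", id=entity.id, text=entity.text)
            for pair in sent.pairs:
                attrs = {
                    "e1": pair.e1,
                    "e2": pair.e2,
                    "interaction": "True" if pair.interaction else "False",
                }
                if pair.direction:
                    attrs["direction"] = pair.direction
                etree.SubElement(sent_el, "pair", **attrs)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# serialized parses
# ---------------------------------------------------------------------------


def read_dependency_triples(path: str | Path) -> list[DependencyEdge]:
    """Read a ``.deps`` file with one ``label(gov-i, dep-j)`` triple per line."""
    return parse_dependency_triples(Path(path).read_text(encoding="utf-8"))


def read_bracketed_tree(path: str | Path) -> ConstituencyTree:
    """Read a ``.ptb`` file containing one bracketed constituency tree."""
    return parse_bracketed_tree(Path(path).read_text(encoding="utf-8"))


class FixtureParseProvider:
    """Parse provider backed by a directory of ``.ptb``/``.deps`` fixtures.

    Files are named ``<doc_id>.s<index>.ptb`` and ``<doc_id>.s<index>.deps``.
    Either file may be absent; the corresponding analysis is then ``None``.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def _path(self, sentence: Sentence, ext: str) -> Path:
        return self.directory / f"{sentence.doc_id}.s{sentence.index}{ext}"

    def constituency(self, sentence: Sentence) -> Optional[ConstituencyTree]:
        path = self._path(sentence, ".ptb")
        return read_bracketed_tree(path) if path.exists() else None

    def dependencies(self, sentence: Sentence) -> Optional[list[DependencyEdge]]:
        path = self._path(sentence, ".deps")
        return read_dependency_triples(path) if path.exists() else None


# fixture generation lives in its own module but is part of this surface;
# resolved lazily to avoid a circular import with brainrelex.fixtures
_FIXTURE_NAMES = (
    "FixtureSpec",
    "FixtureCorpus",
    "generate_fixture_corpus",
    "write_fixture_corpus",
)


def __getattr__(name: str):
    if name in _FIXTURE_NAMES:
        from . import fixtures

        return getattr(fixtures, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
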