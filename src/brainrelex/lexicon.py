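"""Brain-region dictionary and the mention-matching/normalization cascade.

A dictionary entry is a canonical region name with its acronyms (literal
abbreviations such as "SCN") and synonyms (alternative names such as
"suprachiasmatic nuclei").  Direction-qualified regions ("anterior PVT") are
distinct entries.  Candidate text coming out of the syntactic rules is pushed
through a fixed cascade: whole-string lookup, conjunction splitting with
stop-word removal, then substring and per-token search, keeping only the
longest non-overlapping hits.

Name and synonym lookup is case-insensitive; acronym lookup is case-sensitive
by default so that short acronyms ("Pa") do not collide with ordinary words.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "BrainRegionEntry",
    "RegionMatch",
    "Dictionary",
    "load_dictionary",
    "save_dictionary",
    "match_text",
    "classify_against_gold",
    "DEFAULT_STOP_WORDS",
]

#: words removed from candidate pieces before lookup
DEFAULT_STOP_WORDS = ("of", "the", "area", "part")

_DELIM_RE = re.compile(r",|;|\band\b|\bor\b", re.IGNORECASE)
_WS_RE = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS_RE.sub(" ", text.strip())


@dataclass(frozen=True)
class BrainRegionEntry:
    """A dictionary entry: canonical name plus acronyms and synonyms."""

    name: str
    acronyms: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()

    def surface_forms(self) -> tuple[str, ...]:
        return (self.name,) + self.acronyms + self.synonyms


@dataclass(frozen=True)
class RegionMatch:
    """A located, normalized region mention inside some candidate text.

    ``kind`` is "full" when the matched surface covers the entire
    (post-processed) candidate piece, "partial" when it covers only part of
    it (substring or single-token hits inside a longer phrase).
    """

    entry: BrainRegionEntry
    surface: str
    start: int
    end: int
    kind: str  # "full" | "partial"

    @property
    def canonical(self) -> str:
        return self.entry.name


class Dictionary:
    """Index over all surface forms of a set of brain-region entries."""

    def __init__(
        self,
        entries: Iterable[BrainRegionEntry],
        acronym_case_insensitive: bool = False,
    ):
        self.entries: list[BrainRegionEntry] = list(entries)
        self.acronym_case_insensitive = acronym_case_insensitive
        self._ci: dict[str, BrainRegionEntry] = {}
        self._acronyms: dict[str, BrainRegionEntry] = {}
        names = set()
        for entry in self.entries:
            if entry.name in names:
                raise ValueError(f"duplicate canonical name: {entry.name!r}")
            names.add(entry.name)
        for entry in self.entries:
            for form in (entry.name,) + entry.synonyms:
                self._register(self._ci, _norm(form).lower(), entry)
            for acro in entry.acronyms:
                if acronym_case_insensitive:
                    self._register(self._ci, _norm(acro).lower(), entry)
                else:
                    self._register(self._acronyms, _norm(acro), entry)

    @staticmethod
    def _register(index: dict, key: str, entry: BrainRegionEntry) -> None:
        if not key:
            raise ValueError(f"empty surface form in entry {entry.name!r}")
        if key in index and index[key] is not entry:
            logger.warning(
                "surface form %r maps to both %r and %r; keeping the first",
                key, index[key].name, entry.name,
            )
            return
        index[key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> Optional[BrainRegionEntry]:
        """Exact surface-form lookup (case-sensitive for acronyms)."""
        norm = _norm(surface)
        if not norm:
            return None
        hit = self._acronyms.get(norm)
        if hit is not None:
            return hit
        return self._ci.get(norm.lower())

    def iter_surface_forms(self) -> Iterable[tuple[str, BrainRegionEntry, bool]]:
        """Yield (surface form, entry, case_sensitive) over the whole index."""
        for entry in self.entries:
            for form in (entry.name,) + entry.synonyms:
                yield form, entry, False
            for acro in entry.acronyms:
                yield acro, entry, not self.acronym_case_insensitive


def _split_row(line: str) -> list[str]:
    delim = "|" if "|" in line else "\t"
    return [cell.strip() for cell in line.split(delim)]


def load_dictionary(
    path: str | Path, acronym_case_insensitive: bool = False
) -> Dictionary:
    """Load a delimited dictionary file: name | acronyms | synonyms.

    Tab- or pipe-delimited, one entry per row, ``#`` comment lines skipped;
    acronym and synonym cells hold comma-separated lists, with "-" meaning
    none.  Duplicate canonical names raise; duplicate surface forms across
    entries are logged and resolved first-wins.
    """
    entries: list[BrainRegionEntry] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = _split_row(line)
        name = cells[0]
        if not name:
            raise ValueError(f"dictionary row with empty canonical name: {raw!r}")

        def _list(cell: str) -> tuple[str, ...]:
            cell = cell.strip()
            if cell in ("", "-", "–"):
                return ()
            return tuple(s.strip() for s in cell.split(",") if s.strip())

        acronyms = _list(cells[1]) if len(cells) > 1 else ()
        synonyms = _list(cells[2]) if len(cells) > 2 else ()
        entries.append(BrainRegionEntry(name, acronyms, synonyms))
    return Dictionary(entries, acronym_case_insensitive=acronym_case_insensitive)


def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    lines = ["# brain region dictionary: name\tacronyms\tsynonyms"]
    for entry in dictionary.entries:
        lines.append(
            "\t".join(
                (
                    entry.name,
                    ", ".join(entry.acronyms) or "-",
                    ", ".join(entry.synonyms) or "-",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# matching cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Piece:
    text: str
    start: int  # char offset in the candidate text

    def token_spans(self) -> list[tuple[str, int, int]]:
        return [
            (m.group(), self.start + m.start(), self.start + m.end())
            for m in re.finditer(r"\S+", self.text)
        ]


def _pieces(text: str) -> list[_Piece]:
    pieces: list[_Piece] = []
    prev = 0
    for m in _DELIM_RE.finditer(text):
        chunk = text[prev : m.start()]
        if chunk.strip():
            lead = len(chunk) - len(chunk.lstrip())
            pieces.append(_Piece(chunk.strip(), prev + lead))
        prev = m.end()
    chunk = text[prev:]
    if chunk.strip():
        lead = len(chunk) - len(chunk.lstrip())
        pieces.append(_Piece(chunk.strip(), prev + lead))
    return pieces


def _strip_stop_words(piece: _Piece, stop_words: tuple[str, ...]) -> list[tuple[str, int, int]]:
    stop = {w.lower() for w in stop_words}
    kept = []
    for surface, start, end in piece.token_spans():
        word = surface.strip(".,;:()[]\"'")
        if not word or word.lower() in stop:
            continue
        kept.append((word, start, end))
    return kept


def _substring_hits(
    piece_text: str, piece_start: int, dictionary: Dictionary
) -> list[RegionMatch]:
    """Find dictionary surface forms occurring inside the piece at word boundaries."""
    hits: list[RegionMatch] = []
    for form, entry, case_sensitive in dictionary.iter_surface_forms():
        norm = _norm(form)
        if len(norm) < 3:
            continue  # short forms produce spurious substring hits
        pattern = r"(?<!\w)" + re.escape(norm).replace(r"\ ", r"\s+") + r"(?!\w)"
        flags = 0 if case_sensitive else re.IGNORECASE
        for m in re.finditer(pattern, piece_text, flags):
            kind = "full" if _norm(m.group()).lower() == _norm(piece_text).lower() else "partial"
            hits.append(
                RegionMatch(
                    entry=entry,
                    surface=m.group(),
                    start=piece_start + m.start(),
                    end=piece_start + m.end(),
                    kind=kind,
                )
            )
    return hits


def _longest_non_overlapping(matches: list[RegionMatch]) -> list[RegionMatch]:
    """Keep only the longest version of overlapping matches.

    Sorted by span length (descending), ties by start offset then canonical
    name, and kept greedily when not overlapping an already kept match.
    """
    ordered = sorted(
        set(matches),
        key=lambda m: (-(m.end - m.start), m.start, m.canonical),
    )
    kept: list[RegionMatch] = []
    for match in ordered:
        if any(match.start < k.end and match.end > k.start for k in kept):
            continue
        kept.append(match)
    return sorted(kept, key=lambda m: (m.start, m.canonical))


def match_text(
    candidate_text: str,
    dictionary: Dictionary,
    stop_words: tuple[str, ...] = DEFAULT_STOP_WORDS,
) -> list[RegionMatch]:
    """Run the full dictionary-matching cascade over candidate text.

    Steps: (1) whole-string lookup; (2) split on "and"/"or"/comma/semicolon
    and look up each piece after removing stop words; (3) for still-unmatched
    pieces, search dictionary surface forms as substrings of the piece and
    look up each remaining token separately.  Finally only the longest
    non-overlapping matches are kept.  No match yields an empty list.
    """
    text = candidate_text
    entry = dictionary.lookup(text)
    if entry is not None:
        lead = len(text) - len(text.lstrip())
        return [
            RegionMatch(entry, text.strip(), lead, lead + len(text.strip()), "full")
        ]

    matches: list[RegionMatch] = []
    for piece in _pieces(text):
        kept_tokens = _strip_stop_words(piece, stop_words)
        if not kept_tokens:
            continue
        filtered = " ".join(tok for tok, _, _ in kept_tokens)
        entry = dictionary.lookup(filtered)
        if entry is not None:
            matches.append(
                RegionMatch(
                    entry,
                    filtered,
                    kept_tokens[0][1],
                    kept_tokens[-1][2],
                    "full",
                )
            )
            continue
        # step 3b: substring search over the raw piece …
        sub = _substring_hits(piece.text, piece.start, dictionary)
        matches.extend(sub)
        # … then per-token lookup
        for tok, start, end in kept_tokens:
            entry = dictionary.lookup(tok)
            if entry is not None:
                kind = "full" if tok.lower() == filtered.lower() else "partial"
                matches.append(RegionMatch(entry, tok, start, end, kind))
    return _longest_non_overlapping(matches)


def classify_against_gold(extracted: str, gold_mention: str) -> str:
    """Compare an extracted region string with a gold-annotated mention.

    "full": case-insensitive equality after whitespace normalization;
    "partial": the extracted string is a proper word-boundary substring of
    the gold mention; "miss" otherwise.
    """
    ext = _norm(extracted).lower()
    gold = _norm(gold_mention).lower()
    if not ext or not gold:
        return "miss"
    if ext == gold:
        return "full"
    pattern = r"(?<!\w)" + re.escape(ext).replace(r"\ ", r"\s+") + r"(?!\w)"
    if re.search(pattern, gold):
        return "partial"
    return "miss"
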