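"""Trigger patterns for connectivity statements and their role semantics.

Each pattern is an unanchored case-insensitive regular expression over a
connectivity keyword ("project", "innervate", "receive ... from"), usually
permitting a bounded number of interleaved words between the keyword and its
preposition, so that "projects densely to" or "receives dense input from"
match.  Every pattern also declares which side of the relation the text
following it belongs to: after "receive input from" the following text names
the agent (source) of the projection, after "project to" it names the target.

Dual-slot patterns ("projection from X to Y") carry both arguments in fixed
preposition slots and are handled positionally, without the dependency-based
search for the second argument.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus_io import Sentence, Token

__all__ = [
    "PatternDef",
    "PatternMatch",
    "compile_patterns",
    "load_pattern_config",
    "dump_pattern_table",
    "find_pattern_matches",
    "select_candidate_sentences",
    "AGENT",
    "TARGET",
]

AGENT = "agent"
TARGET = "target"

# bounded runs of interleaved words; the dual-slot gap additionally admits
# trailing commas/semicolons so that region lists ("Pa, Pt, and …") fit
def _gap(n: int) -> str:
    return r"(?:\w+\s+){0,%d}" % n


def _list_gap(n: int) -> str:
    return r"(?:\w+[,;]?\s+){0,%d}" % n


@dataclass(frozen=True)
class PatternDef:
    """A compiled trigger pattern with role semantics.

    ``role_after`` is the role of the text following the pattern; the
    dependency-derived second argument takes the complementary role.  For
    dual-slot patterns ``role_slot`` is the role of the mid-pattern
    preposition slot and ``role_after`` that of the trailing slot.
    ``passive_flips`` marks verb-headed patterns whose roles swap when the
    keyword is found in a passive construction.
    """

    name: str
    regex: str
    role_after: str
    slots: str = "single"  # "single" | "dual"
    role_slot: Optional[str] = None
    passive_flips: bool = False

    def __post_init__(self):
        object.__setattr__(self, "_compiled", re.compile(self.regex, re.IGNORECASE))
        if self.role_after not in (AGENT, TARGET):
            raise ValueError(f"invalid role_after {self.role_after!r}")
        if self.slots == "dual" and self.role_slot is None:
            raise ValueError(f"dual-slot pattern {self.name!r} needs role_slot")

    @property
    def compiled(self) -> "re.Pattern[str]":
        return self._compiled  # type: ignore[attr-defined]

    @property
    def role_other(self) -> str:
        return AGENT if self.role_after == TARGET else TARGET


@dataclass(frozen=True)
class PatternMatch:
    """A located occurrence of a trigger pattern in a sentence."""

    pattern: PatternDef
    start: int
    end: int
    token_positions: tuple[int, ...]
    keyword: tuple[str, int]
    slot_span: Optional[tuple[int, int]] = None  # char span of the mid slot (dual)

    @property
    def name(self) -> str:
        return self.pattern.name

    @property
    def last_position(self) -> int:
        return self.token_positions[-1]


_DEFAULT_ROWS: tuple[PatternDef, ...] = (
    PatternDef("innervate", r"innervat(?:e|es|ing)", TARGET, passive_flips=True),
    PatternDef("innervation of", r"innervation(?:s)?\s+of\b", TARGET),
    PatternDef("projection to", r"projection(?:s)?\s+to\b", TARGET),
    PatternDef(
        "projection to from",
        r"projection(?:s)?\s+to\s+(?P<slot>" + _list_gap(8) + r")from\b",
        AGENT,
        slots="dual",
        role_slot=TARGET,
    ),
    PatternDef("projection of", r"projection(?:s)?\s+of\b", AGENT),
    PatternDef("projection target of", r"projection\s+target(?:s)?\s+of\b", AGENT),
    PatternDef("projection from", r"projection(?:s)?\s+from\b", AGENT),
    PatternDef(
        "projection from to",
        r"projection(?:s)?\s+from\s+(?P<slot>" + _list_gap(8) + r")to\b",
        TARGET,
        slots="dual",
        role_slot=AGENT,
    ),
    PatternDef(
        "project to",
        r"project(?:ing|s|ed)?\s+" + _gap(2) + r"to\b",
        TARGET,
        passive_flips=True,
    ),
    PatternDef(
        "project into",
        r"project(?:ing|s|ed)?\s+" + _gap(2) + r"into\b",
        TARGET,
        passive_flips=True,
    ),
    PatternDef(
        "project from to",
        r"project(?:s|ed|ing)?\s+from\s+(?P<slot>" + _list_gap(8) + r")to\b",
        TARGET,
        slots="dual",
        role_slot=AGENT,
    ),
    PatternDef(
        "receive input from",
        r"receiv(?:e|es|ing|ed)?\s+" + _gap(4) + r"input(?:s)?\s+" + _gap(3) + r"from\b",
        AGENT,
        passive_flips=True,
    ),
    PatternDef(
        "receive fiber from",
        r"receiv(?:e|es|ing|ed)?\s+" + _gap(4) + r"fiber(?:s)?\s+" + _gap(3) + r"from\b",
        AGENT,
        passive_flips=True,
    ),
    PatternDef(
        "receive innervation from",
        r"receiv(?:e|es|ing|ed)?\s+" + _gap(4) + r"innervation(?:s)?\s+" + _gap(3) + r"from\b",
        AGENT,
        passive_flips=True,
    ),
    PatternDef(
        "receive [ae]fferent from",
        r"receiv(?:e|es|ing|ed)?\s+" + _gap(4) + r"[ae]fferent(?:s)?\s+" + _gap(3) + r"from\b",
        AGENT,
        passive_flips=True,
    ),
    PatternDef(
        "traveling from to",
        r"travel(?:s|ling)?\s+" + _gap(2) + r"from\s+(?P<slot>" + _list_gap(5) + r")to\b",
        TARGET,
        slots="dual",
        role_slot=AGENT,
    ),
    PatternDef(
        "exit through",
        r"exit(?:s|ing)?\s+" + _gap(8) + r"through\b",
        AGENT,
        passive_flips=True,
    ),
    PatternDef(
        "exit from",
        r"exit(?:s|ing)?\s+" + _gap(8) + r"from\b",
        AGENT,
        passive_flips=True,
    ),
)


def compile_patterns(config: Optional[Sequence[PatternDef]] = None) -> list[PatternDef]:
    """Return the active pattern set (18 built-in patterns by default).

    ``config`` replaces the defaults entirely.  Duplicate names or regexes
    that fail to compile raise ValueError.
    """
    rows = list(config) if config is not None else list(_DEFAULT_ROWS)
    names = set()
    for row in rows:
        if row.name in names:
            raise ValueError(f"duplicate pattern name {row.name!r}")
        names.add(row.name)
        try:
            re.compile(row.regex)
        except re.error as exc:  # pragma: no cover - PatternDef compiles eagerly
            raise ValueError(f"invalid regex for pattern {row.name!r}: {exc}") from exc
    return rows


def load_pattern_config(path: str | Path) -> list[PatternDef]:
    """Load a pattern/role table from a tab-delimited config file.

    Columns: name, regex, role_after, slots, role_slot, passive_flips.
    ``#`` comments and blank lines are skipped, so optional extra patterns
    can ship commented out.
    """
    rows: list[PatternDef] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 3:
            raise ValueError(f"pattern config row needs ≥3 columns: {raw!r}")
        name, regex, role_after = cells[0], cells[1], cells[2]
        slots = cells[3] if len(cells) > 3 and cells[3] else "single"
        role_slot = cells[4] if len(cells) > 4 and cells[4] not in ("", "-") else None
        flips = len(cells) > 5 and cells[5].lower() in ("1", "true", "yes")
        rows.append(PatternDef(name, regex, role_after, slots, role_slot, flips))
    return compile_patterns(rows)


def dump_pattern_table(patterns: Optional[Sequence[PatternDef]] = None) -> str:
    """Render the active pattern table in the config file format."""
    rows = compile_patterns(patterns) if patterns is not None else compile_patterns()
    lines = ["# name\tregex\trole_after\tslots\trole_slot\tpassive_flips"]
    for p in rows:
        lines.append(
            "\t".join(
                (p.name, p.regex, p.role_after, p.slots, p.role_slot or "-",
                 "true" if p.passive_flips else "false")
            )
        )
    return "\n".join(lines) + "\n"


def _match_tokens(sentence: Sentence, start: int, end: int) -> list[Token]:
    return sentence.tokens_in_char_span(start, end)


def find_pattern_matches(
    sentence: Sentence, patterns: Optional[Sequence[PatternDef]] = None
) -> list[PatternMatch]:
    """Locate all non-subsumed trigger-pattern occurrences in a sentence.

    When one match's character span lies strictly inside another's (the
    single-slot "projection from" inside the dual-slot "projection from …
    to"), only the more specific covering match is kept.  The keyword token
    is the token at the start of the match — the keyword stem, never an
    interleaved word.
    """
    active = compile_patterns(patterns) if patterns is not None else compile_patterns()
    raw: list[PatternMatch] = []
    for pattern in active:
        for m in pattern.compiled.finditer(sentence.text):
            tokens = _match_tokens(sentence, m.start(), m.end())
            if not tokens:
                continue
            slot_span = None
            if pattern.slots == "dual":
                try:
                    if m.group("slot"):
                        slot_span = m.span("slot")
                except IndexError:
                    slot_span = None
            raw.append(
                PatternMatch(
                    pattern=pattern,
                    start=m.start(),
                    end=m.end(),
                    token_positions=tuple(t.position for t in tokens),
                    keyword=(tokens[0].surface, tokens[0].position),
                    slot_span=slot_span,
                )
            )
    kept = [
        match
        for match in raw
        if not any(
            other is not match
            and other.start <= match.start
            and match.end <= other.end
            and (other.end - other.start) > (match.end - match.start)
            for other in raw
        )
    ]
    kept.sort(key=lambda m: (m.start, m.end, m.name))
    return kept


def select_candidate_sentences(
    sentences: Iterable[Sentence],
    patterns: Optional[Sequence[PatternDef]] = None,
) -> list[Sentence]:
    """Exactly the sentences with at least one trigger match, in input order."""
    active = compile_patterns(patterns) if patterns is not None else compile_patterns()
    return [s for s in sentences if find_pattern_matches(s, active)]
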