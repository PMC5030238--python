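"""Parse-tree abstractions and the syntactic rules that yield candidate region spans.

The extraction method locates one argument of a connectivity trigger with the
constituency parse (the first noun phrase after the trigger) and the other
argument with the dependency parse (three rule groups keyed on which
grammatical relation the trigger keyword participates in).  All rule logic
here consumes plain in-memory tree/edge types, so it runs identically from a
live parser provider or from serialized parse fixtures.

Dependency labels follow the Stanford-typed, collapsed-preposition scheme
(``nsubj``, ``nsubjpass``, ``xsubj``, ``nn``, ``dobj``, ``vmod``, ``amod``,
``det``, ``prep_into``, ...).  :func:`map_dependency_labels` converts
Universal-Dependencies output from a modern parser into this label set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "ConstituencyTree",
    "TreeNode",
    "DependencyEdge",
    "CandidateSpan",
    "parse_bracketed_tree",
    "parse_dependency_triples",
    "first_np_after",
    "extend_with_including_pp",
    "second_dependent",
    "rule_subject_group",
    "rule_dobj_nsubj",
    "rule_vmod",
    "detect_voice",
    "map_dependency_labels",
]

#: labels of the subject/compound group searched first
SUBJECT_GROUP_LABELS = frozenset({"nsubj", "nsubjpass", "xsubj", "nn"})

# Penn Treebank escapes for brackets in leaf position
_PTB_ESCAPES = {
    "-LRB-": "(",
    "-RRB-": ")",
    "-LSB-": "[",
    "-RSB-": "]",
    "-LCB-": "{",
    "-RCB-": "}",
}


@dataclass
class TreeNode:
    """A node of a phrase-structure tree.

    Leaves carry ``surface`` and a 1-based ``position``; internal nodes carry
    only a phrase ``label`` and ``children``.
    """

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    surface: Optional[str] = None
    position: Optional[int] = None
    parent: Optional["TreeNode"] = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return self.surface is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


@dataclass
class ConstituencyTree:
    """Rooted ordered constituency tree with 1-based leaf positions."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    @classmethod
    def from_string(cls, text: str) -> "ConstituencyTree":
        return parse_bracketed_tree(text)


@dataclass(frozen=True)
class DependencyEdge:
    """``label(governor-pos1, dependent-pos2)`` over 1-based token positions."""

    label: str
    gov: tuple[str, int]
    dep: tuple[str, int]

    def __str__(self) -> str:  # round-trips through parse_dependency_triples
        return f"{self.label}({self.gov[0]}-{self.gov[1]}, {self.dep[0]}-{self.dep[1]})"


@dataclass(frozen=True)
class CandidateSpan:
    """An ordered, position-sorted list of tokens proposed as one relation argument."""

    tokens: tuple[tuple[str, int], ...]
    source: str
    role: Optional[str] = None

    def __bool__(self) -> bool:
        return bool(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(surface for surface, _ in self.tokens)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for _, pos in self.tokens)

    def with_role(self, role: str) -> "CandidateSpan":
        return CandidateSpan(self.tokens, self.source, role)


# ---------------------------------------------------------------------------
# parsing of serialized analyses
# ---------------------------------------------------------------------------

_TREE_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_bracketed_tree(text: str) -> ConstituencyTree:
    """Parse standard bracketed (Penn Treebank style) notation.

    Preterminals collapse into leaves: ``(NN dog)`` becomes a leaf with label
    ``NN`` and surface ``dog``.  Leaf positions are assigned 1..n left to
    right.  Raises :class:`ValueError` on unbalanced or empty input.
    """
    tokens = _TREE_TOKEN_RE.findall(text)
    if not tokens:
        raise ValueError("empty bracketed tree")
    pos_counter = [0]

    def build(i: int) -> tuple[TreeNode, int]:
        if tokens[i] != "(":
            raise ValueError(f"expected '(' at token {i}: {tokens[i]!r}")
        i += 1
        if i >= len(tokens) or tokens[i] in "()":
            raise ValueError("missing node label in bracketed tree")
        node = TreeNode(label=tokens[i])
        i += 1
        while i < len(tokens) and tokens[i] != ")":
            if tokens[i] == "(":
                child, i = build(i)
                child.parent = node
                node.children.append(child)
            else:
                # a bare atom under a label: this node is a preterminal leaf
                pos_counter[0] += 1
                node.surface = _PTB_ESCAPES.get(tokens[i], tokens[i])
                node.position = pos_counter[0]
                i += 1
        if i >= len(tokens):
            raise ValueError("unbalanced brackets in tree")
        return node, i + 1

    root, end = build(0)
    if end != len(tokens):
        raise ValueError("trailing content after tree")
    if root.surface is not None and root.children:
        raise ValueError("node mixes surface text and children")
    return ConstituencyTree(root)


_TRIPLE_RE = re.compile(
    r"^\s*(?P<label>[\w:']+)\(\s*(?P<gov>.+)-(?P<gpos>\d+)'*\s*,\s*(?P<dep>.+)-(?P<dpos>\d+)'*\s*\)\s*$"
)


def parse_dependency_triples(text: str) -> list[DependencyEdge]:
    """Parse one ``label(gov-i, dep-j)`` triple per line.

    Blank lines and ``#`` comment lines are skipped.  A malformed line raises
    :class:`ValueError` naming the offending line.
    """
    edges: list[DependencyEdge] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _TRIPLE_RE.match(stripped)
        if m is None:
            raise ValueError(f"malformed dependency triple on line {lineno}: {line!r}")
        edges.append(
            DependencyEdge(
                label=m.group("label"),
                gov=(m.group("gov"), int(m.group("gpos"))),
                dep=(m.group("dep"), int(m.group("dpos"))),
            )
        )
    return edges


# ---------------------------------------------------------------------------
# constituency rules
# ---------------------------------------------------------------------------


def first_np_after(
    tree: ConstituencyTree, last_pattern_pos: int
) -> Optional[CandidateSpan]:
    """Return the leaves under the first NP strictly after the trigger.

    The tree is walked in pre-order (top-down, left-to-right over the
    bracketed form), so the outermost qualifying NP is found first; all of its
    leaves become the candidate span.  ``None`` when no NP follows the
    trigger, in which case the relation attempt is abandoned for this match.
    """
    for node in tree.preorder():
        if node.is_leaf or node.label != "NP":
            continue
        leaves = node.leaves()
        if leaves and leaves[0].position > last_pattern_pos:
            return CandidateSpan(
                tuple((leaf.surface, leaf.position) for leaf in leaves),
                source="np_after",
            )
    return None


def _find_np_node(tree: ConstituencyTree, span: CandidateSpan) -> Optional[TreeNode]:
    wanted = span.positions
    for node in tree.preorder():
        if node.is_leaf or node.label != "NP":
            continue
        if tuple(leaf.position for leaf in node.leaves()) == wanted:
            return node
    return None


def extend_with_including_pp(
    tree: ConstituencyTree, np_span: CandidateSpan
) -> CandidateSpan:
    """Append a trailing ``including``-PP to an NP span when present.

    Lists such as "limbic structures including the amygdala and hippocampus"
    keep their members inside a prepositional phrase; when the PP immediately
    follows the detected NP (as a right sibling) and contains the keyword
    "including", its leaves join the candidate span.  Otherwise the span is
    returned unchanged.
    """
    node = _find_np_node(tree, np_span)
    if node is None or node.parent is None:
        return np_span
    siblings = node.parent.children
    idx = siblings.index(node)
    for sib in siblings[idx + 1 :]:
        if sib.is_leaf:
            continue  # punctuation or bare conjunction between NP and PP
        if sib.label != "PP":
            break
        if any(leaf.surface.lower() == "including" for leaf in sib.leaves()):
            extra = tuple((leaf.surface, leaf.position) for leaf in sib.leaves())
            return CandidateSpan(np_span.tokens + extra, source=np_span.source, role=np_span.role)
        break  # first following PP lacks the keyword
    return np_span


# ---------------------------------------------------------------------------
# dependency rule groups
# ---------------------------------------------------------------------------


def _sorted_span(
    tokens: Sequence[tuple[str, int]], source: str, exclude_pos: int
) -> CandidateSpan:
    uniq = {pos: surface for surface, pos in tokens if pos != exclude_pos}
    ordered = tuple((uniq[pos], pos) for pos in sorted(uniq))
    return CandidateSpan(ordered, source=source)


def rule_subject_group(
    edges: Sequence[DependencyEdge], keyword: tuple[str, int]
) -> CandidateSpan:
    """Candidates when the keyword sits in an nsubj/nsubjpass/xsubj/nn relation.

    Keyword as governor: the relation's dependent is the candidate head, and
    every dependent it governs (determiner, adjectival and compound modifiers)
    joins the span.  Keyword as dependent: the governor's prepositional
    dependent is the candidate, together with its own amod/nn modifiers.
    """
    kpos = keyword[1]
    found: list[tuple[str, int]] = []
    for edge in edges:
        if edge.label not in SUBJECT_GROUP_LABELS:
            continue
        if edge.gov[1] == kpos:
            head = edge.dep
            found.append(head)
            for sub in edges:
                if sub.gov[1] == head[1]:
                    found.append(sub.dep)
        elif edge.dep[1] == kpos:
            gov = edge.gov
            for prep in edges:
                if prep.label.startswith("prep") and prep.gov[1] == gov[1]:
                    found.append(prep.dep)
                    for sub in edges:
                        if sub.label in ("amod", "nn") and sub.gov[1] == prep.dep[1]:
                            found.append(sub.dep)
    return _sorted_span(found, "subj_group", kpos)


def rule_dobj_nsubj(
    edges: Sequence[DependencyEdge], keyword: tuple[str, int]
) -> CandidateSpan:
    """Candidates when the keyword is the direct object of the main verb.

    The governor of the ``dobj`` relation is searched as the governor of an
    ``nsubj`` relation (which need not contain the keyword); the nominal
    subject is the candidate head.  Its amod/nn/prep dependents are added,
    and the amod/nn modifiers of a prepositional dependent are added in turn,
    so that phrases like "injection into the dorsal midline thalamus" are
    recovered in full.
    """
    kpos = keyword[1]
    found: list[tuple[str, int]] = []
    for dobj in edges:
        if dobj.label != "dobj" or dobj.dep[1] != kpos:
            continue
        verb = dobj.gov
        for nsubj in edges:
            if nsubj.label != "nsubj" or nsubj.gov[1] != verb[1]:
                continue
            subj = nsubj.dep
            found.append(subj)
            for mod in edges:
                if mod.gov[1] != subj[1]:
                    continue
                if mod.label in ("amod", "nn"):
                    found.append(mod.dep)
                elif mod.label.startswith("prep"):
                    found.append(mod.dep)
                    for sub in edges:
                        if sub.label in ("amod", "nn") and sub.gov[1] == mod.dep[1]:
                            found.append(sub.dep)
    return _sorted_span(found, "dobj_nsubj", kpos)


def rule_vmod(
    edges: Sequence[DependencyEdge], keyword: tuple[str, int]
) -> CandidateSpan:
    """Candidates when the keyword is a reduced verbal modifier.

    For "orexin neurons projecting to ..." the keyword "projecting" is the
    dependent of a ``vmod`` edge; the governor noun plus its amod/nn
    modifiers form the candidate span.
    """
    kpos = keyword[1]
    found: list[tuple[str, int]] = []
    for vmod in edges:
        if vmod.label != "vmod" or vmod.dep[1] != kpos:
            continue
        head = vmod.gov
        found.append(head)
        for mod in edges:
            if mod.label in ("amod", "nn") and mod.gov[1] == head[1]:
                found.append(mod.dep)
    return _sorted_span(found, "vmod", kpos)


_RULE_ORDER = (rule_subject_group, rule_dobj_nsubj, rule_vmod)


def second_dependent(
    edges: Sequence[DependencyEdge], keyword: tuple[str, int]
) -> CandidateSpan:
    """Dispatch the three dependency rule groups in order; first hit wins.

    Precedence is subject-group, then the dobj/nsubj special case, then the
    vmod group.  The returned span is position-sorted and never contains the
    keyword token itself.  An empty span signals that no rule fired.
    """
    for rule in _RULE_ORDER:
        span = rule(edges, keyword)
        if span:
            return span
    return CandidateSpan((), source="none")


def detect_voice(edges: Sequence[DependencyEdge], keyword: tuple[str, int]) -> str:
    """``"passive"`` when the keyword participates in an nsubjpass relation."""
    kpos = keyword[1]
    for edge in edges:
        if edge.label == "nsubjpass" and kpos in (edge.gov[1], edge.dep[1]):
            return "passive"
    return "active"


# ---------------------------------------------------------------------------
# label-scheme mapping for live parser providers
# ---------------------------------------------------------------------------

_UD_LABEL_MAP = {
    "obj": "dobj",
    "dobj": "dobj",
    "compound": "nn",
    "acl": "vmod",
    "acl:relcl": "vmod",
    "nsubj:pass": "nsubjpass",
    "nsubjpass": "nsubjpass",
    "nsubj": "nsubj",
    "csubj": "xsubj",
    "amod": "amod",
    "det": "det",
}


def map_dependency_labels(edges: Sequence[DependencyEdge]) -> list[DependencyEdge]:
    """Map Universal-Dependencies labels onto the internal collapsed scheme.

    ``obl``/``nmod`` edges are collapsed with their ``case`` marker into
    ``prep_<preposition>``; other labels go through a lookup table; unmapped
    labels are passed through unchanged (the rules ignore them).
    """
    case_by_gov: dict[int, str] = {}
    for edge in edges:
        if edge.label == "case":
            case_by_gov[edge.gov[1]] = edge.dep[0].lower()
    mapped: list[DependencyEdge] = []
    for edge in edges:
        if edge.label == "case":
            continue
        base = edge.label.split(":")[0]
        if base in ("obl", "nmod"):
            prep = case_by_gov.get(edge.dep[1])
            label = f"prep_{prep}" if prep else "prep"
        else:
            label = _UD_LABEL_MAP.get(edge.label, _UD_LABEL_MAP.get(base, edge.label))
        mapped.append(DependencyEdge(label, edge.gov, edge.dep))
    return mapped
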