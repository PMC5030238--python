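# Methods

## Problem and model

The package extracts *directed* neuroanatomical connectivity relations
between brain regions from free text. The unit of analysis is the sentence;
relations described across sentence boundaries are out of scope (anaphora
resolution would be required and is deliberately not attempted). A relation
is a tuple (agent region, target region, sentence, trigger pattern), where
the agent is the source and the target the destination of the projection.

The extraction model is knowledge-based rather than learned, trading recall
for precision: a relation can only be found in a sentence containing one of
the trigger patterns, and only when both argument spans normalize to
dictionary regions. This is the right trade-off when the output feeds a
connectivity graph, where false edges are costlier than missed ones.

## Trigger patterns

Eighteen built-in patterns cover the productive connectivity vocabulary:
nominal triggers (`projection to/of/from`, `innervation of`, `projection
target of`), verbal triggers (`project to/into`, `innervate`, `receive
input/fiber/innervation/[ae]fferent from`, `exit through/from`,
`travel(s|ling) from … to`), and dual-slot constructions (`projection(s)
from X to Y`, `projection(s) to X from Y`, `project from … to`). All are
case-insensitive, unanchored (so `innervate` fires inside `innervated`),
and admit bounded runs of interleaved words — two words between `project`
and `to`, up to four between `receive` and `input`. In the dual-slot gaps
the interleaved words may carry a trailing comma or semicolon so that
region lists (`from Pa, Pt, and other midline nuclei to …`) stay inside a
single dual-slot match. When a dual-slot match covers a single-slot match
(`projection from` inside `projection from … to`), only the more specific
match is kept.

Each pattern declares the role of the post-trigger text. Defaults: the text
after `projection from/of`, `projection target of`, `receive … from` and
`exit …` names the **agent**; after `innervate`, `innervation of`,
`projection to`, `project to/into` it names the **target**; dual-slot
patterns assign the from-slot to the agent and the to-slot to the target.
The table is config-overridable (`brainrelex patterns dump` emits the
format), because only part of the role inventory is forced by the grammar;
the remainder is a modeling choice. Two further candidate triggers
(`efferent from`, `terminate in`) ship commented out in
`data/extra_patterns.tsv` rather than in the default set.

## Argument identification

Positions are 1-based and count punctuation as tokens; hyphenated words
(`tract-tracing`) are single tokens. All serialized analyses use this
numbering, which is what makes printed dependency triples directly usable
as fixtures.

*Post-trigger argument (constituency).* The tree is traversed in pre-order
and the first NP whose first leaf lies strictly after the trigger's last
token is taken whole (outermost NP wins, so a coordinate NP keeps all its
conjuncts). If the NP's right sibling is a PP containing the word
`including`, the PP's leaves are appended — this captures appositive lists
("limbic structures including the amygdala and hippocampus"). No NP after
the trigger abandons the attempt for that match.

*Second argument (dependencies).* Three rule groups are tried in order, and
the first non-empty result wins:

1. **Subject group** — trigger keyword in an `nsubj`/`nsubjpass`/`xsubj`/
   `nn` relation. As governor: the dependent is the head and every
   dependent it governs (determiner, `amod`, `nn`, appositions) joins the
   span. As dependent: the governor's `prep_*` dependent is taken, plus its
   `amod`/`nn` modifiers.
2. **dobj special case** — keyword is the direct object; the `dobj`
   governor is searched as governor of an `nsubj` (which need not involve
   the keyword); the subject is the head, expanded one level through
   `amod`/`nn`/`prep_*`, and the `amod`/`nn` modifiers of a prepositional
   dependent are added in turn. The recursion depth (one level, then
   modifiers of the prep dependent) is inferred from the worked example in
   `brainrelex.examples` and is the narrowest reading that reproduces it.
3. **vmod group** — keyword is a reduced verbal modifier (`neurons
   projecting to …`); the `vmod` governor plus its `amod`/`nn` modifiers
   form the span.

Spans are position-sorted, never contain the keyword token, and determiners
are kept (stop-word removal in the dictionary cascade discards them later).
The group precedence mirrors increasing structural specificity; in random
edge sets it also matches a brute-force enumeration oracle exactly (tested
on 10,000 graphs of up to 8 edges).

The keyword anchoring the dependency search is the token at the start of
the regex match — the keyword stem (`projects`, `projections`,
`innervated`, `receives`) — never an interleaved word.

*Voice.* If the keyword participates in an `nsubjpass` relation and the
pattern is verb-headed, the agent/target roles flip; this is what turns
"the aPVT was strongly innervated by the ventral subiculum" into
ventral subiculum → aPVT.

*Dual-slot patterns* bypass the dependency search entirely: both arguments
are syntactically local (the tokens between the two prepositions, and the
first NP after the match).

## Dictionary and normalization

A dictionary entry is a canonical region name with acronyms and synonyms;
direction-qualified regions (`anterior PVT`) are separate entries. Name and
synonym lookup is case-insensitive; acronym lookup is case-sensitive exact
by default (`Pa` must not match the preposition "pa(rt)" of ordinary text;
`--acronym-case-insensitive` relaxes this). Plural variants are not
stemmed; they are expected as synonyms (`suprachiasmatic nuclei`).

The matching cascade over a candidate span:

1. whole-string lookup;
2. split on `and`/`or`/comma/semicolon; per piece, remove the stop words
   `of, the, area, part` (config-extendable: the inventory is open) and
   retry the lookup;
3. for still-unmatched pieces: search every dictionary surface form of ≥ 3
   characters as a word-boundary substring of the piece, then look up each
   remaining token individually. The 3-character/word-boundary guard is a
   precision device against spurious acronym hits inside longer words.

Finally only the longest non-overlapping matches are kept (ties broken by
start offset, then canonical name), so a candidate matching both
`thalamus` and `midline thalamus` yields only the latter. A match is
labeled `full` when its surface covers the whole post-processed piece and
`partial` otherwise. Conjunction-ambiguous phrases ("dorsal and ventral
cortex") are *not* expanded into multiple regions; the pieces go through
the cascade as-is — expansion was found to cost precision and is left out.

Both spans' region sets are cross-multiplied into relations; relations
whose two sides normalize to the same canonical region are suppressed as
artifacts. Within a document, duplicate directed pairs are merged
(first-occurrence representative, mention count accumulated); direction is
part of the uniqueness key so A→B and B→A coexist.

## Evaluation

Predictions are aligned to gold pairwise relations within the same
document and sentence, orderlessly (corpus annotations record undirected
interactions). Alignment runs in two greedy passes — exact-mention
alignments first, then (outside strict mode) partial ones — which makes the
strict true positives a subset of the lenient ones by construction.
Comparison of an extracted region string against a gold mention is `full`
on case-insensitive equality after whitespace normalization, `partial` when
the extracted string is a proper word-boundary substring of the mention.

Modes: **strict** counts only full/full alignments as true positives;
**lenient** also counts partial ones; **nlp** additionally credits
unmatched predictions explicitly flagged as dictionary-validated
unannotated candidates. In nlp mode the false-negative count is taken as
(gold − TP): the credited candidates are not gold members, and this is the
bookkeeping under which the published strict/lenient/nlp triples
(66.46/75.78/87.58 precision on 161 retrieved against 322 gold) are
arithmetically consistent. Note the computed strict precision is 66.46
(= 107/161), while 66.43 has also circulated for the same counts; this
package always reports the computed ratio. Percentages are rounded
half-up to 2 decimals. Precision with zero retrieved is reported as 0 with
a `zero_retrieved` flag.

Direction accuracy is the share of true-positive relations whose predicted
direction matches the gold direction; false positives and relations without
a gold direction are excluded (the latter with a warning). The majority
baseline predicts every direction as first mention → second mention and is
scored on the same true positives.

## Synthetic corpora

The fixture generator emulates the study conditions the rules must handle:
active templates (`X projects densely to Y`), passives (`X was strongly
innervated by Y`), dual-slot (`projections from X₁, X₂ and X₃ to Y`),
conjunction targets (`X innervates the Y₁ and the Y₂`), `including` lists,
plus distractors — sentences with no trigger, and trigger sentences whose
arguments name no dictionary region. Defaults: 20 documents of 3–6
sentences, 20 % distractors, 25 % passives among relation sentences, list
sizes 1/2/3 with weights 0.6/0.3/0.1 — a mix in which every rule group and
both match directions are exercised many times at the default sizes. Every
sentence carries a template-derived constituency tree and dependency
triples; generation is bit-exact for a fixed seed.

What fixtures do **not** emulate: parser errors, spelling variation,
out-of-dictionary region names, negation and hedging, cross-sentence
discourse. The 100 % precision/recall recovery on fixtures therefore
verifies the pipeline's internal consistency (patterns ↔ rules ↔
dictionary ↔ scoring), not expected performance on real abstracts, which
is bounded by trigger coverage (the recall ceiling) and dictionary
coverage. The bundled 27-entry dictionary is likewise a synthetic stand-in
for a full literature-compiled dictionary (thousands of entries).

## Graph analysis

The connectivity graph is a directed multigraph: one edge per extracted
mention, so edge multiplicity encodes literature support. Edge betweenness
follows the shortest-path counting definition: parallel edges are collapsed
and direction ignored for path-finding; each unordered node pair
contributes 1 split equally among its shortest paths; an
`ordered_pairs=True` flag doubles the scores for the ordered-pair
convention. The implementation delegates to networkx's Brandes-style
accumulation and is checked against an explicit all-shortest-paths
enumeration on 1,000 random graphs of ≤ 8 nodes. Color bins for rendering
(green → yellow → orange → red) are empirical quartiles of the mapped
attribute — a rendering convention, not a model quantity.

## Numerical and design notes

- Sentence splitting is a compact rule-based splitter (terminal punctuation
  + following capital/digit, abbreviation guard list, parenthesis
  awareness). It is deliberately conservative; a provider-backed splitter
  can replace it where a full NLP stack is available.
- Abbreviation expansion implements the classic right-to-left
  character-matching definition detector (short form 2–10 characters, ≤ 2
  words, long form at most min(|SF|+5, 2·|SF|) words, first short-form
  character must begin a long-form word). Expansion skips occurrences
  already wrapped in parentheses, which makes it idempotent.
- The pattern regexes as historically printed contain typographic artifacts
  (`(\w)^*^`, spaces inside `{0, 1}`); they are normalized to valid syntax
  preserving the stated optionality and word-gap counts.
- The `travel(s|ling)` alternation is kept as printed even though it misses
  the single-l spelling "traveling".
- All randomness is confined to fixture generation; extraction is
  deterministic given parses and dictionary.

## Limitations

Sentence-level only; no negation or hedge detection (a sentence like "no
substantial differences in the degree to which stress activates PVT neurons
that innervate the PFC, NAS and AMG" still yields its three candidate
pairs — by design, such candidates surface for expert review); recall is
structurally capped by trigger coverage; dictionary misses silently drop
relations; the role table for patterns not forced by grammar is a
convention the user can override.
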