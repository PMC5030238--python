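# brainrelex

Rule-based extraction of **directed neuroanatomical connectivity relations**
from neuroscience text, with a literature-mined connectivity graph on top.

Statements like *"the suprachiasmatic nucleus projects densely to the
paraventricular thalamus"* are scattered across decades of publications.
`brainrelex` mines them into normalized, directed region-to-region relations
(agent → target, i.e. source → destination of the projection) that can be
aggregated into a connectivity multigraph — the kind of resource used to
survey the circuitry of a structure such as the paraventricular nucleus of
the thalamus (PVT).

## How it works

The pipeline is knowledge-based and precision-first:

1. **Sentence splitting** and optional abbreviation expansion
   (Schwartz–Hearst pairing of `long form (SF)` definitions, with every later
   `SF` replaced by `long form (SF)`).
2. **Trigger patterns.** 18 case-insensitive regular expressions over
   connectivity keywords (`projection to`, `innervate`, `receive input
   from`, dual-slot `projection from … to …`, …) admitting a bounded number
   of interleaved words (`projects densely to`). Only sentences containing a
   trigger become extraction candidates.
3. **Argument spans from parses.** The argument after the trigger is the
   first noun phrase following it in the constituency tree (extended by a
   trailing `including`-PP); the other argument comes from the dependency
   graph via three rule groups keyed on the relation the trigger keyword
   participates in: the nsubj/nsubjpass/xsubj/nn group, a dobj→nsubj special
   case, and a vmod group. Labels follow the Stanford-typed
   collapsed-preposition scheme (`prep_into`, …); a mapping from Universal
   Dependencies is provided for live parser providers.
4. **Dictionary decision.** Candidate spans are pushed through a brain-region
   dictionary (canonical name + acronyms + synonyms) with a fixed cascade:
   whole-string lookup, conjunction splitting with stop-word removal
   (`of, the, area, part`), substring and per-token search, and finally
   longest-non-overlapping match selection. A relation is emitted only when
   both sides normalize to (different) dictionary regions.
5. **Direction.** Each pattern declares which side of the relation the
   post-trigger text names (after `receive input from` it is the **agent**;
   after `project to` the **target**); passive voice (`was innervated by`)
   flips the roles.
6. **Graph.** Every mention adds a directed edge between canonical region
   nodes; edge betweenness (number of all-pairs shortest paths through an
   edge, equal-length paths splitting the count) is computed on the
   collapsed undirected graph and exported along with quartile color bins
   (GraphML, DOT, TSV, JSON).

Evaluation against gold-annotated corpora reports precision, recall and
F-measure (harmonic mean) in three modes — **strict** (both region strings
equal the gold mentions), **lenient** (word-boundary substrings also count,
e.g. `thalamus` vs `dorsal midline thalamus`) and **NLP-based** (credits
dictionary-validated pairs the annotators left unannotated) — plus direction
accuracy over true positives and a majority baseline that always predicts
first mention → second mention.

## Worked example

```python
from brainrelex import extraction, fixtures
from brainrelex.corpus_io import Sentence
from brainrelex.examples import EXTRACTION_EXAMPLES
from brainrelex.syntax import parse_bracketed_tree, parse_dependency_triples

dictionary = fixtures.load_fixture_dictionary()
ex = next(e for e in EXTRACTION_EXAMPLES if e.name == "passive_apvt_ventral_subiculum")
# "… the aPVT was strongly innervated by the ventral subiculum …"
relations = extraction.extract_from_sentence(
    Sentence("demo", 0, ex.text),
    parse_bracketed_tree(ex.tree),
    parse_dependency_triples(ex.deps),
    dictionary,
)
for rel in relations:
    print(f"{rel.agent} -> {rel.target}   (pattern: {rel.pattern})")
```

prints

```
Ventral subiculum -> Anterior paraventricular nucleus of the thalamus   (pattern: innervate)
```

— the `innervate` trigger normally marks the following text as target, but
the keyword sits in an `nsubjpass` relation, so the roles flip and the
by-phrase region becomes the agent of the projection.

The same flow from the shell, on a generated synthetic corpus with known
gold relations and shipped parses:

```bash
brainrelex fixtures --out demo --n-docs 8 --seed 7
brainrelex extract --in demo/docs --dict src/brainrelex/data/fixture_dictionary.tsv \
    --parses demo/parses --out demo/relations.tsv
brainrelex evaluate --pred demo/relations.tsv --gold demo/gold.xml --mode strict
```

reports `tp 39 / fp 0 / fn 0` — precision, recall and F-measure 100.0 — on
that corpus: every templated relation is recovered exactly, and distractor
sentences yield nothing. `brainrelex graph --relations demo/relations.tsv
--betweenness --format graphml --out demo/pvt.graphml` exports the
connectivity multigraph; `brainrelex patterns dump` prints the active
pattern/role table (extra patterns can be enabled via
`src/brainrelex/data/extra_patterns.tsv`).

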