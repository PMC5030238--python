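"""End-to-end pipeline configuration and execution.

Ties the stages together: sentence splitting → (optional abbreviation
expansion) → trigger-pattern selection → parse lookup → candidate rules →
dictionary decision → direction assignment → deduplication → outputs.
All randomness lives in fixture generation; given fixed parses the pipeline
is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import corpus_io, evaluation, extraction, graph as graph_mod, patterns
from .corpus_io import Document, FixtureParseProvider, expand_abbreviations
from .lexicon import Dictionary, load_dictionary
from .patterns import PatternDef

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one extraction run.

    Exactly one parse source must be configured (currently: a directory of
    serialized parse fixtures).  ``expand_abbreviations_first`` controls
    whether expansion runs before sentence splitting (the default) or is
    skipped entirely via ``expand_abbreviations``.
    """

    docs_dir: Path
    dictionary_path: Path
    parses_dir: Path
    out_relations: Optional[Path] = None
    gold_path: Optional[Path] = None
    eval_mode: str = "lenient"
    pattern_config: Optional[Path] = None
    expand_abbreviations: bool = False
    expand_abbreviations_first: bool = True
    dedup_scope: str = "document"  # "sentence" | "document"
    acronym_case_insensitive: bool = False

    def validate(self) -> None:
        for path in (self.docs_dir, self.dictionary_path, self.parses_dir):
            if not Path(path).exists():
                raise FileNotFoundError(f"configured path does not exist: {path}")
        if self.dedup_scope not in ("sentence", "document"):
            raise ValueError(f"invalid dedup scope {self.dedup_scope!r}")
        if self.eval_mode not in evaluation.MODES:
            raise ValueError(f"invalid evaluation mode {self.eval_mode!r}")


@dataclass
class PipelineResult:
    relations: list[extraction.DirectedRelation]
    stage_counts: dict[str, int] = field(default_factory=dict)
    eval_result: Optional[evaluation.EvalResult] = None


def _load_documents(config: PipelineConfig) -> list[Document]:
    docs: list[Document] = []
    for path in sorted(Path(config.docs_dir).glob("*.txt")):
        text = path.read_text(encoding="utf-8").strip()
        if config.expand_abbreviations and config.expand_abbreviations_first:
            text = expand_abbreviations(text)
        doc = Document.from_text(path.stem, text)
        if config.expand_abbreviations and not config.expand_abbreviations_first:
            for sentence in doc.sentences:
                expanded = expand_abbreviations(sentence.text)
                if expanded != sentence.text:
                    sentence.text = expanded
                    sentence.tokens = corpus_io.tokenize(expanded)
        docs.append(doc)
    return docs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full extraction pipeline for a configured corpus.

    Stage counts (sentences, candidates, relations, …) are returned and
    logged; a stage failure aborts with an error naming the stage.
    """
    config.validate()
    stage = "load"
    try:
        documents = _load_documents(config)
        dictionary = load_dictionary(
            config.dictionary_path,
            acronym_case_insensitive=config.acronym_case_insensitive,
        )
        active: Optional[Sequence[PatternDef]] = None
        if config.pattern_config is not None:
            active = patterns.load_pattern_config(config.pattern_config)
        provider = FixtureParseProvider(config.parses_dir)

        stage = "extract"
        n_sentences = sum(len(d.sentences) for d in documents)
        n_candidates = 0
        relations: list[extraction.DirectedRelation] = []
        for doc in documents:
            candidates = patterns.select_candidate_sentences(doc.sentences, active)
            n_candidates += len(candidates)
            relations.extend(
                extraction.extract_document(doc, provider, dictionary, active)
            )
        n_mentions = len(relations)
        if config.dedup_scope == "document":
            relations = extraction.dedup_document(relations)

        stage = "output"
        if config.out_relations is not None:
            extraction.write_relations_tsv(relations, config.out_relations)

        stage = "evaluate"
        eval_result = None
        if config.gold_path is not None:
            gold = corpus_io.read_interaction_xml(config.gold_path)
            eval_result = evaluation.score(relations, gold, mode=config.eval_mode)
    except Exception as exc:
        if config.out_relations is not None and stage != "output":
            Path(config.out_relations).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    counts = {
        "documents": len(documents),
        "sentences": n_sentences,
        "candidate_sentences": n_candidates,
        "relation_mentions": n_mentions,
        "relations": len(relations),
    }
    for key, value in counts.items():
        logger.info("pipeline %s: %d", key, value)
    return PipelineResult(relations=relations, stage_counts=counts, eval_result=eval_result)
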