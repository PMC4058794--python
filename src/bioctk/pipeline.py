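"""End-to-end preprocessing pipeline over BioC collections.

Stages — ``sentence``, ``token``, ``pos``, ``lemma``, ``parse``,
``abbrev`` — are applied per passage in dependency order; any subset can
be selected as long as its prerequisites are satisfied either in the same
run or by a previous run (the applied stages are recorded in the
collection infon ``pipeline_stages``, so incremental invocations compose
exactly like a single one).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable

from . import __version__
from .abbrev import annotate_abbreviations
from .errors import PipelineUsageError
from .model import (
    BioCAnnotation,
    BioCCollection,
    BioCSentence,
    next_annotation_id,
    next_relation_id,
)
from .parse import ParseResult, encode_parse, naive_dependencies
from .segment import DEFAULT_CONFIG, TokenizerConfig, segment, tokenize
from .tag import (
    PENN_TAGSET_NAME,
    Tagger,
    baseline_sentence_tagger,
    lemmatize_tokens,
    tag_tokens,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_ORDER", "STAGE_REQUIRES"]

STAGE_ORDER = ["sentence", "token", "pos", "lemma", "parse", "abbrev"]

STAGE_REQUIRES = {
    "sentence": None,
    "token": "sentence",
    "pos": "token",
    "lemma": "pos",
    "parse": "pos",
    "abbrev": "sentence",
}

STAGES_INFON = "pipeline_stages"


@dataclass
class PipelineConfig:
    """Pipeline knobs: tokenizer settings and the pluggable tagger/parser.

    ``parser`` maps a sentence's token list to a :class:`ParseResult`;
    the default is the deterministic right-headed chain, and any external
    parser with the same signature can be plugged in.
    """

    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    tagger: Tagger = baseline_sentence_tagger
    parser: Callable[[list[BioCAnnotation]], ParseResult] = naive_dependencies


def _sentence_tokens(sentence: BioCSentence) -> list[BioCAnnotation]:
    toks = [a for a in sentence.annotations if a.infons.get("type") != "ABBR"]
    toks.sort(key=lambda a: a.locations[0].offset)
    return toks


def run_pipeline(collection: BioCCollection,
                 stages: set[str] | list[str],
                 config: PipelineConfig | None = None,
                 logger: Callable[[str], None] | None = None) -> BioCCollection:
    """Apply the selected stages and return a new annotated collection.

    Stage prerequisites (token needs sentence, pos needs token, lemma and
    parse need pos, abbrev needs sentence) may be satisfied either by the
    same invocation or by stages already applied to the input collection;
    otherwise :class:`PipelineUsageError` names the missing prerequisite.
    The output records the accumulated stage list and tool version as
    collection infons.
    """
    config = config or PipelineConfig()
    requested = set(stages)
    unknown = requested.difference(STAGE_ORDER)
    if unknown:
        raise PipelineUsageError(
            f"unknown stages {sorted(unknown)}; valid: {STAGE_ORDER}")

    out = copy.deepcopy(collection)
    already = set(filter(None, out.infons.get(STAGES_INFON, "").split(",")))
    for stage in requested:
        prereq = STAGE_REQUIRES[stage]
        if prereq and prereq not in requested and prereq not in already:
            raise PipelineUsageError(
                f"stage {stage!r} requires {prereq!r}, which is neither "
                f"selected nor already applied to the input")

    to_run = [s for s in STAGE_ORDER if s in requested and s not in already]
    for doc in out.documents:
        for stage in to_run:
            if logger:
                logger(f"{stage}: document {doc.id}")
            if stage == "sentence":
                for p in doc.passages:
                    if p.text is not None:
                        sentences = segment(p.text, p.offset, config.tokenizer)
                        if sentences:
                            p.sentences = sentences
                            p.text = None
            elif stage == "token":
                next_id = next_annotation_id(doc)
                for p in doc.passages:
                    for s in p.sentences:
                        tokens = tokenize(s, config.tokenizer, id_start=next_id)
                        next_id += len(tokens)
                        s.annotations.extend(tokens)
            elif stage == "pos":
                for p in doc.passages:
                    for s in p.sentences:
                        tag_tokens(_sentence_tokens(s), config.tagger)
            elif stage == "lemma":
                for p in doc.passages:
                    for s in p.sentences:
                        lemmatize_tokens(_sentence_tokens(s))
            elif stage == "parse":
                next_rel = next_relation_id(doc)
                for p in doc.passages:
                    for s in p.sentences:
                        tokens = _sentence_tokens(s)
                        if tokens:
                            parse = config.parser(tokens)
                            encode_parse(s, parse, relation_id_start=next_rel)
                            next_rel += len(parse.dependencies)
            elif stage == "abbrev":
                for p in doc.passages:
                    annotate_abbreviations(p, document=doc)

    applied = already.union(requested)
    out.infons[STAGES_INFON] = ",".join(s for s in STAGE_ORDER if s in applied)
    out.infons["pipeline_version"] = __version__
    if "pos" in applied:
        out.infons["tagset"] = PENN_TAGSET_NAME
    return out
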