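"""Part-of-speech tagging and lemmatization of token annotations.

The tagger contract is pluggable: any callable mapping a sentence's list
of token texts to an equal-length list of tags can be used, so a trained
context-sensitive tagger drops in without interface changes.  The shipped
baseline is deterministic — a closed-class lexicon, then suffix rules,
then digit/punctuation patterns, with ``NN`` as the documented fallback —
which keeps the whole pipeline testable without any trained model.

Lemmatization takes the word form and its POS (the usual contract for
biomedical lemmatizers), lowercases, normalizes British spellings to
American, and strips inflectional suffixes through an exception lexicon
plus a rule cascade.  All three resources (closed-class lexicon,
irregular forms, British->American map) ship as editable tab-separated
text files under ``bioctk/resources``.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Callable, Sequence

from .errors import ContractError
from .model import BioCAnnotation

__all__ = ["baseline_tag", "baseline_sentence_tagger", "tag_tokens",
           "lemmatize", "lemmatize_tokens", "PENN_TAGSET_NAME"]

PENN_TAGSET_NAME = "PennTreebank"

Tagger = Callable[[Sequence[str]], Sequence[str]]


def _load_tsv(name: str) -> list[list[str]]:
    text = resources.files("bioctk.resources").joinpath(name).read_text("utf-8")
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=1)
def _closed_class() -> dict[str, str]:
    return {w.lower(): tag for w, tag in _load_tsv("closed_class.tsv")}


@lru_cache(maxsize=1)
def _irregular(cls: str) -> dict[str, str]:
    return {form.lower(): lemma for form, lemma, c in _load_tsv("irregular_lemmas.tsv")
            if c == cls}


@lru_cache(maxsize=1)
def _british_map() -> dict[str, str]:
    return {b: a for b, a in _load_tsv("british_american.tsv")}


_PUNCT_ONLY = re.compile(r"[^\w\s]+$")
_HAS_DIGIT = re.compile(r"\d")
_NUMBER = re.compile(r"[+-]?\d[\d,.]*%?$|[+-]?\.\d+%?$")


def baseline_tag(token_text: str, sentence_initial: bool = False) -> str:
    """Deterministic Penn Treebank tag for one token.

    Cascade: closed-class lexicon -> suffix rules -> capitalization ->
    digit pattern -> punctuation (literal tag) -> ``NN`` fallback.
    ``sentence_initial`` suppresses the capitalized->NNP heuristic for the
    first token of a sentence, where capitalization is uninformative.
    """
    if not token_text:
        raise ValueError("empty token")
    lower = token_text.lower()
    tag = _closed_class().get(lower)
    if tag is not None:
        return tag
    if lower.isalpha() or "-" in lower:
        if lower.endswith("ing") and len(lower) >= 5:
            return "VBG"
        if lower.endswith("ed") and len(lower) >= 4:
            return "VBN"
        if lower.endswith("ly") and len(lower) >= 4:
            return "RB"
        if (lower.endswith("s") and len(lower) >= 4
                and not lower.endswith(("ss", "us", "is"))):
            return "NNS"
        if lower.endswith(("tion", "sion", "ity", "ness", "ment")):
            return "NN"
        if token_text[0].isupper() and not sentence_initial:
            return "NNP"
    if _NUMBER.match(token_text) or (_HAS_DIGIT.search(token_text)
                                     and not any(c.isalpha() for c in token_text)):
        return "CD"
    if _PUNCT_ONLY.match(token_text):
        return token_text
    return "NN"


def baseline_sentence_tagger(token_texts: Sequence[str]) -> list[str]:
    """Sentence-level wrapper of :func:`baseline_tag` (the default tagger)."""
    return [baseline_tag(t, sentence_initial=(i == 0))
            for i, t in enumerate(token_texts)]


def tag_tokens(tokens: Sequence[BioCAnnotation],
               tagger: Tagger = baseline_sentence_tagger) -> Sequence[BioCAnnotation]:
    """Assign a ``POS`` infon to every token annotation, in place.

    The tagger sees the whole sentence's token texts at once.  A tagger
    returning the wrong number of tags raises :class:`ContractError`.
    Order and offsets of the tokens are untouched.
    """
    if not tokens:
        return tokens
    tags = list(tagger([t.text for t in tokens]))
    if len(tags) != len(tokens):
        raise ContractError(
            f"tagger returned {len(tags)} tags for {len(tokens)} tokens")
    for tok, tag in zip(tokens, tags):
        tok.infons["POS"] = tag
    return tokens


# ---------------------------------------------------------------------------
# lemmatization

# words where the -our -> -or rule must not fire
_OUR_KEEP = {"four", "hour", "pour", "sour", "flour", "tour", "your", "our",
             "scour", "devour", "velour", "detour", "contour"}


def _americanize(word: str) -> str:
    mapped = _british_map().get(word)
    if mapped is not None:
        return mapped
    if word.endswith("aemia"):
        return word[:-5] + "emia"
    if word.endswith("aemic"):
        return word[:-5] + "emic"
    if word.endswith("isation"):
        return word[:-7] + "ization"
    if word.endswith("isations"):
        return word[:-8] + "izations"
    if word.endswith("our") and len(word) > 5 and word not in _OUR_KEEP:
        return word[:-3] + "or"
    return word


def _restore_e(stem: str) -> str:
    # after stripping -ed/-ing, put back a dropped final 'e' for the
    # stem shapes where that is almost always right
    if stem.endswith(("at", "iz", "yz", "bl", "us", "eas", "v", "c")):
        return stem + "e"
    return stem


def _undouble(stem: str) -> str:
    if (len(stem) >= 3 and stem[-1] == stem[-2]
            and stem[-1].isalpha() and stem[-1] not in "lsz"
            and stem[-1] not in "aeiou"):
        return stem[:-1]
    return stem


def _singularize(word: str) -> str:
    irr = _irregular("N").get(word)
    if irr is not None:
        return irr
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "xes", "zes", "ches", "shes", "uses")):
        return word[:-2]
    if word.endswith("s") and len(word) > 3 and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def _verb_base(word: str) -> str:
    irr = _irregular("V").get(word)
    if irr is not None:
        return irr
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("eed") and len(word) > 4:
        return word[:-1]
    if word.endswith("ed") and len(word) > 3:
        return _restore_e(_undouble(word[:-2]))
    if word.endswith("ing") and len(word) > 4:
        return _restore_e(_undouble(word[:-3]))
    return word


def lemmatize(token_text: str, pos: str = "NN") -> str:
    """Lowercased dictionary base form of ``token_text`` given its POS.

    Plural nouns (``NNS``/``NNPS``) are singularized; verb forms
    (``VBD``/``VBN``/``VBG``/``VBZ``) are reduced to the base form;
    everything else is lowercased and spelling-normalized only.  Total
    (never raises on any Unicode token) and idempotent for a fixed POS.
    """
    if not token_text:
        raise ValueError("empty token")
    word = _americanize(token_text.lower())
    if pos in ("NNS", "NNPS"):
        return _americanize(_singularize(word))
    if pos in ("VBD", "VBN", "VBG"):
        return _americanize(_verb_base(word))
    if pos == "VBZ":
        irr = _irregular("V").get(word)
        return irr if irr is not None else _americanize(_singularize(word))
    return word


def lemmatize_tokens(tokens: Sequence[BioCAnnotation]) -> Sequence[BioCAnnotation]:
    """Assign a ``lemma`` infon to every token, using its ``POS`` infon."""
    for tok in tokens:
        tok.infons["lemma"] = lemmatize(tok.text, tok.infons.get("POS", "NN"))
    return tokens
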