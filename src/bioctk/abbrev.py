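"""Abbreviation definition detection (Schwartz & Hearst-style).

Finds patterns of the form ``long form (SF)`` inside a sentence: a
parenthesized short-form candidate whose characters all appear, in order,
in the words immediately preceding the parenthesis.  The classic
algorithm is a right-to-left character match over a window of
``min(|SF| + 5, 2 * |SF|)`` words, with the extra requirement that the
first character of the short form matches the first character of the
first long-form word.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import (
    BioCAnnotation,
    BioCLocation,
    BioCNode,
    BioCPassage,
    BioCRelation,
    BioCSentence,
    next_annotation_id,
    next_relation_id,
)

__all__ = ["AbbreviationPair", "find_abbreviations", "annotate_abbreviations"]


@dataclass(frozen=True)
class AbbreviationPair:
    """A detected definition: short form in parentheses, long form before it.

    Locations are document coordinates; the long form always precedes the
    short form within the same sentence.
    """

    short_form: str
    short_location: BioCLocation
    long_form: str
    long_location: BioCLocation


def _is_candidate(sf: str) -> bool:
    """Classic short-form candidate filter."""
    if not 2 <= len(sf) <= 10:
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(sf: str, candidate: str) -> str | None:
    """Right-to-left in-order character match of ``sf`` inside ``candidate``.

    Returns the matched tail of ``candidate`` trimmed to a word start, or
    None when the short form's characters cannot be matched.  The first
    short-form character must start a word (the first long-form word).
    """
    s = len(sf) - 1
    l = len(candidate) - 1
    while s >= 0:
        ch = sf[s].lower()
        if not ch.isalnum():
            s -= 1
            continue
        while l >= 0 and (candidate[l].lower() != ch
                          or (s == 0 and l > 0 and candidate[l - 1].isalnum())):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    start = candidate.rfind(" ", 0, l + 1) + 1
    return candidate[start:]


def find_abbreviations(sentence: BioCSentence) -> list[AbbreviationPair]:
    """Detect (short form, long form) definition pairs in one sentence.

    Scans innermost parenthesized spans for candidates, then matches each
    against the preceding window of ``min(|SF| + 5, 2 * |SF|)`` words.
    Hyphens in long forms act as word separators for windowing purposes.
    Returned locations reconstruct their texts from the document exactly.
    """
    text = sentence.text
    pairs: list[AbbreviationPair] = []
    # innermost parentheses only: content with no nested parens
    for m in re.finditer(r"\(([^()]*)\)", text):
        sf = m.group(1).strip()
        if not _is_candidate(sf):
            continue
        sf_rel = m.start(1) + m.group(1).index(sf)
        before = text[:m.start()].rstrip()
        if not before:
            continue
        # window of words preceding the parenthesis; hyphens separate words
        max_words = min(len(sf) + 5, 2 * len(sf))
        flat = before.replace("-", " ")
        starts = [w.start() for w in re.finditer(r"\S+", flat)]
        if not starts:
            continue
        window_start = starts[-max_words] if len(starts) > max_words else starts[0]
        candidate = before[window_start:]
        long_form = _best_long_form(sf, candidate)
        if long_form is None or not long_form.strip():
            continue
        long_rel = window_start + (len(candidate) - len(long_form))
        pairs.append(AbbreviationPair(
            short_form=sf,
            short_location=BioCLocation(sentence.offset + sf_rel, len(sf)),
            long_form=long_form,
            long_location=BioCLocation(sentence.offset + long_rel, len(long_form)),
        ))
    return pairs


def annotate_abbreviations(passage: BioCPassage,
                           ann_id_start: int | None = None,
                           rel_id_start: int | None = None,
                           document=None) -> BioCPassage:
    """Add paired ABBR annotations and linking relations to a passage.

    Each detected pair yields two annotations (infons ``type=ABBR`` and
    ``role=shortform``/``role=longform``) attached to the sentence, plus
    one relation (infon ``relation=ABBR``) whose nodes carry the same
    roles.  Id counters continue the document's ``T``/``R`` schemes when
    ``document`` is given.
    """
    if document is not None:
        ann_id_start = next_annotation_id(document)
        rel_id_start = next_relation_id(document)
    next_a = ann_id_start if ann_id_start is not None else 1
    next_r = rel_id_start if rel_id_start is not None else 1
    for sentence in passage.sentences:
        for pair in find_abbreviations(sentence):
            long_ann = BioCAnnotation(
                id=f"T{next_a}", text=pair.long_form,
                infons={"type": "ABBR", "role": "longform"},
                locations=[pair.long_location])
            short_ann = BioCAnnotation(
                id=f"T{next_a + 1}", text=pair.short_form,
                infons={"type": "ABBR", "role": "shortform"},
                locations=[pair.short_location])
            next_a += 2
            sentence.annotations.extend([long_ann, short_ann])
            sentence.relations.append(BioCRelation(
                id=f"R{next_r}",
                infons={"relation": "ABBR"},
                nodes=[BioCNode(long_ann.id, "longform"),
                       BioCNode(short_ann.id, "shortform")]))
            next_r += 1
    return passage
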