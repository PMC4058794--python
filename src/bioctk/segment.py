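"""Rule-based sentence segmentation and invertible tokenization.

The segmenter is a small finite-state scanner: a sentence terminator
(default ``.``, ``!``, ``?``) ends a sentence only when it is followed by
whitespace and an uppercase letter or digit (or the end of the text), and
the token it closes is not a known abbreviation.  The tokenizer splits on
whitespace, peels clause punctuation into separate tokens, and optionally
splits at hyphens and slashes — the two behaviors real biomedical
tokenizers disagree on.

Both stages are *invertible*: every sentence and token is an exact
substring of the original text, addressed by document-coordinate offsets,
so multi-space runs and all original characters can be recovered from the
annotations alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .model import BioCAnnotation, BioCLocation, BioCSentence

__all__ = ["TokenizerConfig", "segment", "tokenize", "detokenize", "default_abbreviations"]


def default_abbreviations() -> frozenset[str]:
    """Abbreviation list shipped as an editable plain-text resource."""
    text = resources.files("bioctk.resources").joinpath("abbreviations.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization/segmentation knobs.

    ``split_hyphen``/``split_slash`` control whether ``beta-thalassemia``
    is one token or three; ``abbreviation_list`` suppresses sentence
    breaks after e.g. ``Fig.``; ``sentence_end_chars`` is the terminator
    set of the segmenter's finite-state machine.
    """

    split_hyphen: bool = False
    split_slash: bool = False
    abbreviation_list: frozenset[str] = field(default_factory=default_abbreviations)
    sentence_end_chars: frozenset[str] = frozenset(".!?")

    def __post_init__(self):
        if not self.sentence_end_chars:
            raise ValueError("sentence_end_chars must be non-empty")


DEFAULT_CONFIG = TokenizerConfig()

#: punctuation peeled off token edges (terminators handled separately)
_EDGE_PUNCT = set('.,;:()[]{}!?"\'%')


def _is_boundary(text: str, end: int, sent_start: int, config: TokenizerConfig) -> bool:
    """Decide whether the terminator run ending at ``end`` closes a sentence."""
    n = len(text)
    rest = text[end:]
    if end >= n or rest.strip() == "":
        follows_ok = True
    elif text[end].isspace():
        nxt = rest.lstrip()[0]
        follows_ok = nxt.isupper() or nxt.isdigit()
    else:
        return False
    if not follows_ok:
        return False
    if text[end - 1] == ".":
        # the chunk the period closes, e.g. "al." in "et al."
        m = re.search(r"\S+$", text[sent_start:end])
        chunk = m.group(0) if m else ""
        if chunk in config.abbreviation_list:
            return False
        # also honor multi-word entries like "et al."
        tail2 = re.search(r"\S+\s+\S+$", text[sent_start:end])
        if tail2 and tail2.group(0) in config.abbreviation_list:
            return False
    return True


def segment(passage_text: str, passage_offset: int = 0,
            config: TokenizerConfig = DEFAULT_CONFIG) -> list[BioCSentence]:
    """Split passage text into sentences with document-coordinate offsets.

    Each sentence's ``text`` is the exact original substring (leading and
    trailing whitespace excluded); together the sentences cover every
    non-whitespace character.  A pure function of ``(text, config)``.
    """
    sentences: list[BioCSentence] = []
    n = len(passage_text)
    i = 0
    start: int | None = None
    while i < n:
        ch = passage_text[i]
        if start is None:
            if not ch.isspace():
                start = i
            i += 1
            continue
        if ch in config.sentence_end_chars:
            j = i
            while j + 1 < n and passage_text[j + 1] in config.sentence_end_chars:
                j += 1
            end = j + 1
            if _is_boundary(passage_text, end, start, config):
                sentences.append(BioCSentence(
                    offset=passage_offset + start,
                    text=passage_text[start:end],
                ))
                start = None
            i = end
        else:
            i += 1
    if start is not None:
        chunk = passage_text[start:].rstrip()
        if chunk:
            sentences.append(BioCSentence(offset=passage_offset + start, text=chunk))
    return sentences


def _split_chunk(chunk: str, config: TokenizerConfig) -> list[str]:
    """Split one whitespace-delimited chunk into sub-token texts, in order."""
    if chunk in config.abbreviation_list:
        return [chunk]
    leading: list[str] = []
    trailing: list[str] = []
    core = chunk
    while core and core[0] in _EDGE_PUNCT:
        leading.append(core[0])
        core = core[1:]
    while core and core[-1] in _EDGE_PUNCT:
        if core in config.abbreviation_list:
            break
        trailing.append(core[-1])
        core = core[:-1]
    trailing.reverse()
    parts: list[str] = []
    if core:
        seps = ""
        if config.split_hyphen:
            seps += "-"
        if config.split_slash:
            seps += "/"
        if seps:
            parts = [p for p in re.split(f"([{re.escape(seps)}])", core) if p]
        else:
            parts = [core]
    return leading + parts + trailing


def tokenize(sentence: BioCSentence,
             config: TokenizerConfig = DEFAULT_CONFIG,
             id_start: int = 1) -> list[BioCAnnotation]:
    """Tokenize a sentence into offset-bearing token annotations.

    Tokens are ordered and non-overlapping, offsets are document
    coordinates, and every token is an exact substring of the sentence, so
    interleaving token texts with the original inter-token characters
    reproduces the sentence text byte-for-byte.  Ids are ``T<id_start>``
    onward.
    """
    tokens: list[BioCAnnotation] = []
    next_id = id_start
    for m in re.finditer(r"\S+", sentence.text):
        pos = m.start()
        for part in _split_chunk(m.group(0), config):
            # locate the part inside the chunk (parts appear in order)
            rel = sentence.text.index(part, pos, m.end())
            tokens.append(BioCAnnotation(
                id=f"T{next_id}",
                text=part,
                locations=[BioCLocation(sentence.offset + rel, len(part))],
            ))
            next_id += 1
            pos = rel + len(part)
    return tokens


def detokenize(sentence: BioCSentence,
               tokens: list[BioCAnnotation] | None = None) -> str:
    """Rebuild the sentence text from its token annotations.

    Token texts are interleaved with the original gap characters recovered
    via offsets.  Raises ``ValueError`` when tokens disagree with the
    sentence (wrong offsets, overlap, or non-whitespace gaps) — i.e. the
    tokenization was not invertible.
    """
    if tokens is None:
        tokens = sentence.annotations
    parts: list[str] = []
    cursor = 0
    for tok in sorted(tokens, key=lambda t: t.locations[0].offset):
        loc = tok.locations[0]
        rel = loc.offset - sentence.offset
        if rel < cursor:
            raise ValueError(f"token {tok.id} overlaps previous token")
        gap = sentence.text[cursor:rel]
        if gap.strip():
            raise ValueError(f"non-whitespace characters {gap!r} not covered by any token")
        if sentence.text[rel:rel + loc.length] != tok.text:
            raise ValueError(
                f"token {tok.id} text {tok.text!r} disagrees with sentence span "
                f"{sentence.text[rel:rel + loc.length]!r}")
        parts.append(gap)
        parts.append(tok.text)
        cursor = rel + loc.length
    tail = sentence.text[cursor:]
    if tail.strip():
        raise ValueError(f"trailing non-whitespace {tail!r} not covered by any token")
    parts.append(tail)
    return "".join(parts)
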