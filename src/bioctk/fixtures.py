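"""Deterministic synthetic-corpus generator.

Every round-trip and pipeline test runs against corpora built here, with
no download.  The generated text is deliberately adversarial rather than
realistic: it mixes multi-space runs, hyphenated and slashed tokens,
parenthesized abbreviation definitions, known sentence-internal
abbreviations and non-ASCII characters — every edge the tokenizer,
segmenter and converters commit to handling.  Mention categories follow
the four disease categories of the reference corpus and concept ids mix
MeSH-style ``D``-numbers with ``OMIM:``-prefixed ids, including
occasional composite ids.
"""

from __future__ import annotations

import random

from .model import (
    BioCAnnotation,
    BioCCollection,
    BioCDocument,
    BioCLocation,
    BioCNode,
    BioCPassage,
    BioCRelation,
    BioCSentence,
)
from .pubtator import Mention, PubTatorDocument, write_pubtator

__all__ = ["generate_corpus", "generate_documents", "generate_broken_fixture",
           "BROKEN_KINDS", "CATEGORIES"]

CATEGORIES = ["SpecificDisease", "DiseaseClass", "Modifier", "CompositeMention"]

_WORDS = [
    "the", "of", "in", "with", "and", "for", "patients", "families",
    "mutation", "mutations", "gene", "protein", "expression", "analysis",
    "clinical", "severe", "recurrent", "hereditary", "associated",
    "identified", "observed", "reported", "studied", "linkage", "locus",
    "deficiency", "component", "complement", "infections", "syndrome",
    "autosomal", "dominant", "recessive", "carriers", "probands",
    "and/or", "x-linked", "long-term", "follow-up", "wild-type",
    "β-globin", "α-chain", "naïve",
]

_DISEASES = [
    "colon cancer", "breast cancer", "beta-thalassemia",
    "cystic fibrosis", "Duchenne muscular dystrophy", "G6PD deficiency",
    "ataxia-telangiectasia", "Crohn disease", "hereditary neuropathy",
    "insulin-dependent diabetes mellitus", "sickle cell anemia",
    "familial hypercholesterolemia", "β-thalassemia",
]

_ABBREV_DEFS = [
    ("Online Mendelian Inheritance in Man", "OMIM"),
    ("Medical Subject Headings", "MeSH"),
    ("polymerase chain reaction", "PCR"),
    ("magnetic resonance imaging", "MRI"),
    ("adenomatous polyposis coli", "APC"),
]


class _TextBuilder:
    """Accumulates chunks and records the span of each appended chunk."""

    def __init__(self):
        self.parts: list[str] = []
        self.length = 0

    def append(self, chunk: str, sep: str = "") -> int:
        """Append ``sep + chunk``; return the offset where ``chunk`` starts."""
        if sep:
            self.parts.append(sep)
            self.length += len(sep)
        start = self.length
        self.parts.append(chunk)
        self.length += len(chunk)
        return start

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _sep(rng: random.Random) -> str:
    # mostly single spaces, with occasional multi-space runs
    return " " * (2 if rng.random() < 0.12 else 1)


def _sentence(rng: random.Random, builder: _TextBuilder, base: int,
              mentions: list[Mention], concept_pool: list[str],
              allow_mention: bool = True) -> None:
    n_words = rng.randint(4, 9)
    first = rng.choice(_WORDS).capitalize()
    builder.append(first, sep="" if builder.length == 0 else _sep(rng))
    for _ in range(n_words - 1):
        builder.append(rng.choice(_WORDS), sep=_sep(rng))
    if allow_mention and rng.random() < 0.6:
        for _ in range(rng.randint(1, 2)):
            phrase = rng.choice(_DISEASES)
            start = builder.append(phrase, sep=_sep(rng))
            mentions.append(Mention(
                start=base + start, end=base + start + len(phrase),
                text=phrase, category=rng.choice(CATEGORIES),
                concept_id=rng.choice(concept_pool)))
    if rng.random() < 0.25:
        long_form, short_form = rng.choice(_ABBREV_DEFS)
        builder.append(f"{long_form} ({short_form})", sep=_sep(rng))
    if rng.random() < 0.1:
        builder.append("cf.", sep=_sep(rng))
        builder.append(rng.choice(_WORDS), sep=_sep(rng))
    builder.append(".")


def generate_documents(n_docs: int, seed: int) -> list[PubTatorDocument]:
    """Generate ``n_docs`` synthetic PubTator documents, deterministically."""
    rng = random.Random(seed)
    mesh_pool = [f"D{rng.randrange(10 ** 6):06d}" for _ in range(15)]
    omim_pool = [f"OMIM:{rng.randrange(100000, 999999)}" for _ in range(8)]
    concept_pool = mesh_pool + omim_pool
    # a few composite identifiers, preserved verbatim
    concept_pool += [f"{rng.choice(mesh_pool)}|{rng.choice(mesh_pool)}",
                     f"{rng.choice(mesh_pool)}+{rng.choice(omim_pool)}"]

    docs: list[PubTatorDocument] = []
    for i in range(n_docs):
        pmid = str(9000000 + i)
        mentions: list[Mention] = []

        tb = _TextBuilder()
        _sentence(rng, tb, base=0, mentions=mentions,
                  concept_pool=concept_pool, allow_mention=rng.random() < 0.5)
        title = tb.text

        ab = _TextBuilder()
        abstract_base = len(title) + 1
        for _ in range(rng.randint(1, 4)):
            _sentence(rng, ab, base=abstract_base, mentions=mentions,
                      concept_pool=concept_pool)
        abstract = ab.text

        # cap at 5 mentions, keep document order
        mentions = sorted(mentions, key=lambda m: m.start)[:5]
        docs.append(PubTatorDocument(pmid=pmid, title=title,
                                     abstract=abstract, mentions=mentions))
    return docs


def generate_corpus(n_docs: int, seed: int) -> tuple[str, tuple[int, int, int]]:
    """PubTator text for ``n_docs`` synthetic documents plus ground truth.

    Returns ``(stream_text, (documents, mentions, unique_concepts))``;
    byte-identical for identical ``(n_docs, seed)``.
    """
    docs = generate_documents(n_docs, seed)
    n_mentions = sum(len(d.mentions) for d in docs)
    concepts = {m.concept_id for d in docs for m in d.mentions}
    return write_pubtator(docs), (len(docs), n_mentions, len(concepts))


# ---------------------------------------------------------------------------
# broken fixtures


def _base_collection(rng: random.Random) -> BioCCollection:
    """A tiny valid collection with sentences, tokens and one relation."""
    w1, w2 = rng.choice(_WORDS), rng.choice(_WORDS)
    s1_text = f"{w1.capitalize()} {w2} observed."
    s2_text = "It was confirmed."
    passage = BioCPassage(offset=0, sentences=[
        BioCSentence(offset=0, text=s1_text),
        BioCSentence(offset=len(s1_text) + 1, text=s2_text),
    ])
    sent = passage.sentences[0]
    cursor = 0
    for i, word in enumerate([w1.capitalize(), w2], start=1):
        start = s1_text.index(word, cursor)
        sent.annotations.append(BioCAnnotation(
            id=f"T{i}", text=word, infons={"POS": "NN"},
            locations=[BioCLocation(start, len(word))]))
        cursor = start + len(word)
    sent.relations.append(BioCRelation(
        id="R1", infons={"relation": "dep"},
        nodes=[BioCNode("T2", "head"), BioCNode("T1", "dependent")]))
    doc = BioCDocument(id="9000001", passages=[passage])
    return BioCCollection(source="fixture", date="2014-01-01",
                          key="fixture.key", documents=[doc])


def _break_span_text(c, rng):
    ann = c.documents[0].passages[0].sentences[0].annotations[0]
    ann.text = "x" * len(ann.text)  # same length, wrong characters


def _break_text_length(c, rng):
    ann = c.documents[0].passages[0].sentences[0].annotations[0]
    ann.text = ann.text[:-1]  # length now disagrees with the location


def _break_refid(c, rng):
    rel = c.documents[0].passages[0].sentences[0].relations[0]
    rel.nodes[0] = BioCNode("T99", "head")


def _break_sentence_overlap(c, rng):
    sents = c.documents[0].passages[0].sentences
    first = sents[0]
    # an extra sentence whose span lies inside the first one (text agrees
    # with the document, so only the ordering invariant is violated)
    sents.insert(1, BioCSentence(offset=first.offset,
                                 text=first.text[:len(first.text) - 1]))


def _break_duplicate_id(c, rng):
    sent = c.documents[0].passages[0].sentences[0]
    sent.annotations.append(BioCAnnotation(
        id=sent.annotations[0].id, text=sent.annotations[0].text,
        infons=dict(sent.annotations[0].infons),
        locations=[BioCLocation(sent.annotations[0].locations[0].offset,
                                sent.annotations[0].locations[0].length)]))


def _break_empty_infon(c, rng):
    c.documents[0].passages[0].sentences[0].annotations[0].infons["POS"] = ""


def _break_location(c, rng):
    ann = c.documents[0].passages[0].sentences[0].annotations[0]
    ann.locations[0] = BioCLocation(-1, ann.locations[0].length)


#: violation catalogue: kind -> (mutator, rule name it triggers)
BROKEN_KINDS = {
    "span_text_mismatch": (_break_span_text, "span_text"),
    "text_length_mismatch": (_break_text_length, "text_length"),
    "unresolved_refid": (_break_refid, "unresolved_refid"),
    "overlapping_sentences": (_break_sentence_overlap, "sentence_order"),
    "duplicate_annotation_id": (_break_duplicate_id, "unique_annotation_id"),
    "empty_infon": (_break_empty_infon, "infon_value"),
    "bad_location": (_break_location, "location_range"),
}


def generate_broken_fixture(kind: str, seed: int = 0) -> BioCCollection:
    """A collection violating exactly the requested invariant class.

    ``kind`` must be one of :data:`BROKEN_KINDS`; anything else raises
    ``ValueError``.  The returned collection fails ``validate_collection``
    with violations only of the corresponding rule.
    """
    if kind not in BROKEN_KINDS:
        raise ValueError(
            f"unknown broken-fixture kind {kind!r}; known: {sorted(BROKEN_KINDS)}")
    rng = random.Random(seed)
    collection = _base_collection(rng)
    BROKEN_KINDS[kind][0](collection, rng)
    return collection
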