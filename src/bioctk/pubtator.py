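"""PubTator <-> BioC conversion for disease-mention corpora.

PubTator is a plain-text corpus format: per document a ``pmid|t|title``
line, a ``pmid|a|abstract`` line, then one tab-separated line per entity
mention (``pmid  start  end  text  category  concept_id``), with a blank
line between documents.  Mention coordinates run over
``title + one separator character + abstract``.

The BioC rendering follows the disease-corpus infon scheme: every mention
annotation carries ``EntityType`` (the mention category), ``ConceptID``
(the identifier, verbatim) and ``Nomenclature`` (``OMIM`` when the id has
an ``OMIM:`` prefix, else ``MeSH``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, TextIO

from .errors import ConversionError, PubTatorFormatError
from .model import (
    BioCAnnotation,
    BioCCollection,
    BioCDocument,
    BioCLocation,
    BioCPassage,
    passage_text,
)

__all__ = ["Mention", "PubTatorDocument", "parse_pubtator", "pubtator_to_bioc",
           "bioc_to_pubtator", "corpus_stats", "write_pubtator"]


@dataclass(frozen=True)
class Mention:
    """One entity mention: [start, end) over title + separator + abstract."""

    start: int
    end: int
    text: str
    category: str
    concept_id: str


@dataclass
class PubTatorDocument:
    pmid: str
    title: str
    abstract: str = ""
    mentions: list[Mention] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + "\n" + self.abstract


def _check_mention(doc: PubTatorDocument, m: Mention, lineno: int) -> None:
    span = doc.full_text[m.start:m.end]
    if span != m.text:
        raise PubTatorFormatError(
            f"pmid {doc.pmid}, line {lineno}: mention span [{m.start}, {m.end}) "
            f"reads {span!r} but the line claims {m.text!r}")


def parse_pubtator(stream: str | TextIO | Iterable[str]) -> list[PubTatorDocument]:
    """Parse a PubTator stream into documents, verifying every mention span.

    ``stream`` may be the text itself, a text file object, or an iterable
    of lines.  Span/text disagreements and missing title lines raise
    :class:`PubTatorFormatError` citing the pmid and line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]

    docs: list[PubTatorDocument] = []
    current: PubTatorDocument | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            current = None
            continue
        parts = line.split("|", 2)
        if len(parts) == 3 and parts[1] in ("t", "a"):
            pmid, kind, text = parts
            if kind == "t":
                current = PubTatorDocument(pmid=pmid, title=text)
                docs.append(current)
            else:
                if current is None or current.pmid != pmid:
                    raise PubTatorFormatError(
                        f"line {lineno}: abstract line for pmid {pmid!r} "
                        f"without a preceding title line")
                current.abstract = text
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PubTatorFormatError(
                f"line {lineno}: expected a mention line with 6 tab-separated "
                f"fields, got {len(fields)}")
        pmid, start, end, text, category, concept_id = fields[:6]
        if current is None or current.pmid != pmid:
            raise PubTatorFormatError(
                f"line {lineno}: mention for pmid {pmid!r} without its "
                f"title/abstract block")
        try:
            mention = Mention(int(start), int(end), text, category, concept_id)
        except ValueError:
            raise PubTatorFormatError(
                f"pmid {pmid}, line {lineno}: non-integer mention offsets "
                f"{start!r}, {end!r}") from None
        _check_mention(current, mention, lineno)
        current.mentions.append(mention)
    for doc in docs:
        doc.mentions.sort(key=lambda m: (m.start, m.end))
    return docs


def _nomenclature(concept_id: str) -> str:
    return "OMIM" if concept_id.startswith("OMIM:") else "MeSH"


def pubtator_to_bioc(docs: list[PubTatorDocument], source: str = "PubTator",
                     collection_date: str | None = None) -> BioCCollection:
    """Convert parsed PubTator documents to a BioC collection.

    Title passage at offset 0, abstract passage at ``len(title) + 1``;
    each mention becomes an annotation on the passage containing it, with
    the ``EntityType``/``ConceptID``/``Nomenclature`` infons.  Mentions
    straddling the title/abstract boundary raise
    :class:`PubTatorFormatError`.
    """
    collection = BioCCollection(
        source=source,
        date=collection_date or _date.today().isoformat(),
        key=f"{source}.key",
    )
    for doc in docs:
        bdoc = BioCDocument(id=doc.pmid)
        title_p = BioCPassage(offset=0, text=doc.title, infons={"type": "title"})
        abstract_p = BioCPassage(offset=len(doc.title) + 1, text=doc.abstract,
                                 infons={"type": "abstract"})
        boundary = len(doc.title)
        next_id = 1
        for m in doc.mentions:
            if m.start < boundary < m.end:
                raise PubTatorFormatError(
                    f"pmid {doc.pmid}: mention [{m.start}, {m.end}) straddles "
                    f"the title/abstract boundary at {boundary}")
            target = title_p if m.end <= boundary else abstract_p
            target.annotations.append(BioCAnnotation(
                id=f"T{next_id}",
                text=m.text,
                infons={"EntityType": m.category,
                        "Nomenclature": _nomenclature(m.concept_id),
                        "ConceptID": m.concept_id},
                locations=[BioCLocation(m.start, m.end - m.start)],
            ))
            next_id += 1
        bdoc.passages = [title_p, abstract_p]
        collection.documents.append(bdoc)
    return collection


def _mention_annotations(doc: BioCDocument) -> list[tuple[int, BioCAnnotation]]:
    out = []
    for p in doc.passages:
        for a in p.annotations:
            if "ConceptID" in a.infons:
                out.append((a.locations[0].offset, a))
        for s in p.sentences:
            for a in s.annotations:
                if "ConceptID" in a.infons:
                    out.append((a.locations[0].offset, a))
    out.sort(key=lambda pair: pair[0])
    return out


def bioc_to_pubtator(collection: BioCCollection) -> str:
    """Render a BioC collection back to PubTator text.

    The inverse of :func:`pubtator_to_bioc` on its output shape: the
    first passage is the title, the second the abstract; annotations with
    a ``ConceptID`` infon become mention lines (other annotations, e.g.
    tokens, are skipped).  An annotation with an ``EntityType`` but no
    ``ConceptID`` raises :class:`ConversionError`.
    """
    out = io.StringIO()
    for doc in collection.documents:
        if not doc.passages:
            raise ConversionError(f"document {doc.id!r} has no passages")
        title = passage_text(doc.passages[0])
        abstract = passage_text(doc.passages[1]) if len(doc.passages) > 1 else ""
        out.write(f"{doc.id}|t|{title}\n")
        out.write(f"{doc.id}|a|{abstract}\n")
        for p in doc.passages:
            for a in p.annotations:
                if "EntityType" in a.infons and "ConceptID" not in a.infons:
                    raise ConversionError(
                        f"document {doc.id!r}: annotation {a.id!r} has "
                        f"EntityType but no ConceptID infon")
        for offset, a in _mention_annotations(doc):
            loc = a.locations[0]
            out.write("\t".join([
                doc.id, str(loc.offset), str(loc.end), a.text,
                a.infons.get("EntityType", ""), a.infons["ConceptID"],
            ]) + "\n")
        out.write("\n")
    return out.getvalue()


def write_pubtator(docs: list[PubTatorDocument]) -> str:
    """Serialize PubTator documents back to the plain-text format."""
    out = io.StringIO()
    for doc in docs:
        out.write(f"{doc.pmid}|t|{doc.title}\n")
        out.write(f"{doc.pmid}|a|{doc.abstract}\n")
        for m in doc.mentions:
            out.write("\t".join([doc.pmid, str(m.start), str(m.end), m.text,
                                 m.category, m.concept_id]) + "\n")
        out.write("\n")
    return out.getvalue()


def corpus_stats(collection: BioCCollection,
                 split_composite: bool = False) -> tuple[int, int, int]:
    """(documents, mention annotations, unique concept identifiers).

    Mentions are annotations carrying a ``ConceptID`` infon.  Composite
    identifiers (containing ``|`` or ``+``) count as single verbatim
    values by default; ``split_composite`` counts their components
    separately.
    """
    n_docs = len(collection.documents)
    n_mentions = 0
    concepts: set[str] = set()
    for doc in collection.documents:
        for _, a in _mention_annotations(doc):
            n_mentions += 1
            cid = a.infons["ConceptID"]
            if split_composite:
                for part in cid.replace("+", "|").split("|"):
                    concepts.add(part)
            else:
                concepts.add(cid)
    return n_docs, n_mentions, len(concepts)
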