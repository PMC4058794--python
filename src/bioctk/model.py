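"""In-memory BioC data model.

BioC is a stand-off annotation interchange format: the text of a document
is carried once, and every annotation points back into it with a character
offset and length.  The hierarchy is

    collection -> document -> passage -> sentence -> annotation / relation

Offsets are 0-based counts of Unicode code points from the start of the
document's reconstructed text; spans are half-open ``[offset, offset+length)``.
Metadata is attached to any element as an ordered key->value "infon" map
(a plain dict; insertion order is preserved and round-trips through XML).

Document text reconstruction convention: the first passage starts at
offset 0 and each subsequent passage starts one character (a newline)
after the previous passage's text ends.  Within a passage that has been
segmented, each sentence's text is placed at its own offset and gaps are
whitespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import BioCRangeError

__all__ = [
    "BioCLocation",
    "BioCAnnotation",
    "BioCNode",
    "BioCRelation",
    "BioCSentence",
    "BioCPassage",
    "BioCDocument",
    "BioCCollection",
    "Violation",
    "document_text",
    "passage_text",
    "reconstruct_span",
    "validate_collection",
    "iter_annotations",
    "next_annotation_id",
    "next_relation_id",
]


@dataclass
class BioCLocation:
    """A span: ``offset`` code points from document start, ``length`` long."""

    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class BioCAnnotation:
    """A stand-off annotation: id, infons, one or more locations, and the
    surface text the locations cover."""

    id: str
    text: str = ""
    infons: dict[str, str] = field(default_factory=dict)
    locations: list[BioCLocation] = field(default_factory=list)

    @property
    def total_span(self) -> BioCLocation:
        start = min(l.offset for l in self.locations)
        end = max(l.end for l in self.locations)
        return BioCLocation(start, end - start)


@dataclass
class BioCNode:
    """A reference from a relation to an annotation, with a role label
    (``head``, ``dependent``, ``type``, ``shortform`` ...)."""

    refid: str
    role: str


@dataclass
class BioCRelation:
    """A typed link between two or more annotations."""

    id: str
    infons: dict[str, str] = field(default_factory=dict)
    nodes: list[BioCNode] = field(default_factory=list)


@dataclass
class BioCSentence:
    offset: int = 0
    text: str = ""
    infons: dict[str, str] = field(default_factory=dict)
    annotations: list[BioCAnnotation] = field(default_factory=list)
    relations: list[BioCRelation] = field(default_factory=list)


@dataclass
class BioCPassage:
    """A document subdivision (title, abstract, ...).

    Carries either ``text`` or a list of sentences (after segmentation),
    mirroring the BioC DTD.  ``text`` is set to ``None`` once sentences
    exist.
    """

    offset: int = 0
    text: str | None = None
    infons: dict[str, str] = field(default_factory=dict)
    sentences: list[BioCSentence] = field(default_factory=list)
    annotations: list[BioCAnnotation] = field(default_factory=list)
    relations: list[BioCRelation] = field(default_factory=list)

    @property
    def length(self) -> int:
        if self.sentences:
            return max(s.offset + len(s.text) for s in self.sentences) - self.offset
        return len(self.text or "")


@dataclass
class BioCDocument:
    id: str = ""
    infons: dict[str, str] = field(default_factory=dict)
    passages: list[BioCPassage] = field(default_factory=list)
    relations: list[BioCRelation] = field(default_factory=list)


@dataclass
class BioCCollection:
    source: str = ""
    date: str = ""
    key: str = ""
    infons: dict[str, str] = field(default_factory=dict)
    documents: list[BioCDocument] = field(default_factory=list)


@dataclass
class Violation:
    """One validation finding: where, which rule, and a human message."""

    path: str
    rule: str
    message: str


# ---------------------------------------------------------------------------
# text reconstruction


def passage_text(passage: BioCPassage) -> str:
    """The passage's text, rebuilt from sentences when it was segmented.

    Gaps between sentences are filled with spaces; sentence-internal
    whitespace is exact because each sentence keeps its original substring.
    """
    if passage.text is not None:
        return passage.text
    if not passage.sentences:
        return ""
    end = max(s.offset + len(s.text) for s in passage.sentences)
    buf = [" "] * (end - passage.offset)
    for s in passage.sentences:
        rel = s.offset - passage.offset
        buf[rel:rel + len(s.text)] = list(s.text)
    return "".join(buf)


def document_text(document: BioCDocument) -> str:
    """Reconstruct the document's full text from its passages.

    Passages are placed at their stored offsets; gap characters between
    them are newlines (one by convention).
    """
    if not document.passages:
        return ""
    end = max(p.offset + p.length for p in document.passages)
    buf = ["\n"] * end
    for p in document.passages:
        text = passage_text(p)
        buf[p.offset:p.offset + len(text)] = list(text)
    return "".join(buf)


def reconstruct_span(document: BioCDocument, location: BioCLocation) -> str:
    """Return the substring of the document's original text the location covers.

    Raises :class:`BioCRangeError` when the span falls outside the
    document's reconstructable extent.
    """
    text = document_text(document)
    if location.offset < 0 or location.length < 1 or location.end > len(text):
        raise BioCRangeError(
            f"location [{location.offset}, {location.end}) out of range for "
            f"document {document.id!r} of length {len(text)}"
        )
    return text[location.offset:location.end]


# ---------------------------------------------------------------------------
# traversal helpers


def iter_annotations(document: BioCDocument) -> Iterator[tuple[str, BioCAnnotation]]:
    """Yield (path, annotation) for every annotation in the document."""
    for ip, p in enumerate(document.passages):
        for ia, a in enumerate(p.annotations):
            yield f"passage[{ip}]/annotation[{ia}]", a
        for is_, s in enumerate(p.sentences):
            for ia, a in enumerate(s.annotations):
                yield f"passage[{ip}]/sentence[{is_}]/annotation[{ia}]", a


def _iter_relations(document: BioCDocument):
    for ip, p in enumerate(document.passages):
        for is_, s in enumerate(p.sentences):
            for ir, r in enumerate(s.relations):
                yield f"passage[{ip}]/sentence[{is_}]/relation[{ir}]", r
        for ir, r in enumerate(p.relations):
            yield f"passage[{ip}]/relation[{ir}]", r
    for ir, r in enumerate(document.relations):
        yield f"relation[{ir}]", r


def _max_numeric_suffix(ids: Iterator[str], prefix: str) -> int:
    best = 0
    for i in ids:
        if i.startswith(prefix) and i[len(prefix):].isdigit():
            best = max(best, int(i[len(prefix):]))
    return best


def next_annotation_id(document: BioCDocument) -> int:
    """Next free integer for the document's ``T<n>`` annotation id scheme."""
    return _max_numeric_suffix((a.id for _, a in iter_annotations(document)), "T") + 1


def next_relation_id(document: BioCDocument) -> int:
    """Next free integer for the document's ``R<n>`` relation id scheme."""
    return _max_numeric_suffix((r.id for _, r in _iter_relations(document)), "R") + 1


# ---------------------------------------------------------------------------
# validation


def _check_infons(infons: dict[str, str], path: str, out: list[Violation]) -> None:
    for k, v in infons.items():
        if not isinstance(k, str) or k == "":
            out.append(Violation(path, "infon_key", "infon key must be non-empty text"))
        if not isinstance(v, str) or v == "":
            out.append(Violation(path, "infon_value", f"infon {k!r} has empty value"))


def validate_collection(collection: BioCCollection) -> list[Violation]:
    """Check every structural invariant; return violations instead of raising.

    An empty list means the collection is valid: offsets agree with texts,
    ids are unique, relation nodes resolve, passages and sentences are
    ordered and non-overlapping.
    """
    out: list[Violation] = []
    _check_infons(collection.infons, "collection", out)

    seen_docs: set[str] = set()
    for idoc, doc in enumerate(collection.documents):
        dpath = f"document[{idoc}](id={doc.id})"
        if doc.id in seen_docs:
            out.append(Violation(dpath, "unique_document_id", f"duplicate document id {doc.id!r}"))
        seen_docs.add(doc.id)
        _check_infons(doc.infons, dpath, out)

        dtext = document_text(doc)

        prev_end = None
        for ip, p in enumerate(doc.passages):
            ppath = f"{dpath}/passage[{ip}]"
            _check_infons(p.infons, ppath, out)
            if p.offset < 0:
                out.append(Violation(ppath, "offset_range", f"negative passage offset {p.offset}"))
            if prev_end is not None and p.offset < prev_end:
                out.append(Violation(ppath, "passage_order",
                                     f"passage at {p.offset} overlaps or precedes previous end {prev_end}"))
            prev_end = p.offset + p.length

            s_prev_end = None
            for is_, s in enumerate(p.sentences):
                spath = f"{ppath}/sentence[{is_}]"
                _check_infons(s.infons, spath, out)
                if dtext[s.offset:s.offset + len(s.text)] != s.text:
                    out.append(Violation(spath, "sentence_text",
                                         "sentence text disagrees with document text at its offset"))
                if s_prev_end is not None and s.offset < s_prev_end:
                    out.append(Violation(spath, "sentence_order",
                                         f"sentence at {s.offset} overlaps or precedes previous end {s_prev_end}"))
                s_prev_end = s.offset + len(s.text)

        # annotations: unique ids, span/text agreement
        ann_ids: set[str] = set()
        for apath, a in iter_annotations(doc):
            full = f"{dpath}/{apath}(id={a.id})"
            _check_infons(a.infons, full, out)
            if a.id in ann_ids:
                out.append(Violation(full, "unique_annotation_id", f"duplicate annotation id {a.id!r}"))
            ann_ids.add(a.id)
            if not a.locations:
                out.append(Violation(full, "location_count", "annotation has no location"))
                continue
            bad_loc = False
            for loc in a.locations:
                if loc.offset < 0 or loc.length < 1:
                    out.append(Violation(full, "location_range",
                                         f"bad location (offset={loc.offset}, length={loc.length})"))
                    bad_loc = True
                elif loc.end > len(dtext):
                    out.append(Violation(full, "location_range",
                                         f"location [{loc.offset}, {loc.end}) beyond document end {len(dtext)}"))
                    bad_loc = True
            if bad_loc:
                continue
            if len(a.locations) == 1:
                loc = a.locations[0]
                if len(a.text) != loc.length:
                    out.append(Violation(full, "text_length",
                                         f"text length {len(a.text)} != location length {loc.length}"))
                elif dtext[loc.offset:loc.end] != a.text:
                    out.append(Violation(full, "span_text",
                                         f"document span reads {dtext[loc.offset:loc.end]!r}, "
                                         f"annotation text is {a.text!r}"))

        # relations: unique ids, resolvable nodes, >=2 nodes
        rel_ids: set[str] = set()
        for rpath, r in _iter_relations(doc):
            full = f"{dpath}/{rpath}(id={r.id})"
            _check_infons(r.infons, full, out)
            if r.id in rel_ids:
                out.append(Violation(full, "unique_relation_id", f"duplicate relation id {r.id!r}"))
            rel_ids.add(r.id)
            if len(r.nodes) < 2:
                out.append(Violation(full, "node_count", "relation has fewer than 2 nodes"))
            for node in r.nodes:
                if node.refid not in ann_ids:
                    out.append(Violation(full, "unresolved_refid",
                                         f"node refid {node.refid!r} resolves to no annotation"))
    return out
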