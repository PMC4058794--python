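"""BioC XML interchange: read, write, and the sidecar ``.key`` file.

The serialized layout follows the standard BioC element order
(``collection -> source, date, key, infon*, document*``; infons first in
every element, annotations before relations).  Output is deterministic so
that ``write(read(write(c)))`` is byte-identical to ``write(c)``, which
makes byte-level golden tests possible.
"""

from __future__ import annotations

from pathlib import Path
from typing import BinaryIO

from lxml import etree

from .errors import BioCFormatError, BioCParseError, BioCValidationError
from .model import (
    BioCAnnotation,
    BioCCollection,
    BioCDocument,
    BioCLocation,
    BioCNode,
    BioCPassage,
    BioCRelation,
    BioCSentence,
    validate_collection,
)

__all__ = ["read_collection", "write_collection", "write_key_file", "DEFAULT_KEY_ENTRIES"]


# ---------------------------------------------------------------------------
# reading


def _elem_path(elem) -> str:
    tree = elem.getroottree()
    try:
        return tree.getpath(elem)
    except Exception:  # pragma: no cover - getpath is robust in practice
        return elem.tag


def _read_infons(elem) -> dict[str, str]:
    infons: dict[str, str] = {}
    for inf in elem.findall("infon"):
        key = inf.get("key")
        if key is None:
            raise BioCFormatError(f"infon without key attribute at {_elem_path(inf)}")
        infons[key] = inf.text or ""
    return infons


def _req_text(elem, tag: str, default: str | None = None) -> str:
    child = elem.find(tag)
    if child is None:
        if default is not None:
            return default
        raise BioCFormatError(f"missing <{tag}> under {_elem_path(elem)}")
    return child.text or ""

def _int_attr(elem, name: str) -> int:
    value = elem.get(name)
    if value is None:
        raise BioCFormatError(f"<{elem.tag}> missing {name!r} attribute at {_elem_path(elem)}")
    try:
        return int(value)
    except ValueError:
        raise BioCFormatError(f"non-integer {name}={value!r} at {_elem_path(elem)}") from None


def _read_annotation(elem) -> BioCAnnotation:
    ann_id = elem.get("id", "")
    locations = [BioCLocation(_int_attr(l, "offset"), _int_attr(l, "length"))
                 for l in elem.findall("location")]
    if not locations:
        raise BioCFormatError(f"annotation {ann_id!r} without location at {_elem_path(elem)}")
    return BioCAnnotation(
        id=ann_id,
        infons=_read_infons(elem),
        locations=locations,
        text=_req_text(elem, "text", default=""),
    )


def _read_relation(elem) -> BioCRelation:
    return BioCRelation(
        id=elem.get("id", ""),
        infons=_read_infons(elem),
        nodes=[BioCNode(_int_or_str(n, "refid"), n.get("role", ""))
               for n in elem.findall("node")],
    )


def _int_or_str(elem, name: str) -> str:
    value = elem.get(name)
    if value is None:
        raise BioCFormatError(f"<node> missing {name!r} attribute at {_elem_path(elem)}")
    return value


def _read_sentence(elem) -> BioCSentence:
    return BioCSentence(
        offset=int(_req_text(elem, "offset")),
        text=_req_text(elem, "text", default=""),
        infons=_read_infons(elem),
        annotations=[_read_annotation(a) for a in elem.findall("annotation")],
        relations=[_read_relation(r) for r in elem.findall("relation")],
    )


def _read_passage(elem) -> BioCPassage:
    text_elem = elem.find("text")
    sentences = [_read_sentence(s) for s in elem.findall("sentence")]
    return BioCPassage(
        offset=int(_req_text(elem, "offset")),
        text=text_elem.text or "" if text_elem is not None else None,
        infons=_read_infons(elem),
        sentences=sentences,
        annotations=[_read_annotation(a) for a in elem.findall("annotation")],
        relations=[_read_relation(r) for r in elem.findall("relation")],
    )


def _read_document(elem) -> BioCDocument:
    return BioCDocument(
        id=_req_text(elem, "id"),
        infons=_read_infons(elem),
        passages=[_read_passage(p) for p in elem.findall("passage")],
        relations=[_read_relation(r) for r in elem.findall("relation")],
    )


def read_collection(source: str | bytes | Path | BinaryIO) -> BioCCollection:
    """Parse BioC XML into a :class:`BioCCollection`.

    ``source`` may be a path, XML bytes/text, or a binary file object.
    Malformed XML raises :class:`BioCParseError` with the line number;
    structural problems (e.g. a location without a length) raise
    :class:`BioCFormatError` naming the element path.
    """
    parser = etree.XMLParser(resolve_entities=False, no_network=True)
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source, parser)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"), parser)
        elif isinstance(source, (str, Path)):
            root = etree.parse(str(source), parser).getroot()
        else:
            root = etree.parse(source, parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise BioCParseError(str(exc.args[0] if exc.args else exc), line=exc.lineno) from exc

    if root.tag != "collection":
        raise BioCFormatError(f"root element is <{root.tag}>, expected <collection>")
    return BioCCollection(
        source=_req_text(root, "source", default=""),
        date=_req_text(root, "date", default=""),
        key=_req_text(root, "key", default=""),
        infons=_read_infons(root),
        documents=[_read_document(d) for d in root.findall("document")],
    )


# ---------------------------------------------------------------------------
# writing


def _add_text_elem(parent, tag: str, text: str) -> None:
    child = etree.SubElement(parent, tag)
    child.text = text


def _write_infons(parent, infons: dict[str, str]) -> None:
    for k, v in infons.items():
        inf = etree.SubElement(parent, "infon", key=k)
        inf.text = v


def _write_annotation(parent, a: BioCAnnotation) -> None:
    elem = etree.SubElement(parent, "annotation", id=a.id)
    _write_infons(elem, a.infons)
    for loc in a.locations:
        etree.SubElement(elem, "location", offset=str(loc.offset), length=str(loc.length))
    _add_text_elem(elem, "text", a.text)


def _write_relation(parent, r: BioCRelation) -> None:
    elem = etree.SubElement(parent, "relation", id=r.id)
    _write_infons(elem, r.infons)
    for node in r.nodes:
        etree.SubElement(elem, "node", refid=node.refid, role=node.role)


def _write_sentence(parent, s: BioCSentence) -> None:
    elem = etree.SubElement(parent, "sentence")
    _write_infons(elem, s.infons)
    _add_text_elem(elem, "offset", str(s.offset))
    _add_text_elem(elem, "text", s.text)
    for a in s.annotations:
        _write_annotation(elem, a)
    for r in s.relations:
        _write_relation(elem, r)


def _write_passage(parent, p: BioCPassage) -> None:
    elem = etree.SubElement(parent, "passage")
    _write_infons(elem, p.infons)
    _add_text_elem(elem, "offset", str(p.offset))
    if p.text is not None:
        _add_text_elem(elem, "text", p.text)
    for s in p.sentences:
        _write_sentence(elem, s)
    for a in p.annotations:
        _write_annotation(elem, a)
    for r in p.relations:
        _write_relation(elem, r)


def write_collection(collection: BioCCollection, destination=None) -> bytes:
    """Serialize a collection to UTF-8 BioC XML bytes.

    The collection must validate; otherwise :class:`BioCValidationError`
    is raised listing the violations.  ``destination`` may be a path or a
    binary file object; the bytes are returned either way.
    """
    violations = validate_collection(collection)
    if violations:
        raise BioCValidationError(violations)

    root = etree.Element("collection")
    _add_text_elem(root, "source", collection.source)
    _add_text_elem(root, "date", collection.date)
    _add_text_elem(root, "key", collection.key)
    _write_infons(root, collection.infons)
    for doc in collection.documents:
        delem = etree.SubElement(root, "document")
        _add_text_elem(delem, "id", doc.id)
        _write_infons(delem, doc.infons)
        for p in doc.passages:
            _write_passage(delem, p)
        for r in doc.relations:
            _write_relation(delem, r)

    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True,
        doctype='<!DOCTYPE collection SYSTEM "BioC.dtd">',
    )
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_bytes(data)
        else:
            destination.write(data)
    return data


# ---------------------------------------------------------------------------
# key file

#: infon keys the shipped pipeline emits, with one-line descriptions
DEFAULT_KEY_ENTRIES: list[tuple[str, str]] = [
    ("POS", "Penn Treebank part-of-speech tag of a token annotation"),
    ("lemma", "lowercased dictionary base form of the token, given its POS"),
    ("parse_tree", "flat Penn-Treebank-style bracket string for the sentence"),
    ("relation", "dependency label of a head->dependent relation"),
    ("initial_gr", "initial grammatical relation, when the parser provides one"),
    ("root", "annotation id of the sentence's dependency root token"),
    ("type", "annotation class marker (e.g. ABBR for abbreviation forms)"),
    ("role", "abbreviation role of an ABBR annotation: shortform or longform"),
    ("EntityType", "disease mention category from the source corpus"),
    ("Nomenclature", "terminology resource of the concept id: MeSH or OMIM"),
    ("ConceptID", "unique concept identifier of the mention (verbatim)"),
    ("tagset", "name of the POS tag set used by the collection"),
    ("pipeline_stages", "comma-separated preprocessing stages applied"),
]


def write_key_file(collection: BioCCollection,
                   entries: list[tuple[str, str]] | None = None,
                   destination=None) -> str:
    """Render the sidecar key file documenting the collection's infon keys.

    Duplicate keys keep the last description; one line per key.  Returns
    the text; optionally writes it to ``destination`` (path or text file).
    """
    if entries is None:
        entries = DEFAULT_KEY_ENTRIES
    dedup: dict[str, str] = {}
    for key, desc in entries:
        dedup[key] = desc
    lines = [
        f"# Key file for BioC collection {collection.source!r}" if collection.source
        else "# Key file",
        "# Documents the semantics of infon keys used in this collection.",
        "",
    ]
    lines += [f"{key}\t{desc}" for key, desc in dedup.items()]
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text, encoding="utf-8")
        else:
            destination.write(text)
    return text
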