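"""Stage-by-stage diff of two annotated BioC collections.

Pipelines built on different tool sets (or configurations) should agree
on sentence boundaries and mostly agree on tokens; this module measures
exactly where they differ.  Comparison is by character offsets, never by
annotation ids, so collections produced by independent implementations
with different id schemes remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ComparisonError
from .model import BioCCollection, BioCDocument

__all__ = ["DiffDetail", "DiffReport", "compare_collections"]


@dataclass(frozen=True)
class DiffDetail:
    """One mismatch: where it is and what each side says ('-' = absent)."""

    document_id: str
    coordinate: str
    left: str
    right: str


@dataclass
class DiffReport:
    """Per-stage mismatch details; counts are the lengths of the lists."""

    sentence_details: list[DiffDetail] = field(default_factory=list)
    token_details: list[DiffDetail] = field(default_factory=list)
    pos_details: list[DiffDetail] = field(default_factory=list)
    relation_details: list[DiffDetail] = field(default_factory=list)

    @property
    def sentence_boundary_mismatches(self) -> int:
        return len(self.sentence_details)

    @property
    def token_span_mismatches(self) -> int:
        return len(self.token_details)

    @property
    def pos_mismatches(self) -> int:
        return len(self.pos_details)

    @property
    def relation_mismatches(self) -> int:
        return len(self.relation_details)

    @property
    def total(self) -> int:
        return (self.sentence_boundary_mismatches + self.token_span_mismatches
                + self.pos_mismatches + self.relation_mismatches)

    def to_tsv(self) -> str:
        """Detail report: stage, document, coordinate, left, right."""
        lines = ["stage\tdocument\tcoordinate\tleft\tright"]
        for stage, details in [("sentence", self.sentence_details),
                               ("token", self.token_details),
                               ("pos", self.pos_details),
                               ("relation", self.relation_details)]:
            for d in details:
                lines.append(f"{stage}\t{d.document_id}\t{d.coordinate}\t{d.left}\t{d.right}")
        return "\n".join(lines) + "\n"


def _sentence_spans(doc: BioCDocument) -> set[tuple[int, int]]:
    return {(s.offset, len(s.text)) for p in doc.passages for s in p.sentences}


def _token_map(doc: BioCDocument) -> dict[tuple[int, int], str | None]:
    """Token span -> POS (or None).  Tokens are sentence-level annotations
    that are not abbreviation-pair annotations."""
    out: dict[tuple[int, int], str | None] = {}
    for p in doc.passages:
        for s in p.sentences:
            for a in s.annotations:
                if a.infons.get("type") == "ABBR":
                    continue
                loc = a.locations[0]
                out[(loc.offset, loc.length)] = a.infons.get("POS")
    return out


def _relation_set(doc: BioCDocument) -> set[tuple[tuple[int, int], tuple[int, int], str]]:
    """Relations as (head span, dependent span, label) triples."""
    out = set()
    for p in doc.passages:
        for s in p.sentences:
            spans = {a.id: (a.locations[0].offset, a.locations[0].length)
                     for a in s.annotations}
            for r in s.relations:
                roles = {n.role: n.refid for n in r.nodes}
                if "head" in roles and "dependent" in roles:
                    head = spans.get(roles["head"])
                    dep = spans.get(roles["dependent"])
                    if head and dep:
                        out.add((head, dep, r.infons.get("relation", "")))
    return out


def _set_diff(doc_id: str, left: set, right: set, fmt) -> list[DiffDetail]:
    details = []
    for item in sorted(left - right):
        details.append(DiffDetail(doc_id, fmt(item), fmt(item), "-"))
    for item in sorted(right - left):
        details.append(DiffDetail(doc_id, fmt(item), "-", fmt(item)))
    return details


def compare_collections(a: BioCCollection, b: BioCCollection) -> DiffReport:
    """Diff two collections over the same documents.

    Sentences and tokens are compared as ``(offset, length)`` sets per
    document; POS tags only on tokens whose spans match exactly on both
    sides; dependency relations as (head span, dependent span, label)
    triples.  Symmetric: swapping the arguments swaps left/right in the
    details but preserves every count.  Document ids present on one side
    only raise :class:`ComparisonError`.
    """
    ids_a = {d.id for d in a.documents}
    ids_b = {d.id for d in b.documents}
    if ids_a != ids_b:
        only = sorted(ids_a.symmetric_difference(ids_b))
        raise ComparisonError(
            f"collections cover different documents: {only}")

    docs_b = {d.id: d for d in b.documents}
    report = DiffReport()
    span_fmt = lambda s: f"[{s[0]},{s[0] + s[1]})"
    for doc_a in a.documents:
        doc_b = docs_b[doc_a.id]
        report.sentence_details += _set_diff(
            doc_a.id, _sentence_spans(doc_a), _sentence_spans(doc_b), span_fmt)

        toks_a = _token_map(doc_a)
        toks_b = _token_map(doc_b)
        report.token_details += _set_diff(
            doc_a.id, set(toks_a), set(toks_b), span_fmt)
        for span in sorted(set(toks_a) & set(toks_b)):
            pa, pb = toks_a[span], toks_b[span]
            if pa != pb and not (pa is None and pb is None):
                report.pos_details.append(DiffDetail(
                    doc_a.id, span_fmt(span), pa or "-", pb or "-"))

        report.relation_details += _set_diff(
            doc_a.id, _relation_set(doc_a), _relation_set(doc_b),
            lambda t: f"{span_fmt(t[0])}->{span_fmt(t[1])}:{t[2]}")
    return report
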