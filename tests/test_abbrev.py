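"""Abbreviation definition detection."""

import pytest

from bioctk.abbrev import annotate_abbreviations, find_abbreviations
from bioctk.model import (
    BioCCollection,
    BioCDocument,
    BioCPassage,
    BioCSentence,
    reconstruct_span,
    validate_collection,
)
from bioctk.segment import segment


def _sentence(text: str, offset: int = 0) -> BioCSentence:
    return BioCSentence(offset=offset, text=text)


@pytest.mark.parametrize("text,short,long", [
    ("Online Mendelian Inheritance in Man (OMIM)",
     "OMIM", "Online Mendelian Inheritance in Man"),
    ("Medical Subject Headings (MeSH)",
     "MeSH", "Medical Subject Headings"),
    ("the adenomatous polyposis coli (APC) gene",
     "APC", "adenomatous polyposis coli"),
    ("treated with polymerase chain reaction (PCR) methods",
     "PCR", "polymerase chain reaction"),
])
def test_definition_pairs_found(text, short, long):
    pairs = find_abbreviations(_sentence(text))
    assert [(p.short_form, p.long_form) for p in pairs] == [(short, long)]


@pytest.mark.parametrize("text", [
    "a value (12.5) was seen",          # no letter / numeric short form
    "a long parenthetical (this is far too long to be an abbreviation)",
    "mismatch of letters (XYZ) entirely",
    "(OMIM) with nothing before it",
    "no parentheses at all",
])
def test_non_definitions_rejected(text):
    assert find_abbreviations(_sentence(text)) == []


def test_offsets_are_document_coordinates():
    text = "It uses Medical Subject Headings (MeSH) terms."
    sentence = _sentence(text, offset=50)
    pair = find_abbreviations(sentence)[0]
    assert pair.short_location.offset == 50 + text.index("MeSH")
    assert pair.long_location.offset == 50 + text.index("Medical")
    assert pair.long_location.length == len("Medical Subject Headings")


def test_long_form_contains_short_form_characters_in_order():
    text = ("Patients with insulin-dependent diabetes mellitus (IDDM) and "
            "Online Mendelian Inheritance in Man (OMIM) entries.")
    for pair in find_abbreviations(_sentence(text)):
        long_lower = pair.long_form.lower()
        idx = 0
        for ch in pair.short_form.lower():
            if not ch.isalnum():
                continue
            idx = long_lower.find(ch, idx)
            assert idx >= 0, (pair.short_form, pair.long_form)
            idx += 1


def test_innermost_parentheses_only():
    pairs = find_abbreviations(
        _sentence("the Medical Subject Headings (thesaurus (MeSH)) list"))
    assert [p.short_form for p in pairs] == ["MeSH"]


class TestAnnotatePassage:
    def _passage(self, text: str) -> BioCPassage:
        return BioCPassage(offset=0, sentences=segment(text, 0))

    def test_one_definition_two_annotations_one_relation(self):
        passage = self._passage(
            "See Online Mendelian Inheritance in Man (OMIM).")
        annotate_abbreviations(passage)
        sentence = passage.sentences[0]
        abbr = [a for a in sentence.annotations if a.infons.get("type") == "ABBR"]
        assert len(abbr) == 2
        assert {a.infons["role"] for a in abbr} == {"shortform", "longform"}
        assert len(sentence.relations) == 1
        assert {n.role for n in sentence.relations[0].nodes} == {
            "shortform", "longform"}

    def test_no_parentheses_unchanged(self):
        passage = self._passage("Nothing to detect here.")
        before = sum(len(s.annotations) for s in passage.sentences)
        annotate_abbreviations(passage)
        assert sum(len(s.annotations) for s in passage.sentences) == before

    def test_two_definitions_four_annotations_two_relations(self):
        passage = self._passage(
            "We use Medical Subject Headings (MeSH) and the separate "
            "polymerase chain reaction (PCR) method.")
        annotate_abbreviations(passage)
        abbr = [a for s in passage.sentences for a in s.annotations
                if a.infons.get("type") == "ABBR"]
        rels = [r for s in passage.sentences for r in s.relations]
        assert len(abbr) == 4
        assert len(rels) == 2

    def test_annotated_passage_validates_and_spans_reconstruct(self):
        passage = self._passage(
            "Data from Online Mendelian Inheritance in Man (OMIM) was used.")
        annotate_abbreviations(passage)
        doc = BioCDocument(id="d", passages=[passage])
        collection = BioCCollection(source="s", date="2014-01-01", key="k",
                                    documents=[doc])
        assert validate_collection(collection) == []
        for s in passage.sentences:
            for a in s.annotations:
                assert reconstruct_span(doc, a.locations[0]) == a.text
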