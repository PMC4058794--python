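"""PubTator parsing and PubTator <-> BioC conversion."""

import pytest

from bioctk.errors import ConversionError, PubTatorFormatError
from bioctk.fixtures import generate_corpus
from bioctk.model import reconstruct_span, validate_collection
from bioctk.pubtator import (
    Mention,
    PubTatorDocument,
    bioc_to_pubtator,
    corpus_stats,
    parse_pubtator,
    pubtator_to_bioc,
)

TOY = ("123|t|Colon cancer risk.\n"
       "123|a|We studied it.\n"
       "123\t0\t12\tColon cancer\tSpecificDisease\tD003110\n")


class TestParse:
    def test_toy_block(self):
        docs = parse_pubtator(TOY)
        assert len(docs) == 1
        doc = docs[0]
        assert (doc.pmid, doc.title, doc.abstract) == (
            "123", "Colon cancer risk.", "We studied it.")
        assert doc.mentions == [
            Mention(0, 12, "Colon cancer", "SpecificDisease", "D003110")]

    def test_empty_stream(self):
        assert parse_pubtator("") == []

    def test_span_text_mismatch_cites_pmid_and_line(self):
        bad = TOY.replace("Colon cancer\tSpecific", "Colon cance\tSpecific")
        with pytest.raises(PubTatorFormatError, match="pmid 123.*line 3"):
            parse_pubtator(bad)

    def test_missing_title_line(self):
        with pytest.raises(PubTatorFormatError, match="title"):
            parse_pubtator("123|a|Abstract without title.\n")

    def test_abstract_mention_coordinates(self):
        text = ("9|t|Short title.\n"
                "9|a|Colon cancer was studied.\n"
                "9\t13\t25\tColon cancer\tSpecificDisease\tD003110\n")
        doc = parse_pubtator(text)[0]
        assert doc.full_text[13:25] == "Colon cancer"


class TestToBioC:
    def test_toy_conversion(self):
        collection = pubtator_to_bioc(parse_pubtator(TOY),
                                      collection_date="2014-01-01")
        doc = collection.documents[0]
        assert [p.offset for p in doc.passages] == [0, 19]
        ann = doc.passages[0].annotations[0]
        assert (ann.locations[0].offset, ann.locations[0].length) == (0, 12)
        assert ann.text == "Colon cancer"
        assert ann.infons == {"EntityType": "SpecificDisease",
                              "Nomenclature": "MeSH",
                              "ConceptID": "D003110"}
        assert validate_collection(collection) == []

    def test_omim_prefix_sets_nomenclature(self):
        text = ("5|t|An OMIM case.\n"
                "5|a|None here.\n"
                "5\t3\t7\tOMIM\tSpecificDisease\tOMIM:143100\n")
        collection = pubtator_to_bioc(parse_pubtator(text),
                                      collection_date="2014-01-01")
        ann = collection.documents[0].passages[0].annotations[0]
        assert ann.infons["Nomenclature"] == "OMIM"

    def test_no_mentions_two_passages(self):
        collection = pubtator_to_bioc(
            [PubTatorDocument(pmid="1", title="T.", abstract="A.")],
            collection_date="2014-01-01")
        doc = collection.documents[0]
        assert len(doc.passages) == 2
        assert sum(len(p.annotations) for p in doc.passages) == 0

    def test_boundary_straddling_mention_rejected(self):
        doc = PubTatorDocument(pmid="1", title="AB", abstract="CD", mentions=[
            Mention(1, 4, "B\nC", "DiseaseClass", "D000001")])
        with pytest.raises(PubTatorFormatError, match="straddle"):
            pubtator_to_bioc([doc])

    def test_mention_spans_reconstruct_from_document(self):
        text, _ = generate_corpus(15, 3)
        collection = pubtator_to_bioc(parse_pubtator(text),
                                      collection_date="2014-01-01")
        n = 0
        for doc in collection.documents:
            for p in doc.passages:
                for a in p.annotations:
                    assert reconstruct_span(doc, a.locations[0]) == a.text
                    n += 1
        assert n > 10


class TestRoundTrip:
    def test_toy_round_trip(self):
        docs = parse_pubtator(TOY)
        back = parse_pubtator(bioc_to_pubtator(
            pubtator_to_bioc(docs, collection_date="2014-01-01")))
        assert back == docs

    @pytest.mark.parametrize("seed", [0, 13, 99])
    def test_fixture_corpus_round_trip(self, seed):
        text, _ = generate_corpus(100, seed)
        docs = parse_pubtator(text)
        back = parse_pubtator(bioc_to_pubtator(
            pubtator_to_bioc(docs, collection_date="2014-01-01")))
        assert back == docs

    def test_token_annotations_are_skipped(self, annotated_collection):
        """The inverse converter emits mentions only, ignoring tokens."""
        docs = parse_pubtator(bioc_to_pubtator(annotated_collection))
        _, n_mentions, _ = corpus_stats(annotated_collection)
        assert sum(len(d.mentions) for d in docs) == n_mentions

    def test_missing_concept_id_is_conversion_error(self):
        collection = pubtator_to_bioc(parse_pubtator(TOY),
                                      collection_date="2014-01-01")
        ann = collection.documents[0].passages[0].annotations[0]
        del ann.infons["ConceptID"]
        with pytest.raises(ConversionError, match="ConceptID"):
            bioc_to_pubtator(collection)


class TestStats:
    def test_empty_collection(self):
        from bioctk.model import BioCCollection
        assert corpus_stats(BioCCollection()) == (0, 0, 0)

    def test_by_construction(self):
        blocks = []
        for i in range(10):
            pmid = str(i)
            blocks.append(f"{pmid}|t|Colon cancer risk.\n{pmid}|a|More.\n")
            for j in range(3):
                cid = f"D00000{j % 5}"
                blocks.append(f"{pmid}\t0\t12\tColon cancer\tModifier\t{cid}\n")
            blocks.append("\n")
        collection = pubtator_to_bioc(parse_pubtator("".join(blocks)),
                                      collection_date="2014-01-01")
        assert corpus_stats(collection) == (10, 30, 3)

    def test_matches_generator_ground_truth(self):
        text, truth = generate_corpus(100, 42)
        collection = pubtator_to_bioc(parse_pubtator(text),
                                      collection_date="2014-01-01")
        assert corpus_stats(collection) == truth

    def test_split_composite_counts_components(self):
        text = ("7|t|Colon cancer risk.\n"
                "7|a|None.\n"
                "7\t0\t12\tColon cancer\tCompositeMention\tD000001|D000002\n")
        collection = pubtator_to_bioc(parse_pubtator(text),
                                      collection_date="2014-01-01")
        assert corpus_stats(collection)[2] == 1
        assert corpus_stats(collection, split_composite=True)[2] == 2
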