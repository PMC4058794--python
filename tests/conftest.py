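import pytest

from bioctk.fixtures import generate_corpus
from bioctk.pipeline import run_pipeline
from bioctk.pubtator import parse_pubtator, pubtator_to_bioc

FIXED_DATE = "2014-01-01"


def corpus_collection(n_docs: int, seed: int):
    """Generated PubTator corpus converted to BioC (deterministic)."""
    text, truth = generate_corpus(n_docs, seed)
    collection = pubtator_to_bioc(parse_pubtator(text), source="fixture",
                                  collection_date=FIXED_DATE)
    return collection, truth


@pytest.fixture(scope="session")
def fixture_collection():
    """A 20-document converted corpus (mentions only, no pipeline output)."""
    return corpus_collection(20, 42)[0]


@pytest.fixture(scope="session")
def annotated_collection(fixture_collection):
    """The fixture corpus with every pipeline stage applied."""
    return run_pipeline(
        fixture_collection,
        ["sentence", "token", "pos", "lemma", "parse", "abbrev"])
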