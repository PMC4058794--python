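"""Sentence segmentation and invertible tokenization."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from bioctk.model import BioCSentence
from bioctk.segment import TokenizerConfig, detokenize, segment, tokenize

FAMILIAL = ("Familial deficiency of the seventh component of complement "
            "associated with recurrent bacteremic infections due to Neisseria")


class TestSegment:
    def test_two_sentences_with_offsets(self):
        sentences = segment("A cat. A dog.", 0)
        assert [(s.offset, s.text) for s in sentences] == [
            (0, "A cat."), (7, "A dog.")]

    def test_single_headline_sentence(self):
        assert len(segment(FAMILIAL, 0)) == 1

    def test_abbreviation_suppresses_boundary(self):
        assert len(segment("Dr. Smith was ill.", 0)) == 1

    def test_without_abbreviation_list_splits(self):
        config = TokenizerConfig(abbreviation_list=frozenset())
        assert len(segment("Dr. Smith was ill.", 0, config)) == 2

    def test_empty_and_whitespace_input(self):
        assert segment("", 0) == []
        assert segment("   \t ", 0) == []

    def test_passage_offset_propagates(self):
        sentences = segment("A cat. A dog.", 100)
        assert [s.offset for s in sentences] == [100, 107]

    def test_lowercase_continuation_not_a_boundary(self):
        assert len(segment("It was approx. five cases.", 0)) == 1

    def test_decimal_number_not_a_boundary(self):
        assert len(segment("A rate of 12.5 was seen. Next sentence.", 0)) == 2

    def test_determinism(self):
        text = "One thing.  Another  thing!   A third?"
        assert segment(text, 0) == segment(text, 0)

    def test_sentences_cover_all_non_whitespace(self):
        text = "First one.   Second  one!  Third one? Tail without stop"
        sentences = segment(text, 0)
        covered = set()
        for s in sentences:
            covered.update(range(s.offset, s.offset + len(s.text)))
            assert text[s.offset:s.offset + len(s.text)] == s.text
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered


class TestTokenize:
    def test_familial_sentence_token_count(self):
        sentence = segment(FAMILIAL, 0)[0]
        tokens = tokenize(sentence)
        assert len(tokens) == 16
        assert (tokens[0].locations[0].offset, tokens[0].text) == (0, "Familial")
        assert tokens[-1].text == "Neisseria"

    @pytest.mark.parametrize("split,expected", [
        (False, ["beta-thalassemia"]),
        (True, ["beta", "-", "thalassemia"]),
    ])
    def test_hyphen_config(self, split, expected):
        sentence = BioCSentence(offset=0, text="beta-thalassemia")
        config = TokenizerConfig(split_hyphen=split)
        assert [t.text for t in tokenize(sentence, config)] == expected

    def test_slash_config(self):
        sentence = BioCSentence(offset=0, text="HbA/HbF")
        assert [t.text for t in tokenize(sentence)] == ["HbA/HbF"]
        config = TokenizerConfig(split_slash=True)
        assert [t.text for t in tokenize(sentence, config)] == ["HbA", "/", "HbF"]

    def test_empty_sentence(self):
        assert tokenize(BioCSentence(offset=0, text="")) == []

    def test_punctuation_becomes_separate_tokens(self):
        sentence = BioCSentence(offset=0, text="Low risk (n=3), see text.")
        texts = [t.text for t in tokenize(sentence)]
        assert texts == ["Low", "risk", "(", "n=3", ")", ",", "see", "text", "."]

    def test_sentence_final_abbreviation_period_stays_attached(self):
        sentence = BioCSentence(offset=0, text="described by Smith et al.")
        assert [t.text for t in tokenize(sentence)][-1] == "al."

    def test_tokens_within_sentence_span(self):
        sentence = segment("A cat. A dog.", 50)[1]
        for tok in tokenize(sentence):
            loc = tok.locations[0]
            assert sentence.offset <= loc.offset
            assert loc.offset + loc.length <= sentence.offset + len(sentence.text)


# word pool for random invertibility texts: multi-space runs, unicode,
# hyphens, slashes, parens, numbers
_token_st = st.sampled_from(
    ["alpha", "β-globin", "naïve", "x/y", "12.5", "(OMIM)", "e.g.", "A",
     "gene,", "risk.", "Neisseria", "--", "..."])
_gap_st = st.sampled_from([" ", "  ", "   ", "\t", " \t "])


@st.composite
def _texts(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    words = [draw(_token_st) for _ in range(n)]
    gaps = [draw(_gap_st) for _ in range(n - 1)]
    parts = [words[0]]
    for gap, word in zip(gaps, words[1:]):
        parts += [gap, word]
    return "".join(parts)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(text=_texts(), split_hyphen=st.booleans(), split_slash=st.booleans())
def test_tokenization_is_invertible(text, split_hyphen, split_slash):
    """Interleaving token texts with the original gap characters
    reproduces the sentence byte-for-byte, for any config."""
    config = TokenizerConfig(split_hyphen=split_hyphen, split_slash=split_slash)
    sentence = BioCSentence(offset=0, text=text)
    tokens = tokenize(sentence, config)
    assert detokenize(sentence, tokens) == text


def test_detokenize_rejects_broken_offsets():
    sentence = BioCSentence(offset=0, text="two words")
    tokens = tokenize(sentence)
    tokens[1].locations[0].offset += 1
    with pytest.raises(ValueError):
        detokenize(sentence, tokens)


def test_config_requires_sentence_end_chars():
    with pytest.raises(ValueError):
        TokenizerConfig(sentence_end_chars=frozenset())
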