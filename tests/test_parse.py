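"""Dependency-parse encoding, decoding and DOT export."""

import pytest
from hypothesis import given, settings, strategies as st

from bioctk.errors import BioCFormatError, ContractError
from bioctk.model import BioCSentence
from bioctk.parse import (
    DependencyEdge,
    ParseResult,
    decode_parse,
    encode_parse,
    naive_dependencies,
    to_dot,
)
from bioctk.segment import tokenize


def _token_sentence(text: str) -> BioCSentence:
    sentence = BioCSentence(offset=0, text=text)
    sentence.annotations = tokenize(sentence)
    return sentence


class TestEncode:
    def test_two_token_nn_edge(self):
        sentence = _token_sentence("Neisseria infections")
        encode_parse(sentence, ParseResult(
            dependencies=[DependencyEdge(head=1, dependent=0, label="nn")]))
        assert len(sentence.relations) == 1
        rel = sentence.relations[0]
        assert rel.infons["relation"] == "nn"
        assert [(n.refid, n.role) for n in rel.nodes] == [
            ("T2", "head"), ("T1", "dependent")]

    def test_type_token_adds_third_node(self):
        sentence = _token_sentence("deficiency of complement")
        encode_parse(sentence, ParseResult(dependencies=[
            DependencyEdge(head=0, dependent=2, label="iobj", type_token=1,
                           initial_gr="iobj")]))
        rel = sentence.relations[0]
        assert [n.role for n in rel.nodes] == ["head", "dependent", "type"]
        assert rel.infons["initial_gr"] == "iobj"

    def test_tree_only(self):
        sentence = _token_sentence("a b")
        encode_parse(sentence, ParseResult(tree="(S (NN a) (NN b))"))
        assert sentence.relations == []
        assert sentence.infons["parse_tree"] == "(S (NN a) (NN b))"

    def test_root_infon_set(self):
        sentence = _token_sentence("one two three")
        encode_parse(sentence, naive_dependencies(sentence.annotations))
        assert sentence.infons["root"] == sentence.annotations[-1].id

    @pytest.mark.parametrize("edge", [
        DependencyEdge(head=5, dependent=0, label="x"),
        DependencyEdge(head=0, dependent=0, label="x"),
    ])
    def test_bad_edges_rejected(self, edge):
        sentence = _token_sentence("a b")
        with pytest.raises(ContractError):
            encode_parse(sentence, ParseResult(dependencies=[edge]))


class TestDecode:
    def test_no_relations_empty_edges(self):
        sentence = _token_sentence("just tokens here")
        assert decode_parse(sentence) == ParseResult(tree=None, dependencies=[])

    def test_three_relations_decode(self):
        sentence = _token_sentence("a b c d")
        edges = [DependencyEdge(3, 0, "det"), DependencyEdge(3, 1, "amod"),
                 DependencyEdge(3, 2, "nn")]
        encode_parse(sentence, ParseResult(dependencies=edges))
        assert decode_parse(sentence).dependencies == edges

    def test_unresolved_refid_is_format_error(self):
        sentence = _token_sentence("a b")
        encode_parse(sentence, ParseResult(
            dependencies=[DependencyEdge(1, 0, "dep")]))
        sentence.relations[0].nodes[0].refid = "T99"
        with pytest.raises(BioCFormatError):
            decode_parse(sentence)


class TestNaiveChain:
    @pytest.mark.parametrize("text,n_edges", [
        ("one", 0), ("one two three", 2), ("a b c d e f", 5)])
    def test_chain_edge_count(self, text, n_edges):
        tokens = tokenize(BioCSentence(offset=0, text=text))
        parse = naive_dependencies(tokens)
        assert len(parse.dependencies) == n_edges
        assert all(e.head == e.dependent + 1 and e.label == "dep"
                   for e in parse.dependencies)

    def test_requires_tokens(self):
        with pytest.raises(ValueError):
            naive_dependencies([])


_edges_st = st.integers(min_value=2, max_value=8).flatmap(
    lambda n: st.lists(
        st.tuples(st.integers(0, n - 1), st.integers(0, n - 1),
                  st.sampled_from(["nn", "det", "dobj", "ncmod"]),
                  st.one_of(st.none(), st.integers(0, n - 1)),
                  st.one_of(st.none(), st.sampled_from(["iobj", "xcomp"])))
        .filter(lambda t: t[0] != t[1]),
        max_size=6).map(lambda edges: (n, edges)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(spec=_edges_st, tree=st.one_of(st.none(), st.just("(S)")))
def test_encode_decode_round_trip(spec, tree):
    """decode(encode(s, p)) == p for random ParseResults."""
    n, raw = spec
    sentence = _token_sentence(" ".join(f"w{i}" for i in range(n)))
    parse = ParseResult(tree=tree, dependencies=[
        DependencyEdge(h, d, lab, tt, gr) for h, d, lab, tt, gr in raw])
    encode_parse(sentence, parse)
    assert decode_parse(sentence) == parse


class TestDot:
    def test_no_relations_no_edges(self):
        dot = to_dot(_token_sentence("alpha beta"))
        assert "->" not in dot
        assert dot.startswith("digraph")

    def test_edge_with_label(self):
        sentence = _token_sentence("Neisseria infections")
        encode_parse(sentence, ParseResult(
            dependencies=[DependencyEdge(head=1, dependent=0, label="nn")]))
        dot = to_dot(sentence)
        assert 'T2 -> T1 [label="nn"];' in dot
        assert 'T1 [label="Neisseria"];' in dot

    def test_parser_source_independence(self):
        """Identical edges from different ParseResult objects (different
        trees, different construction order) give identical DOT."""
        def build(tree):
            sentence = _token_sentence("Neisseria infections occur")
            encode_parse(sentence, ParseResult(tree=tree, dependencies=[
                DependencyEdge(1, 0, "nn"), DependencyEdge(2, 1, "nsubj")]))
            return sentence

        assert to_dot(build(None)) == to_dot(build("(S (NP x))"))

    def test_duplicate_surface_words_stay_distinct_nodes(self):
        sentence = _token_sentence("gene gene")
        encode_parse(sentence, ParseResult(
            dependencies=[DependencyEdge(1, 0, "nn")]))
        dot = to_dot(sentence)
        assert dot.count('[label="gene"]') == 2
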