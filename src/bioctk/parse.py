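"""Encode parser output as BioC relations and decode it back; DOT export.

A parse of a sentence has two parts: an optional flat Penn-Treebank-style
bracket string (stored verbatim in the sentence infon ``parse_tree``) and
a list of labeled dependency edges between tokens.  Each edge becomes one
BioC relation whose nodes reference the participating token annotations
by id, with roles ``head`` and ``dependent``; Briscoe & Carroll-style
grammatical relations may carry a third *type* token (role ``type``) and
an ``initial_gr`` value, which is preserved as a relation infon.

Because the encoding lives entirely in the BioC representation, the DOT
exporter works on relations produced by *any* parser — it never sees the
parser itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import BioCFormatError, ContractError
from .model import BioCAnnotation, BioCNode, BioCRelation, BioCSentence

__all__ = ["DependencyEdge", "ParseResult", "encode_parse", "decode_parse",
           "naive_dependencies", "to_dot",
           "PARSE_TREE_KEY", "RELATION_KEY", "INITIAL_GR_KEY", "ROOT_KEY"]

PARSE_TREE_KEY = "parse_tree"
RELATION_KEY = "relation"
INITIAL_GR_KEY = "initial_gr"
ROOT_KEY = "root"


@dataclass(frozen=True)
class DependencyEdge:
    """One labeled dependency: token indices into the sentence's token list."""

    head: int
    dependent: int
    label: str
    type_token: int | None = None
    initial_gr: str | None = None


@dataclass
class ParseResult:
    """Constituent tree (flat bracket string, optional) plus dependency edges."""

    tree: str | None = None
    dependencies: list[DependencyEdge] = field(default_factory=list)


def _tokens_in_order(sentence: BioCSentence) -> list[BioCAnnotation]:
    # abbreviation-pair annotations are not tokens
    return sorted((a for a in sentence.annotations
                   if a.infons.get("type") != "ABBR"),
                  key=lambda a: a.locations[0].offset)


def encode_parse(sentence: BioCSentence, parse: ParseResult,
                 relation_id_start: int = 1) -> BioCSentence:
    """Store a parse on the sentence as infons and relations, in place.

    Tokens are the sentence's annotations in offset order; edge indices
    refer into that list.  Relations get ids ``R<relation_id_start>``
    onward.  A single dependency root (a token with no incoming edge) is
    recorded in the sentence infon ``root``.  Out-of-range or self-loop
    edges raise :class:`ContractError`.
    """
    tokens = _tokens_in_order(sentence)
    n = len(tokens)
    if parse.tree is not None:
        sentence.infons[PARSE_TREE_KEY] = parse.tree
    next_id = relation_id_start
    has_incoming: set[int] = set()
    for edge in parse.dependencies:
        indices = [edge.head, edge.dependent]
        if edge.type_token is not None:
            indices.append(edge.type_token)
        for idx in indices:
            if not 0 <= idx < n:
                raise ContractError(
                    f"edge token index {idx} out of range for {n} tokens")
        if edge.head == edge.dependent:
            raise ContractError(f"self-edge on token index {edge.head}")
        nodes = [BioCNode(tokens[edge.head].id, "head"),
                 BioCNode(tokens[edge.dependent].id, "dependent")]
        if edge.type_token is not None:
            nodes.append(BioCNode(tokens[edge.type_token].id, "type"))
        infons = {RELATION_KEY: edge.label}
        if edge.initial_gr is not None:
            infons[INITIAL_GR_KEY] = edge.initial_gr
        sentence.relations.append(
            BioCRelation(id=f"R{next_id}", infons=infons, nodes=nodes))
        next_id += 1
        has_incoming.add(edge.dependent)
    if parse.dependencies:
        roots = [i for i in range(n) if i not in has_incoming]
        if len(roots) == 1:
            sentence.infons[ROOT_KEY] = tokens[roots[0]].id
    return sentence


def decode_parse(sentence: BioCSentence) -> ParseResult:
    """Invert :func:`encode_parse`: rebuild the ParseResult from the sentence.

    Relations whose nodes do not resolve to token annotations of the
    sentence raise :class:`BioCFormatError`.
    """
    tokens = _tokens_in_order(sentence)
    index_of = {t.id: i for i, t in enumerate(tokens)}
    edges: list[DependencyEdge] = []
    for rel in sentence.relations:
        role_names = {node.role for node in rel.nodes}
        if not role_names & {"head", "dependent"}:
            continue  # not a dependency relation (e.g. an abbreviation pair)
        roles: dict[str, str] = {}
        for node in rel.nodes:
            if node.refid not in index_of:
                raise BioCFormatError(
                    f"relation {rel.id}: refid {node.refid!r} is not a token "
                    f"of this sentence")
            roles[node.role] = node.refid
        if "head" not in roles or "dependent" not in roles:
            raise BioCFormatError(
                f"relation {rel.id}: missing head/dependent roles")
        edges.append(DependencyEdge(
            head=index_of[roles["head"]],
            dependent=index_of[roles["dependent"]],
            label=rel.infons.get(RELATION_KEY, ""),
            type_token=index_of[roles["type"]] if "type" in roles else None,
            initial_gr=rel.infons.get(INITIAL_GR_KEY),
        ))
    return ParseResult(tree=sentence.infons.get(PARSE_TREE_KEY), dependencies=edges)


def naive_dependencies(tokens: list[BioCAnnotation]) -> ParseResult:
    """Deterministic stand-in parser: a right-headed chain.

    Token ``i`` depends on token ``i+1`` with label ``dep``; the last
    token is the root.  No constituent tree.  Exists so the encoding and
    export machinery runs end-to-end without a statistical parser; the
    plug-point for a real parser is any callable with this signature.
    """
    if not tokens:
        raise ValueError("naive_dependencies requires at least one token")
    return ParseResult(dependencies=[
        DependencyEdge(head=i + 1, dependent=i, label="dep")
        for i in range(len(tokens) - 1)
    ])


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(sentence: BioCSentence, name: str = "sentence") -> str:
    """Render the sentence's dependency relations as a DOT digraph.

    One node per participating token (label = token text, id = annotation
    id), one labeled edge per head->dependent relation.  Deterministic:
    nodes in offset order, edges in relation order.  Consumes only the
    BioC representation, so it is independent of the producing parser.
    """
    decode_parse(sentence)  # raises if the encoding is malformed
    tokens = _tokens_in_order(sentence)
    participating: set[str] = set()
    edges: list[tuple[str, str, str]] = []
    for rel in sentence.relations:
        roles = {node.role: node.refid for node in rel.nodes}
        if "head" not in roles or "dependent" not in roles:
            continue
        for refid in roles.values():
            participating.add(refid)
        edges.append((roles["head"], roles["dependent"],
                      rel.infons.get(RELATION_KEY, "")))
    lines = [f"digraph {name} {{"]
    for tok in tokens:
        if tok.id in participating:
            lines.append(f'  {tok.id} [label="{_dot_escape(tok.text)}"];')
    for head, dep, label in edges:
        lines.append(f'  {head} -> {dep} [label="{_dot_escape(label)}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
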