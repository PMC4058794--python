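"""Encode a dependency parse as BioC relations and export it to DOT.

The edges here are hand-written (what a grammatical-relations parser
would produce for the noun phrase, including a Briscoe & Carroll-style
type token); the exporter only ever sees the BioC relations, so it works
identically for any parser's output.
"""

from bioctk import BioCSentence, DependencyEdge, ParseResult, encode_parse, to_dot
from bioctk.segment import tokenize

sentence = BioCSentence(offset=0, text="Familial deficiency of complement")
sentence.annotations = tokenize(sentence)

parse = ParseResult(
    tree="(NP (JJ Familial) (NN deficiency) (PP (IN of) (NN complement)))",
    dependencies=[
        DependencyEdge(head=1, dependent=0, label="ncmod"),
        DependencyEdge(head=1, dependent=3, label="iobj", type_token=2,
                       initial_gr="iobj"),
    ])
encode_parse(sentence, parse)

print("parse_tree infon:", sentence.infons["parse_tree"])
# "of" participates only as a type token, so two tokens lack incoming
# edges and no unique root is recorded
print("root token:", sentence.infons.get("root", "(not unique)"))
print(to_dot(sentence))
# Each relation links head -> dependent by token id; the second edge
# carries a third node (role "type", the preposition) and preserves the
# initial grammatical relation as the infon initial_gr.
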