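"""Run the full preprocessing pipeline on a small abstract.

Builds a one-document BioC collection from raw text, applies sentence
segmentation, tokenization, POS tagging, lemmatization and the stand-in
dependency parse, and prints the token annotations.  Offsets are document
coordinates; every token is an exact substring of the original text.
"""

from bioctk import (
    BioCCollection,
    BioCDocument,
    BioCPassage,
    run_pipeline,
    validate_collection,
)

TEXT = ("Familial deficiency of the seventh component of complement "
        "associated with recurrent bacteremic infections due to Neisseria")

collection = BioCCollection(
    source="example", date="2014-01-01", key="example.key",
    documents=[BioCDocument(id="1", passages=[BioCPassage(offset=0, text=TEXT)])])

annotated = run_pipeline(
    collection, ["sentence", "token", "pos", "lemma", "parse"])

sentence = annotated.documents[0].passages[0].sentences[0]
print(f"sentence at offset {sentence.offset}: {sentence.text!r}")
print(f"{len(sentence.annotations)} tokens, {len(sentence.relations)} dependency relations")
print(f"{'id':<5}{'offset':<8}{'token':<14}{'POS':<6}lemma")
for token in sentence.annotations[:6]:
    loc = token.locations[0]
    print(f"{token.id:<5}{loc.offset:<8}{token.text:<14}"
          f"{token.infons['POS']:<6}{token.infons['lemma']}")
print("...")
print("validation violations:", len(validate_collection(annotated)))
# Each row is one stand-off token annotation: its span [offset, offset+len)
# points back into the original text, and POS/lemma ride along as infons.
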