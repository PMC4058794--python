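# bioctk

A toolkit for **BioC**, the XML-based stand-off annotation interchange
format used in biomedical text mining. Text is carried once per document;
every annotation points back into it with a character **offset** and
**length**, and arbitrary metadata rides along as ordered key→value
*infons*. bioctk provides:

- an in-memory BioC data model (`collection → document → passage →
  sentence → annotation/relation`) with full invariant validation —
  offset/text agreement, unique ids, resolvable relation references;
- a deterministic BioC XML reader/writer (round-trip exact, byte-stable
  output) plus the sidecar `.key` file documenting infon semantics;
- a native preprocessing pipeline: rule-based sentence segmentation,
  **invertible** tokenization (multi-space runs are reflected in token
  offsets, so the original text is always recoverable from the
  annotations), a deterministic baseline POS tagger (Penn Treebank tags),
  a rule-cascade lemmatizer with British→American spelling
  normalization, dependency-parse encoding as typed BioC relations
  (head/dependent/type nodes, `initial_gr` infons), and Schwartz &
  Hearst-style abbreviation definition detection;
- a **PubTator ↔ BioC** converter for disease-mention corpora using the
  `EntityType` / `Nomenclature` / `ConceptID` infon scheme, with corpus
  statistics (documents, mentions, unique concepts);
- a cross-pipeline **diff** that compares two annotated collections by
  offsets (sentence boundaries, token spans, POS on span-aligned tokens,
  dependency triples);
- DOT export of dependency graphs, consuming only the BioC
  representation, so it is independent of the producing parser;
- a deterministic synthetic-corpus generator so every test and demo runs
  offline.

It is aimed at people building or debugging BioC-compliant text mining
components: the tagger and parser are deliberately simple deterministic
baselines behind pluggable contracts — swap in a trained tagger or a real
parser without touching the interchange layer.

## Worked example

```python
from bioctk import BioCCollection, BioCDocument, BioCPassage, run_pipeline

TEXT = ("Familial deficiency of the seventh component of complement "
        "associated with recurrent bacteremic infections due to Neisseria")
collection = BioCCollection(
    source="example", date="2014-01-01", key="example.key",
    documents=[BioCDocument(id="1", passages=[BioCPassage(offset=0, text=TEXT)])])
annotated = run_pipeline(collection, ["sentence", "token", "pos", "lemma", "parse"])
```

Running `python examples/preprocess_text.py` prints:

```
sentence at offset 0: 'Familial deficiency of the seventh component of complement associated with recurrent bacteremic infections due to Neisseria'
16 tokens, 15 dependency relations
id   offset  token         POS   lemma
T1   0       Familial      NN    familial
T2   9       deficiency    NN    deficiency
T3   20      of            IN    of
T4   23      the           DT    the
T5   27      seventh       NN    seventh
T6   35      component     NN    component
...
validation violations: 0
```

The headline sentence becomes one BioC sentence with 16 token
annotations; each row is a stand-off annotation whose span
`[offset, offset+len)` indexes the original text exactly, with the POS
tag and lemma attached as infons. The 15 relations are the stand-in
parser's head→dependent chain encoded as BioC relations by token id.

The other `examples/` scripts each demonstrate one capability —
PubTator conversion and counting (`pubtator_conversion.py`), dependency
encoding and DOT export (`dependency_graph.py`), abbreviation detection
(`abbreviations.py`), and configuration diffing (`compare_pipelines.py`).

## Command line

```
bioctk fixtures --docs 10 --seed 1 --out demo/       # synthetic corpus
bioctk preprocess demo/corpus.xml out.xml --stages sentence,token,pos,lemma
bioctk validate out.xml
bioctk pubtator2bioc corpus.txt corpus.xml
bioctk bioc2pubtator corpus.xml corpus.txt
bioctk stats corpus.xml
bioctk diff a.xml b.xml --report report.tsv
bioctk dot out.xml graph.dot --doc 9000000 --sentence 0
```

Exit codes: 0 ok, 1 data error, 2 usage error.

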