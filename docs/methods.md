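# Methods

This note documents the models, conventions and numerical choices behind
bioctk, and what the shipped tests do and do not demonstrate.

## The stand-off annotation model

BioC represents a corpus as `collection → document → passage → sentence →
annotation / relation`. An annotation is a span — `(offset, length)` —
plus the surface text it covers and an ordered infon map; a relation is a
typed link between annotations referenced by id, each reference carrying
a role label. The model's central contract is *span faithfulness*: for
every annotation, slicing the document's text at its location must yield
exactly the annotation's text. `validate_collection` checks this together
with the structural invariants (unique document/annotation/relation ids,
non-empty infon keys and values, ordered non-overlapping passages and
sentences, resolvable relation references) and returns violation records
rather than raising, so a validator can report everything at once.

### Offset conventions

- Offsets are 0-based counts of **Unicode code points**, not bytes, from
  the start of the document's reconstructed text; spans are half-open.
  Code points are unambiguous across encodings; byte-offset dialects are
  out of scope.
- Document text reconstruction: the first passage starts at offset 0 and
  each subsequent passage starts one character after the previous
  passage's text ends; the gap character is a newline. This makes
  reconstruction deterministic without storing the full document text.
- Within a segmented passage (whose own text is no longer stored, per
  the BioC element layout), sentences are placed at their offsets and
  inter-sentence gaps are filled with spaces. Gap *positions* are exact;
  gap *characters* between sentences are a convention. The synthetic
  corpora place exactly one space between sentences, so reconstruction
  is exact on all fixtures; on external data with tabs or newlines
  between sentences, passage-level reconstruction of inter-sentence gaps
  is positionally but not literally faithful (annotation spans are
  unaffected, as they never cross sentence gaps).
- Id schemes: `T<n>` for annotations (tokens, mentions, abbreviation
  forms) and `R<n>` for relations, numbered per document; new stages
  continue from the highest existing number.

## XML interchange

The writer emits a fixed element order (source/date/key, then infons
first in every element, annotations before relations) with deterministic
pretty-printing, which gives two useful properties verified by tests:
`read(write(c)) == c` field-by-field including infon order, and
`write(read(write(c)))` byte-identical to `write(c)`. The reader performs
its own structural checks (e.g. a `location` without a `length`, an
`infon` without a `key`) and reports the offending element path;
well-formedness errors carry the XML line number. The official DTD is not
machine-enforced — the reader's checks are the contract — and the BioC
JSON dialect is out of scope. The collection `date` is the generation
date by default but is always overridable so serialization is
reproducible.

The sidecar `.key` file lists every infon key the pipeline can emit with
a one-line description (one line per key, last description wins on
duplicates). It is a plain documented convention; nothing parses it back.

## Preprocessing pipeline

Stages run per passage in dependency order: `sentence → token → pos →
lemma / parse → abbrev`. Applied stages are recorded in the collection
infon `pipeline_stages`, which is how a later invocation knows its
prerequisites are already met — running stages incrementally is
guaranteed to equal a single combined run.

### Sentence segmentation

A small finite-state scanner: a terminator character (default `.`, `!`,
`?`; configurable) ends a sentence only when followed by whitespace and
an uppercase letter or digit (or end of text), and the token it closes is
not in the abbreviation list (default entries like `Fig.`, `et al.`,
`e.g.`, shipped as an editable text resource). Decimal points and
abbreviation periods therefore do not split. Trailing unterminated text
becomes a final sentence. Sentences are exact substrings covering all
non-whitespace characters; segmentation is a pure function of
`(text, config)`.

### Invertible tokenization

Chunks are whitespace-delimited; edge punctuation (`.,;:()[]{}!?"'%`) is
peeled into separate tokens; hyphen and slash splitting are configuration
flags (`split_hyphen`, `split_slash`), both off by default — biomedical
tokenizers genuinely disagree here, so the behavior is a dial rather than
a dogma, and the diff module measures the consequences. A sentence-final
abbreviation keeps its period attached. Every token is an exact substring
addressed by document offsets, so interleaving token texts with the
original inter-token characters reproduces the sentence byte-for-byte
(`detokenize` checks this and is exercised over adversarial texts with
multi-space runs, tabs and non-ASCII words).

### Baseline POS tagger

The tagger contract is a callable over a sentence's token texts (so a
context-sensitive trained tagger plugs in unchanged; a wrong-length
return is a contract error). The shipped baseline is deterministic:
closed-class lexicon (~180 entries, shipped as TSV) → suffix rules
(`-ing`→VBG, `-ed`→VBN, `-ly`→RB, `-s`→NNS, `-tion/-ity/-ness`→NN) →
capitalized-mid-sentence→NNP → digit pattern→CD → punctuation→itself →
fallback NN. The tag set is Penn Treebank, recorded in the collection
infon `tagset`. The baseline exists to make the pipeline testable and
deterministic; its accuracy is not a claim and is not measured.

### Lemmatizer

Input is `(word form, POS)`. The word is lowercased, British spellings
are normalized to American (word map shipped as TSV, plus the
conservative suffix rules `-our`→`-or` for words longer than five
characters outside a small keep-list, `-aemia/-aemic`→`-emia/-emic`,
`-isation`→`-ization`; the bare `-ise`→`-ize` rule is map-only because it
misfires on common words), then inflection is stripped: irregular forms
from an exception lexicon (~120 entries, TSV), plural rules for NNS
(`-ies`→`-y`, `-xes/-ches/-shes/-sses/-uses`→strip `-es`, else strip
`-s` unless the word ends `-ss/-us/-is`), and verb rules for
VBD/VBN/VBG (strip `-ed`/`-ing`, undouble final consonants, restore a
final `e` for stem shapes like `-at`, `-iz`, `-us`, `-eas`, `-v`, `-c`).
Spelling normalization is re-applied after stripping so inflected
British forms land on American lemmas. The function is total on Unicode
input and idempotent for a fixed POS; like any rule cascade without a
full lexicon it has known misses (e.g. rare `-ouse` plurals), which the
exception file is the supported way to patch.

### Parse encoding

A parse is `(tree, dependencies)`: an optional flat Penn-Treebank-style
bracket string, stored verbatim in the sentence infon `parse_tree`, and
labeled edges over token indices. Each edge becomes one relation with
infon `relation=<label>`, nodes `(head, dependent)` by token id, an
optional third node with role `type` (Briscoe & Carroll grammatical
relations attach a type token, typically the preposition), and an
optional `initial_gr` infon. A unique dependency root (no incoming edge)
is recorded as the sentence infon `root` rather than a degenerate
self-relation; with multiple root candidates no root is recorded.
`decode_parse` inverts the encoding exactly (edge order preserved) and
ignores non-dependency relations such as abbreviation pairs. The shipped
parser is a deliberate stand-in — a right-headed chain (`token i`
depends on `token i+1`, label `dep`) — so the encoding, decoding and
export machinery runs end-to-end deterministically; any callable from
token list to parse can replace it. The DOT exporter consumes only the
BioC relations (nodes in offset order, edges in relation order, node ids
= annotation ids so duplicate surface words stay distinct), which is
what makes it parser-independent.

### Abbreviation detection

Classic parenthesis-driven matching: a candidate short form (innermost
parentheses only; length 2–10, at most two words, contains a letter,
starts alphanumeric) is matched right-to-left against the preceding
window of `min(|SF|+5, 2·|SF|)` words (hyphens count as word
separators), requiring the first short-form character to start the first
long-form word. Matching is case-insensitive. Detected pairs become two
annotations (`type=ABBR`, `role=shortform|longform`) linked by a
relation with the same roles. No precision/recall claim is made — there
are no gold abbreviation annotations in scope — the tests assert the
algorithmic contract (in-order character containment, exact offsets) and
the canonical definition phrases.

## PubTator conversion

Mention coordinates run over `title + one separator character +
abstract`; the separator is written as a newline but always counted as
one character, matching the document-coordinate convention above (title
passage at offset 0, abstract passage at `len(title)+1`). Each mention
becomes an annotation with `EntityType` (category, passed through
verbatim), `ConceptID` (verbatim, composites with `|`/`+` preserved) and
`Nomenclature` (`OMIM` iff the id starts `OMIM:`, else `MeSH`). The
parser verifies every mention's span against its text and reports pmid
and line on disagreement; mentions straddling the title/abstract
boundary are rejected. `corpus_stats` counts documents, mention
annotations (= annotations with a `ConceptID`) and unique verbatim
concept ids; `split_composite=True` counts composite components
separately, since "unique concept" is otherwise ambiguous. The inverse
converter emits only mention annotations, so a fully preprocessed
collection still round-trips to the original corpus text.

## Cross-pipeline diff

Two collections over the same document ids are compared per stage:
sentence and token spans as `(offset, length)` sets, POS only on tokens
whose spans match exactly on both sides, dependency relations as
`(head span, dependent span, label)` triples. Comparison is by offsets,
never ids. A span present on one side only contributes one detail record
(so a single moved token span counts twice: once vanished, once
appeared); the report is symmetric under argument swap. Token
annotations are recognized structurally as sentence-level annotations
without `type=ABBR`; semantic equivalence of different label inventories
is explicitly not attempted.

## Synthetic corpora

The generator emulates the *shape* of a disease-mention abstract corpus:
per document a title and a 1–4 sentence abstract built from a fixed word
pool, with 0–5 non-overlapping mentions drawn from a disease-phrase pool,
categories from the four disease-category names, and concept ids mixing
MeSH-style `D`-numbers, `OMIM:`-prefixed ids and occasional composite
ids. The pool is deliberately adversarial: multi-space runs, hyphenated
and slashed tokens, parenthesized abbreviation definitions,
mid-sentence abbreviations and non-ASCII (Greek-letter) words appear at
fixed rates. Output is byte-identical for identical `(n_docs, seed)`,
and the generator returns its own ground-truth counts so counting code
is tested against construction, not against itself.

What it does **not** emulate: natural language statistics, PubMed
abstract length distributions, annotation disagreements, or the real
corpus's concept distribution. Passing tests therefore demonstrate the
interchange, invertibility and counting *mechanisms* — not linguistic
accuracy on real text. A corpus file in the same PubTator format (e.g. a
downloaded disease corpus) can be run through the same
`pubtator2bioc` / `stats` path unchanged.

`generate_broken_fixture` produces collections violating exactly one
invariant class each (bad span text, wrong text length, unresolved
refid, overlapping sentences, duplicate id, empty infon, out-of-range
location), which is how validation completeness is tested.

## Problem sizes and determinism

The acceptance script and tests use synthetic corpora of 2–150 documents
and property runs of 200–1000 cases; these sizes were chosen to exercise
every code path and edge-case rate in the generator while keeping a full
run comfortably under a minute. All randomness flows from explicit seeds
(the acceptance script derives everything from `--seed`); property tests
are derandomized, so runs are reproducible everywhere.

## Known limitations

- The baseline tagger and chain parser are deterministic stand-ins with
  pluggable contracts, not models of English; POS and dependency output
  on real text is structurally valid but linguistically naive.
- Lemmatization is a rule cascade with a small exception lexicon; rare
  irregular forms fall through to regular rules.
- The segmenter's terminator heuristic can merge sentences when a
  sentence starts with a lowercase word, and the abbreviation list is
  finite and editable rather than learned.
- Only single-location annotations are produced by the pipeline
  (multi-location annotations are representable and validated, but no
  stage emits them).
- Sentence-gap characters inside segmented passages are reconstructed as
  spaces (see offset conventions above).
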