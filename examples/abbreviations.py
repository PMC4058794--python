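"""Detect abbreviation definitions (short form in parentheses).

The detector matches short-form characters right-to-left against the
preceding words; both forms come back with exact document offsets.
"""

from bioctk import BioCSentence, find_abbreviations

SENTENCES = [
    "Online Mendelian Inheritance in Man (OMIM)",
    "We indexed terms with Medical Subject Headings (MeSH) descriptors.",
    "A value (12.5) was seen.",
]

for text in SENTENCES:
    pairs = find_abbreviations(BioCSentence(offset=0, text=text))
    print(f"{text!r}")
    if not pairs:
        print("   no definition found")
    for p in pairs:
        print(f"   short {p.short_form!r} at [{p.short_location.offset},"
              f"{p.short_location.offset + p.short_location.length}) "
              f"<- long {p.long_form!r} at [{p.long_location.offset},"
              f"{p.long_location.offset + p.long_location.length})")
# The numeric parenthetical is rejected by the candidate filter (a short
# form must contain a letter and start with an alphanumeric character).
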