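# Known abbreviations: a trailing period after one of these tokens does
# not end a sentence, and the period stays attached during tokenization.
# One entry per line; lines starting with '#' are ignored.
Dr.
Mr.
Mrs.
Ms.
Prof.
Fig.
Figs.
Eq.
Ref.
Refs.
No.
St.
al.
e.g.
i.e.
cf.
vs.
ca.
approx.
et al.
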