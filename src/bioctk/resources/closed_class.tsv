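# Closed-class lexicon for the baseline tagger: word<TAB>Penn Treebank tag.
# Lookup is case-insensitive. Lines starting with '#' are ignored.
the	DT
a	DT
an	DT
this	DT
that	DT
these	DT
those	DT
each	DT
every	DT
either	DT
neither	DT
some	DT
any	DT
no	DT
all	DT
both	DT
another	DT
such	JJ
of	IN
in	IN
on	IN
at	IN
by	IN
for	IN
with	IN
from	IN
into	IN
onto	IN
through	IN
throughout	IN
during	IN
between	IN
among	IN
within	IN
without	IN
under	IN
over	IN
above	IN
below	IN
after	IN
before	IN
against	IN
toward	IN
towards	IN
upon	IN
about	IN
via	IN
per	IN
despite	IN
besides	IN
beyond	IN
near	IN
since	IN
until	IN
than	IN
as	IN
because	IN
although	IN
though	IN
while	IN
if	IN
unless	IN
whereas	IN
whether	IN
due	JJ
and	CC
or	CC
but	CC
nor	CC
plus	CC
versus	CC
to	TO
i	PRP
you	PRP
he	PRP
she	PRP
it	PRP
we	PRP
they	PRP
me	PRP
him	PRP
her	PRP
us	PRP
them	PRP
itself	PRP
themselves	PRP
himself	PRP
herself	PRP
my	PRP$
your	PRP$
his	PRP$
its	PRP$
our	PRP$
their	PRP$
who	WP
whom	WP
whose	WP$
which	WDT
what	WP
when	WRB
where	WRB
why	WRB
how	WRB
can	MD
could	MD
may	MD
might	MD
must	MD
shall	MD
should	MD
will	MD
would	MD
be	VB
is	VBZ
are	VBP
was	VBD
were	VBD
been	VBN
being	VBG
am	VBP
have	VBP
has	VBZ
had	VBD
do	VBP
does	VBZ
did	VBD
done	VBN
not	RB
n't	RB
very	RB
also	RB
too	RB
only	RB
here	RB
there	EX
now	RB
then	RB
thus	RB
therefore	RB
however	RB
moreover	RB
furthermore	RB
often	RB
never	RB
always	RB
sometimes	RB
further	RB
well	RB
more	RBR
most	RBS
less	RBR
least	RBS
respectively	RB
previously	RB
recently	RB
approximately	RB
one	CD
two	CD
three	CD
four	CD
five	CD
six	CD
seven	CD
eight	CD
nine	CD
ten	CD
eleven	CD
twelve	CD
twenty	CD
hundred	CD
thousand	CD
million	CD
first	JJ
second	JJ
third	JJ
several	JJ
many	JJ
few	JJ
other	JJ
same	JJ
new	JJ
novel	JJ
present	JJ
high	JJ
low	JJ
normal	JJ
common	JJ
rare	JJ
severe	JJ
human	JJ
et	FW
al.	FW
e.g.	FW
i.e.	FW
vs.	FW
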