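# Exception lexicon: inflected form<TAB>lemma<TAB>class (N = noun plural,
# V = verb past/participle). Lookup is on the lowercased form.
men	man	N
women	woman	N
children	child	N
feet	foot	N
teeth	tooth	N
mice	mouse	N
geese	goose	N
people	person	N
data	datum	N
media	medium	N
criteria	criterion	N
phenomena	phenomenon	N
bacteria	bacterium	N
mitochondria	mitochondrion	N
analyses	analysis	N
hypotheses	hypothesis	N
diagnoses	diagnosis	N
prognoses	prognosis	N
syntheses	synthesis	N
bases	basis	N
axes	axis	N
crises	crisis	N
theses	thesis	N
fungi	fungus	N
nuclei	nucleus	N
loci	locus	N
foci	focus	N
stimuli	stimulus	N
radii	radius	N
genera	genus	N
corpora	corpus	N
indices	index	N
matrices	matrix	N
appendices	appendix	N
vertebrae	vertebra	N
larvae	larva	N
sera	serum	N
genomes	genome	N
is	be	V
am	be	V
are	be	V
being	be	V
does	do	V
doing	do	V
having	have	V
goes	go	V
going	go	V
was	be	V
were	be	V
been	be	V
began	begin	V
begun	begin	V
became	become	V
brought	bring	V
built	build	V
bought	buy	V
caught	catch	V
came	come	V
chose	choose	V
chosen	choose	V
did	do	V
done	do	V
drew	draw	V
drawn	draw	V
fell	fall	V
fallen	fall	V
felt	feel	V
found	find	V
gave	give	V
given	give	V
went	go	V
gone	go	V
got	get	V
gotten	get	V
grew	grow	V
grown	grow	V
had	have	V
heard	hear	V
held	hold	V
kept	keep	V
knew	know	V
known	know	V
led	lead	V
left	leave	V
lost	lose	V
made	make	V
meant	mean	V
met	meet	V
paid	pay	V
put	put	V
ran	run	V
read	read	V
rose	rise	V
risen	rise	V
arose	arise	V
arisen	arise	V
said	say	V
saw	see	V
seen	see	V
sent	send	V
set	set	V
showed	show	V
shown	show	V
sought	seek	V
spoke	speak	V
spoken	speak	V
spent	spend	V
stood	stand	V
took	take	V
taken	take	V
thought	think	V
threw	throw	V
thrown	throw	V
underwent	undergo	V
undergone	undergo	V
understood	understand	V
wrote	write	V
written	write	V
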