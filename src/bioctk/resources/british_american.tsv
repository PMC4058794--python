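# British -> American spelling map: british<TAB>american.
# Applied after lowercasing, before inflection stripping; the code adds
# conservative suffix rules (-our/-aemia/-aemic/-isation) on top.
tumour	tumor
tumours	tumors
colour	color
behaviour	behavior
labour	labor
favour	favor
odour	odor
vapour	vapor
anaemia	anemia
anaemic	anemic
leukaemia	leukemia
leukaemic	leukemic
thalassaemia	thalassemia
ischaemia	ischemia
ischaemic	ischemic
septicaemia	septicemia
haemoglobin	hemoglobin
haemorrhage	hemorrhage
haemophilia	hemophilia
haematology	hematology
oedema	edema
oesophagus	esophagus
oesophageal	esophageal
oestrogen	estrogen
paediatric	pediatric
orthopaedic	orthopedic
anaesthesia	anesthesia
anaesthetic	anesthetic
diarrhoea	diarrhea
gonorrhoea	gonorrhea
dyspnoea	dyspnea
coeliac	celiac
foetal	fetal
foetus	fetus
aetiology	etiology
caecum	cecum
faeces	feces
gynaecology	gynecology
encyclopaedia	encyclopedia
analyse	analyze
analysed	analyzed
analysing	analyzing
characterise	characterize
characterised	characterized
hospitalised	hospitalized
immunised	immunized
localised	localized
normalised	normalized
randomised	randomized
recognised	recognized
standardised	standardized
utilise	utilize
utilised	utilized
organisation	organization
centre	center
fibre	fiber
litre	liter
metre	meter
titre	titer
defence	defense
licence	license
practise	practice
programme	program
sulphur	sulfur
sulphate	sulfate
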