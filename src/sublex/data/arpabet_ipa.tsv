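# ARPAbet -> IPA translation for importing CMU-dictionary-style pronunciations.
# Stress digits are stripped on import, except that unstressed AH0 maps to schwa.
# ER expands to the schwa + /ɹ/ sequence (syllabic-consonant-free transcription).
# columns: arpabet  ipa (space-separated if more than one phoneme)
AA	ɑ
AE	æ
AH	ʌ
AH0	ə
AO	ɔ
AW	aʊ
AY	aɪ
B	b
CH	tʃ
D	d
DH	ð
EH	ɛ
ER	ə ɹ
EY	eɪ
F	f
G	g
HH	h
IH	ɪ
IY	i
JH	dʒ
K	k
L	l
M	m
N	n
NG	ŋ
OW	oʊ
OY	ɔɪ
P	p
R	ɹ
S	s
SH	ʃ
T	t
TH	θ
UH	ʊ
UW	u
V	v
W	w
Y	j
Z	z
ZH	ʒ
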