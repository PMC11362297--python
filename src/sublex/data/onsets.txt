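# Attested English syllable onsets, one per line, phonemes space-separated.
# The empty onset is always legal and is not listed.
# Singles (every consonant except /ŋ/; /ʒ/ kept for loans like GENRE).
p
b
t
d
k
g
tʃ
dʒ
f
v
θ
ð
s
z
ʃ
ʒ
h
m
n
l
ɹ
j
w
# Obstruent + liquid / glide
p l
p ɹ
p j
b l
b ɹ
b j
t ɹ
t w
t j
d ɹ
d w
d j
k l
k ɹ
k w
k j
g l
g ɹ
g w
g j
f l
f ɹ
f j
v j
θ ɹ
θ w
θ j
ʃ ɹ
h j
m j
n j
l j
z j
# s-clusters
s l
s w
s m
s n
s p
s t
s k
s f
s j
s p l
s p ɹ
s p j
s t ɹ
s t j
s k ɹ
s k w
s k j
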