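# General American phoneme inventory.
# columns: symbol  klass  sonority_class
# sonority classes (ordinal): stop < fricative < nasal < liquid < glide < vowel
# Diphthongs and affricates are single symbols. Rhotic vowels /ɝ ɚ/ are included
# for users who transcribe them as units; the shipped ARPAbet table expands ER to
# the schwa + /ɹ/ sequence instead.
i	vowel	vowel
ɪ	vowel	vowel
eɪ	vowel	vowel
ɛ	vowel	vowel
æ	vowel	vowel
ʌ	vowel	vowel
ə	vowel	vowel
ɑ	vowel	vowel
ɔ	vowel	vowel
oʊ	vowel	vowel
ʊ	vowel	vowel
u	vowel	vowel
aɪ	vowel	vowel
aʊ	vowel	vowel
ɔɪ	vowel	vowel
ɝ	vowel	vowel
ɚ	vowel	vowel
p	consonant	stop
b	consonant	stop
t	consonant	stop
d	consonant	stop
k	consonant	stop
g	consonant	stop
tʃ	consonant	stop
dʒ	consonant	stop
f	consonant	fricative
v	consonant	fricative
θ	consonant	fricative
ð	consonant	fricative
s	consonant	fricative
z	consonant	fricative
ʃ	consonant	fricative
ʒ	consonant	fricative
h	consonant	fricative
m	consonant	nasal
n	consonant	nasal
ŋ	consonant	nasal
l	consonant	liquid
ɹ	consonant	liquid
j	consonant	glide
w	consonant	glide
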