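# Hand-aligned demonstration corpus in canonical mapping notation.
# Small by design: it exercises every structural phenomenon (multi-letter and
# discontinuous graphemes, non-linear E, letter-X clusters, homographs) and
# makes the word-final S -> /z/ vs /s/ and rime -EASE -> /is/ vs /iz/
# demonstrations computable, but its counts are those of this sample only.
spelling	pronunciation	mapping	pron_id
CAT	kæt	C>k|A>æ|T>t	0
COT	kɑt	C>k|O>ɑ|T>t	0
LOBSTER	lɑbstəɹ	L>l|O>ɑ|B>b-S>s|T>t|E>ə|R>ɹ	0
HAPPY	hæpi	H>h|A>æ-PP>p|Y>i	0
EATER	itəɹ	EA>i-T>t|E>ə|R>ɹ	0
TAXI	tæksi	T>t|A>æ|X>ks-I>i	0
WEIGH	weɪ	W>w|EIGH>eɪ	0
ROGUE	ɹoʊg	R>ɹ|O_E>oʊ|GU>g	0
GUESS	gɛs	GU>g|E>ɛ|SS>s	0
GONE	gɔn	G>g|O_E>ɔ|N>n	0
ONE	wʌn	O>w|E~ʌ|N>n	0
MUSCLE	mʌsəl	M>m|U>ʌ-SC>s|E~ə|L>l	0
MUSSEL	mʌsəl	M>m|U>ʌ-SS>s|E>ə|L>l	0
BAKE	beɪk	B>b|A_E>eɪ|K>k	0
BID	bɪd	B>b|I>ɪ|D>d	0
BIDE	baɪd	B>b|I_E>aɪ|D>d	0
POSE	poʊz	P>p|O_E>oʊ|S>z	0
PLEASE	pliz	P>p|L>l|EA_E>i|S>z	0
TEASE	tiz	T>t|EA_E>i|S>z	0
LEASE	lis	L>l|EA_E>i|S>s	0
CEASE	sis	C>s|EA_E>i|S>s	0
GREASE	gɹis	G>g|R>ɹ|EA_E>i|S>s	0
RELEASE	ɹɪlis	R>ɹ|E>ɪ-L>l|EA_E>i|S>s	0
HIS	hɪz	H>h|I>ɪ|S>z	0
HAS	hæz	H>h|A>æ|S>z	0
IS	ɪz	I>ɪ|S>z	0
WAS	wʌz	W>w|A>ʌ|S>z	0
AS	æz	A>æ|S>z	0
DOES	dʌz	D>d|OE>ʌ|S>z	0
YES	jɛs	Y>j|E>ɛ|S>s	0
BUS	bʌs	B>b|U>ʌ|S>s	0
GAS	gæs	G>g|A>æ|S>s	0
THIS	ðɪs	TH>ð|I>ɪ|S>s	0
STOP	stɑp	S>s|T>t|O>ɑ|P>p	0
TABLE	teɪbəl	T>t|A>eɪ-B>b|E~ə|L>l	0
BASS	beɪs	B>b|A>eɪ|SS>s	0
BASS	bæs	B>b|A>æ|SS>s	1
EXAM	ɪgzæm	E>ɪ|X>gz-A>æ|M>m	0
BOX	bɑks	B>b|O>ɑ|X>ks	0
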