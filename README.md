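# sublex

Type-weighted sound–spelling consistency and frequency norms for English
sublexical units — computable for *any* letter string with a user-supplied
phoneme assignment, not just for a fixed list of real words.

`sublex` is aimed at psycholinguists and quantitative corpus linguists who
need experience-dependent regularity indices for reading and spelling
research: consistency norms for stimulus selection, pseudoword scoring,
error (misspelling/mispronunciation) scoring, and corpus-statistics work on
grapheme–phoneme correspondences.

## The model

A lexicon is stored as phoneme–grapheme **aligned** records: every grapheme
(one or more letters, possibly discontinuous, as in the silent-E grapheme
`A_E` of BAKE) is mapped to exactly one phoneme — the letter X being the
single exception, a one-grapheme consonant cluster (/ks/, /gz/). There are
no "silent letters", only graphemes whose pronunciation differs from that of
their constituent letters (WEIGH = [W]→/w/ [EIGH]→/eɪ/). A word-final
*non-linear E* realizes /ə/ or /ʌ/ with reversed letter/phoneme order
(MUSCLE = [M][U][SC][L][E~ə], pronounced /mʌsəl/).

Pronunciations are parsed into syllables by the **Maximum Onset Principle**:
intervocalic consonants join the following syllable's onset unless that
onset is phonotactically illegal (LOBSTER → LOB-STER: /st/ is a legal onset
but /bst/ is not, so the /b/ closes the first syllable; HAPPY → HA-PPY).
Legality is decided by an editable whitelist of attested English
onsets. Every unit is then coded by the five-category *both-ends* position
scheme — word-initial, syllable-initial, syllable-medial, syllable-final,
word-final — so that, e.g., /p/→PP is attested syllable-initially (HAPPY)
but never word-initially. At the coarser grain, each syllable contributes an
onset (word-initial or syllable-initial) and a rime (word-final or
syllable-final).

From an aligned corpus the package builds position-keyed, type-weighted
count tables and computes, at both grains:

```
reading consistency   p(P|G) = n(G→P, pos) / n(G, pos)
spelling consistency  p(G|P) = n(G→P, pos) / n(P, pos)
phonographeme frequency        n(G→P, pos)          (direction-neutral)
grapheme / phoneme frequency   n(G, pos), n(P, pos) (and log10 forms)
```

where n(·) counts corpus entries containing the unit in that position. The
two consistencies share their numerator: experiencing [C]→/k/ while reading
is simultaneously experiencing /k/→[C] for spelling, which is why the joint
unit is called a *phonographeme*. Measures are available segmentally and as
word-level summaries (mean, min, max, sum); unattested units are *undefined*
(excluded and counted), never zero.

## Worked example

Score the pseudoword BLEASE under its two natural readings, using the
bundled demonstration corpus:

```python
import sublex as sx

words, _ = sx.read_corpus_tsv(sx.demo_corpus_text())
tables = sx.build_count_tables(words)

bliz = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>z")
blis = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>s")

for grain in ("phonographeme", "onset_rime"):
    for w in (bliz, blis):
        m = sx.score_word(w, tables, grain).summary("reading_consistency", "mean")
        print(grain, w.pronunciation, round(m, 3))
```

prints

```
phonographeme bliz 0.882
phonographeme blis 0.868
onset_rime bliz 0.333
onset_rime blis 0.667
```

At the phonographeme grain /bliz/ is the more consistent reading, because
word-final S is read /z/ in 52.9% of the demo corpus entries (9 of 17); at
the onset/rime grain the preference reverses, because the rime -EASE is read
/is/ in 4 of its 6 entries. The most consistent pronunciation depends on the
grain examined — the package exposes both so the question can be put to
behavioral data.

The same works from the shell:

```
sublex build --corpus corpus.tsv --out tables/
sublex score --tables tables/ --queries queries.tsv
sublex lookup --tables tables/ --grapheme EASE --grain onset_rime
sublex search --tables tables/ --where "reading_consistency >= 0.9"
sublex diag  --corpus corpus.tsv --holdout 0.2 --seed 1
```

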