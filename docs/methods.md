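# Methods

This note documents the model implemented by `sublex`, the numerical and
design choices that were genuinely open, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Representation

A corpus record is a spelling, a pronunciation, and an alignment that
decomposes both into ordered *segments*, each pairing one grapheme with one
phoneme. Three departures from strict linearity are supported:

* **Discontinuous (silent-E) graphemes** — `A_E`, `EA_E`, `O_E`, … — a final
  E separated from the head letters by exactly one consonant grapheme. The
  trailing E contributes no segment of its own, and the grapheme takes the
  position of its head letters (the `A_E` in BAKE is syllable-medial).
* **Non-linear E** — a final E realizing /ə/ or /ʌ/, whose phoneme precedes
  the adjacent consonant(s) although the letter follows them (MUSCLE /mʌsəl/
  vs. MUSSEL). Internally, segments are stored in phonological order, which
  is also the order of the mapping notation (`M>m|U>ʌ-SC>s|E~ə|L>l`); the
  orthographic order needed for position coding and spelling reconstruction
  displaces each non-linear E to the end of its syllable's letters. The
  notation parser accepts non-linear E anywhere a syllable permits it; the
  automatic aligner, more conservatively, proposes it only as the final
  letter of a word, which covers the attested patterns (-LE, -RE, ONE/ONCE
  and their affixed forms).
* **Letter-X clusters** — the only grapheme mapped to two phonemes
  (/ks/, /gz/, /kʃ/, /gʒ/; the admissible set is an editable data file).
  When the cluster straddles a syllable boundary (TAXI /ˈtæksi/), the X
  segment is pinned to the earlier syllable (TAX-I), and both its phonemes
  stay in that syllable's rime. The /kw/ of QU is deliberately *not* treated
  this way: it decomposes as /k/→Q, /w/→U.

Pronunciations use an NFC-normalized IPA alphabet with diphthongs and
affricates as single tokens; stress is not represented. An ARPAbet→IPA table
is shipped for importing CMU-dictionary-style pronunciations (stress digits
stripped; unstressed `AH0` → /ə/, `ER` → /əɹ/ rather than a rhotic-vowel
unit, so no syllabic consonants arise). Dialect mergers in source
transcriptions are taken at face value.

## Syllabification and onset legality

Syllable boundaries come from the Maximum Onset Principle over the phoneme
string: each intervocalic consonant run is split so that the longest *legal*
suffix becomes the next onset. Legality is membership in an explicit
whitelist of attested English onsets (`src/sublex/data/onsets.txt`, editable
for other dialects), not a computed sonority rule: verbal sonority
descriptions under-determine the attested cluster set (they admit unattested
clusters like /pw/ and are ambiguous about nasals), so the whitelist is the
mechanism and the per-phoneme sonority ranks are retained only as
diagnostics. A word-initial run that is itself illegal (loanwords such as
MBIRA) is kept as the first onset and flagged rather than rejected.

## Position coding

Phonographeme-grain units are coded by the five-category both-ends scheme —
word-initial, syllable-initial, syllable-medial, syllable-final, word-final
— applied in orthographic order, with word edges taking precedence over
syllable edges and a single-segment word coded word-initial. Onsets are
word-initial or syllable-initial; rimes word-final or syllable-final (a
monosyllable has only a word-final rime). The both-ends scheme, unlike
serial syllable numbering, lets a medial CH inform a final CH while still
capturing edge-only restrictions such as PP never beginning a word.

## Counting and measures

Counts are type-weighted: each record contributes once regardless of token
frequency (no token-weighted mode is implemented). Two modes exist.
`instances` (default) counts every occurrence, which makes the joint table
sum exactly to its marginals, so reading consistencies over the attested
alternatives of a (grapheme, position) sum to 1 (and dually for spelling).
`words` counts each (unit, position) key at most once per record — the
literal "number of words with …" reading of the defining ratios — at the
cost of exact additivity when a word repeats a unit in one position with
different mappings. Both modes are kept because published full-corpus values
could have been computed under either; full-corpus reproductions try both.

Measures with zero denominators (or zero counts, for frequencies and their
base-10 logs) are *undefined*, not zero: word-level summaries (mean, min,
max, sum) are taken over defined values only, with `n_undefined` reported.
Counts are stored unsmoothed; an optional add-k smoothing argument exists on
the consistency functions and defaults to off. A syllable without an onset
contributes no onset row at all — neither a zero nor an undefined entry.
Exported report percentages round half-up. Ranking of candidate
pronunciations uses competition ranking with undefined summaries last.

## Automatic alignment

`auto_align` is a dynamic program over (letter index, phoneme index) with
special transitions for the three non-linear phenomena. Among complete
segmentations it prefers, in order: (1) candidates whose every segment sits
in a position where that mapping is attested; (2) the largest product of
inventory attestation counts; (3) the fewest segments (parsimony, the same
principle that selects [GU][E][SS] + [R][O_E][GU] + [G][O_E][N] over
inventories with GUE or O_UE); (4) leftmost-longest graphemes. The per-word
tie-break beyond parsimony is this package's convention — corpus-derived
attestation says nothing about how to choose among equally attested parses.
Failures return a report with the furthest-reached indices; such words are
candidates for manual annotation or inventory extension. The held-out
generalization diagnostic (`sublex diag`) rebuilds the inventory from a
training split and reports the fraction of held-out records the aligner
reproduces — on synthetic 500-word lexicons this lands around 93–98%
depending on the seed, the analogue of the published ~99% statistic for the
full corpus.

## Synthetic data

The generator (`sublex.fixtures`) assembles words syllable-by-syllable from
a small synthetic inventory drawn from the real phoneme alphabet, with
configurable per-phenomenon rates (multi-letter graphemes 0.25, silent-E
0.15 per eligible syllable, non-linear E 0.10, X clusters 0.08 per juncture,
homograph duplication 0.05 — roughly the order of prevalence in English and
high enough that a 100-word corpus exercises every special code path).
Junctures are rejection-sampled so the MOP reproduces the intended
boundaries, making every generated record parseable and MOP-consistent by
construction. Ground-truth tables are tallied during generation from the
generator's own structures; `oracle_counts` is a second, naive enumeration
over finished words. Exact three-way agreement with the production tables is
the central counting test.

What the synthetic corpora do *not* emulate: realistic English rime/onset
frequency distributions, orthographic neighborhoods, morphology, or the long
tail of rare graphemes. Passing the synthetic suite therefore validates the
counting, position-coding, and measure machinery — not the empirical values
any particular real corpus yields; those depend entirely on the corpus
supplied.

## Problem sizes

The test suite and the acceptance script use 50 synthetic corpora of 40–200
words for the oracle sweep, a 500-word lexicon for the held-out alignment
diagnostic, and 500 random phoneme strings for the syllabification
invariants; these sizes give exact (not sampled) checks of every attested
key while keeping a full run in the low seconds.

## Known limitations

* Pronunciations are inputs; there is no text-to-phoneme generation, and the
  toolkit scores a *given* parse — it assigns no probability to the parse
  itself (A-DANE vs. A-DA-NE must be compared by the user).
* No stress, prosody, morphology, or semantics.
* The automatic aligner's non-linear-E transition is word-final only.
* The rime string of a discontinuous grapheme whose gap consonant lies
  outside the unit (A_E in a BAKER-like parse) keeps the underscore form
  (`A_E`) rather than a woven letter string.
* Entropy-style measures over response distributions and token-weighted
  counting are out of scope (a counting-mode hook exists, unimplemented).
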