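"""Mapping notation, auto-alignment, position coding, onset/rime units."""

import pytest

import sublex as sx
from sublex.alignment import (
    ONSET_SYLLABLE_INITIAL,
    ONSET_WORD_INITIAL,
    RIME_SYLLABLE_FINAL,
    RIME_WORD_FINAL,
    SYLLABLE_INITIAL,
    SYLLABLE_MEDIAL,
    WORD_FINAL,
    WORD_INITIAL,
)

from conftest import word_by_spelling


# --- notation parsing and round trip ---------------------------------------


def test_notation_round_trip_on_all_corpus_records(demo_words):
    text = sx.demo_corpus_text()
    for w in demo_words:
        mapping = sx.format_mapping_notation(w)
        assert f"\t{mapping}\t" in text  # bit-exact against the source record
        again = sx.parse_mapping_notation(w.spelling, mapping, w.pronunciation_id)
        assert sx.format_mapping_notation(again) == mapping


def test_parse_weigh():
    w = sx.parse_mapping_notation("WEIGH", "W>w|EIGH>eɪ")
    assert len(w.segments) == 2
    assert w.pronunciation == "weɪ"
    assert [s.grapheme.notation for s in w.segments] == ["W", "EIGH"]


def test_parse_one_nonlinear():
    w = sx.parse_mapping_notation("ONE", "O>w|E~ʌ|N>n")
    assert w.pronunciation == "wʌn"  # phonological order has the vowel second
    e = w.segments[1]
    assert e.nonlinear and e.grapheme.notation == "E" and e.phoneme_str == "ʌ"
    assert w.reconstruct_spelling() == "ONE"  # ...but the letter E is final


def test_parse_rogue_discontinuous():
    w = sx.parse_mapping_notation("ROGUE", "R>ɹ|O_E>oʊ|GU>g")
    assert w.segments[1].grapheme.discontinuous
    assert w.segments[1].grapheme.head == "O"
    assert w.reconstruct_spelling() == "ROGUE"


def test_boundaries_optional_but_checked():
    # omitted boundary: derived from the MOP
    w = sx.parse_mapping_notation("HAPPY", "H>h|A>æ|PP>p|Y>i")
    assert w.syllable_spans == ((0, 2), (2, 4))
    # wrong boundary: rejected
    with pytest.raises(sx.MappingError):
        sx.parse_mapping_notation("HAPPY", "H>h|A>æ|PP>p-Y>i")


@pytest.mark.parametrize(
    "spelling,mapping",
    [
        ("CAT", "C>k|A>æ"),  # letters unaccounted for
        ("CAT", "C>k|A>æ|T>t|T>t"),  # too many letters
        ("TST", "T>t|S>s|T>t"),  # no vowel anywhere
        ("ONE", "O>w|E>ʌ|N>n"),  # linear E cannot precede N orthographically
        ("BOX", "B>b|O>ɑ|X>kk"),  # inadmissible X cluster
        ("CAT", "C>k|A>"),  # empty phoneme
    ],
)
def test_parse_rejects_malformed(spelling, mapping):
    with pytest.raises((sx.MappingError, sx.UnsyllabifiableError)):
        sx.parse_mapping_notation(spelling, mapping)


# --- position coding --------------------------------------------------------


def test_positions_happy(demo_words):
    w = word_by_spelling(demo_words, "HAPPY")
    pp = next(s for s in w.segments if s.grapheme.notation == "PP")
    assert pp.position == SYLLABLE_INITIAL  # not word-initial


def test_positions_blease_monosyllabic():
    w = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>z")
    ea = next(s for s in w.segments if s.grapheme.notation == "EA_E")
    assert ea.position == SYLLABLE_MEDIAL
    assert w.segments[-1].position == WORD_FINAL


def test_positions_blease_disyllabic_final_e():
    # BLEA-SE with a non-silent final E pronounced /eɪ/
    w = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA>i-S>s|E>eɪ")
    assert w.n_syllables == 2
    assert w.segments[-1].grapheme.notation == "E"
    assert w.segments[-1].position == WORD_FINAL


def test_positions_muscle_nonlinear_e_is_word_final(demo_words):
    w = word_by_spelling(demo_words, "MUSCLE")
    e = next(s for s in w.segments if s.nonlinear)
    assert e.position == WORD_FINAL  # orthographically last despite /ə/ medial
    l = next(s for s in w.segments if s.grapheme.notation == "L")
    assert l.position == SYLLABLE_MEDIAL


def test_single_segment_word_is_word_initial():
    w = sx.parse_mapping_notation("A", "A>ə")
    assert w.segments[0].position == WORD_INITIAL


def test_position_exhaustiveness(demo_words):
    for w in demo_words:
        assert all(s.position is not None for s in w.segments)
        rimes = [u for u in sx.derive_onset_rime_units(w) if u.kind == "rime"]
        assert len(rimes) == w.n_syllables  # exactly one rime per syllable


# --- onset/rime units -------------------------------------------------------


def test_units_blease():
    w = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>z")
    units = sx.derive_onset_rime_units(w)
    assert [(u.kind, u.letters, u.phoneme_str, u.position) for u in units] == [
        ("onset", "BL", "bl", ONSET_WORD_INITIAL),
        ("rime", "EASE", "iz", RIME_WORD_FINAL),
    ]


def test_units_adane():
    w = sx.parse_mapping_notation("ADANE", "A>æ-D>d|A_E>eɪ|N>n")
    units = sx.derive_onset_rime_units(w)
    assert [(u.kind, u.letters, u.phoneme_str, u.position) for u in units] == [
        ("rime", "A", "æ", RIME_SYLLABLE_FINAL),
        ("onset", "D", "d", ONSET_SYLLABLE_INITIAL),
        ("rime", "ANE", "eɪn", RIME_WORD_FINAL),
    ]


def test_units_taxi_x_stays_in_earlier_rime(demo_words):
    w = word_by_spelling(demo_words, "TAXI")
    units = sx.derive_onset_rime_units(w)
    rime1 = units[1]
    assert (rime1.letters, rime1.phoneme_str) == ("AX", "æks")
    # no onset carrying /s/ or /ks/ is emitted anywhere
    assert all("s" not in u.phoneme_str for u in units if u.kind == "onset")


def test_units_onsetless_syllable_emits_no_onset():
    w = sx.parse_mapping_notation("OOSH", "OO>u|SH>ʃ")
    units = sx.derive_onset_rime_units(w)
    assert [u.kind for u in units] == ["rime"]


# --- auto-alignment ---------------------------------------------------------


@pytest.mark.parametrize(
    "spelling,pron,expected",
    [
        ("GUESS", "gɛs", "GU>g|E>ɛ|SS>s"),
        ("TAXI", "tæksi", "T>t|A>æ|X>ks-I>i"),
        ("MUSCLE", "mʌsəl", "M>m|U>ʌ-SC>s|E~ə|L>l"),
        ("CAT", "kæt", "C>k|A>æ|T>t"),
        ("BAKE", "beɪk", "B>b|A_E>eɪ|K>k"),
    ],
)
def test_auto_align_examples(demo_inventory, spelling, pron, expected):
    result = sx.auto_align(spelling, pron, demo_inventory)
    assert not isinstance(result, sx.AlignmentFailure)
    assert sx.format_mapping_notation(result) == expected


def test_auto_align_soundness(demo_inventory, demo_words):
    """Successful alignments cover all letters and phonemes exactly."""
    for w in demo_words:
        result = sx.auto_align(w.spelling, w.phonemes, demo_inventory)
        assert not isinstance(result, sx.AlignmentFailure), w.spelling
        assert result.reconstruct_spelling() == w.spelling
        assert result.pronunciation == w.pronunciation


def test_auto_align_failure_report(demo_inventory):
    result = sx.auto_align("QAT", "kæt", demo_inventory)
    assert isinstance(result, sx.AlignmentFailure)
    assert not result
    assert result.furthest_letter == 0  # Q is not an attested grapheme


def test_inventory_position_admissibility(demo_inventory):
    # /p/ -> PP is attested syllable-initially (HAPPY) but never word-initially
    assert demo_inventory.admissible("p", "PP", SYLLABLE_INITIAL)
    assert not demo_inventory.admissible("p", "PP", WORD_INITIAL)


def test_inventory_closure(demo_words, demo_inventory):
    for w in demo_words:
        for s in w.segments:
            assert (s.phoneme_str, s.grapheme.notation) in demo_inventory


def test_inventory_tsv_round_trip(demo_inventory):
    text = demo_inventory.to_tsv()
    again = sx.GraphemeInventory.from_tsv(text)
    assert again.to_tsv() == text


def test_heldout_generalization_rate_is_computable(demo_words):
    """The corpus-generalization diagnostic yields a single success rate."""
    held, train = demo_words[::4], [w for i, w in enumerate(demo_words) if i % 4]
    inventory = sx.GraphemeInventory.from_corpus(train)
    n_ok = sum(
        1
        for w in held
        if not isinstance(
            sx.auto_align(w.spelling, w.phonemes, inventory), sx.AlignmentFailure
        )
    )
    assert 0.0 <= n_ok / len(held) <= 1.0


def test_corpus_tsv_round_trip(demo_words):
    text = sx.write_corpus_tsv(demo_words)
    again, errors = sx.read_corpus_tsv(text)
    assert not errors
    assert [sx.format_mapping_notation(w) for w in again] == [
        sx.format_mapping_notation(w) for w in demo_words
    ]


def test_duplicate_corpus_records_rejected(demo_words):
    text = sx.write_corpus_tsv([demo_words[0], demo_words[0]])
    with pytest.raises(sx.MappingError):
        sx.read_corpus_tsv(text)
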