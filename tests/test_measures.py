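"""Consistency and frequency measures, word scoring, pronunciation ranking."""

import math

import pytest

import sublex as sx
from sublex.alignment import RIME_WORD_FINAL, WORD_FINAL, WORD_INITIAL
from sublex.measures import GrainError

from conftest import word_by_spelling


def test_word_final_s_reading_consistency(demo_tables, demo_words):
    """Word-final S is read /z/ more often than /s/ in the demo corpus."""
    n_z = sum(
        1
        for w in demo_words
        for s in w.segments
        if s.grapheme.notation == "S" and s.position == WORD_FINAL
        and s.phoneme_str == "z"
    )
    n_s = sum(
        1
        for w in demo_words
        for s in w.segments
        if s.grapheme.notation == "S" and s.position == WORD_FINAL
        and s.phoneme_str == "s"
    )
    p_z = sx.reading_consistency(demo_tables, "S", "z", WORD_FINAL)
    p_s = sx.reading_consistency(demo_tables, "S", "s", WORD_FINAL)
    assert p_z == pytest.approx(n_z / (n_z + n_s))
    assert p_s == pytest.approx(n_s / (n_z + n_s))
    assert p_z > p_s


def test_sole_mapping_has_consistency_one(demo_tables):
    # EIGH only ever maps to /eɪ/ in the demo corpus
    assert sx.reading_consistency(demo_tables, "EIGH", "eɪ", WORD_FINAL) == 1.0
    assert sx.spelling_consistency(demo_tables, "X", "gz", "syllable_final") == 1.0


def test_undefined_is_none_not_zero(demo_tables):
    assert sx.reading_consistency(demo_tables, "ZZZ", "z", WORD_FINAL) is None
    assert sx.spelling_consistency(demo_tables, "S", "ʒ", WORD_FINAL) is None
    # ...but the joint frequency of an unattested pair is a plain 0
    assert sx.phonographeme_frequency(demo_tables, "ZZZ", "z", WORD_FINAL) == 0


def test_grain_mismatch_rejected(demo_tables):
    with pytest.raises(GrainError):
        sx.reading_consistency(demo_tables, "S", "z", "not_a_position")
    with pytest.raises(GrainError):
        sx.unit_frequency(demo_tables, "rime", "EASE", WORD_FINAL, "graphemic")


def test_log_frequency(demo_tables):
    assert sx.log_frequency(demo_tables, "grapheme", "EIGH", WORD_FINAL) == 0.0
    assert sx.log_frequency(demo_tables, "grapheme", "ZZZ", WORD_FINAL) is None


def test_measures_match_oracle_ratios():
    """Every measure equals the naive count-and-divide oracle."""
    words, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=7, n_words=200))
    built = sx.build_count_tables(words)
    oracle = sx.oracle_counts(words)
    for name, marg_g, marg_p in (
        ("phonographeme", "grapheme", "phoneme"),
        ("onset", "onset_graphemic", "onset_phonemic"),
        ("rime", "rime_graphemic", "rime_phonemic"),
    ):
        for (g, p, pos), c in oracle.table(name).items():
            assert sx.phonographeme_frequency(built, g, p, pos) == c
            assert sx.reading_consistency(built, g, p, pos) == pytest.approx(
                c / oracle.table(marg_g)[(g, pos)]
            )
            assert sx.spelling_consistency(built, g, p, pos) == pytest.approx(
                c / oracle.table(marg_p)[(p, pos)]
            )


def test_normalization_over_attested_alternatives():
    words, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=13, n_words=150))
    t = sx.build_count_tables(words)
    for (g, pos) in t.grapheme:
        total = sum(
            sx.reading_consistency(t, g, p, pos)
            for (g2, p, p2) in t.phonographeme
            if g2 == g and p2 == pos
        )
        assert math.isclose(total, 1.0)
    for (p, pos) in t.phoneme:
        total = sum(
            sx.spelling_consistency(t, g, p, pos)
            for (g, p1, p2) in t.phonographeme
            if p1 == p and p2 == pos
        )
        assert math.isclose(total, 1.0)


def test_direction_symmetry_and_frequency_identity(demo_tables):
    t = demo_tables
    for (g, p, pos), c in t.phonographeme.items():
        # the joint frequency is direction-neutral (same table cell) and
        # factors exactly as consistency x marginal
        assert sx.phonographeme_frequency(t, g, p, pos) == c
        assert sx.reading_consistency(t, g, p, pos) * t.grapheme[(g, pos)] == c


def test_monotonicity_under_corpus_growth(demo_words):
    t_small = sx.build_count_tables(demo_words[:20])
    t_full = sx.build_count_tables(demo_words)
    for key, c in t_small.phonographeme.items():
        assert t_full.phonographeme[key] >= c


# --- word scoring -----------------------------------------------------------


def test_score_word_segmental_and_summary(demo_tables):
    w = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>z")
    ms = sx.score_word(w, demo_tables, grain="phonographeme")
    assert [r.graphemic for r in ms.rows] == ["B", "L", "EA_E", "S"]
    rc = [r.values["reading_consistency"] for r in ms.rows]
    assert all(v is not None for v in rc)
    assert ms.summary("reading_consistency", "mean") == pytest.approx(
        sum(rc) / len(rc)
    )
    assert ms.summary("reading_consistency", "min") == pytest.approx(min(rc))
    assert ms.summaries["reading_consistency"]["n_undefined"] == 0


def test_score_word_all_unattested(demo_tables):
    w = sx.parse_mapping_notation("ZZOY", "ZZ>ʒ|OY>ɔɪ")
    ms = sx.score_word(w, demo_tables)
    for m in ("reading_consistency", "phonographeme_frequency"):
        assert ms.summary(m, "mean") is None
        assert ms.summaries[m]["n_undefined"] == len(ms.rows)


def test_score_word_onset_rime_skips_absent_onsets(demo_tables):
    w = sx.parse_mapping_notation("OOSH", "OO>u|SH>ʃ")
    ms = sx.score_word(w, demo_tables, grain="onset_rime")
    assert [r.kind for r in ms.rows] == ["rime"]  # no onset row at all


def test_measure_tsv_uses_na_for_undefined(demo_tables):
    w = sx.parse_mapping_notation("ZZOY", "ZZ>ʒ|OY>ɔɪ")
    out = sx.score_word(w, demo_tables).to_tsv()
    assert "NA" in out and out.endswith("\n")


def test_blease_grain_reversal(demo_tables):
    """/bliz/ wins at the phonographeme grain; /blis/ wins at onset/rime.

    Word-final S is more often /z/, but the rime -EASE is more often /is/:
    the most consistent reading depends on the grain examined.
    """
    bliz = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>z")
    blis = sx.parse_mapping_notation("BLEASE", "B>b|L>l|EA_E>i|S>s")
    by_pg = sx.compare_pronunciations([blis, bliz], demo_tables, "phonographeme")
    assert by_pg[0][1].pronunciation == "bliz"
    by_or = sx.compare_pronunciations([blis, bliz], demo_tables, "onset_rime")
    assert by_or[0][1].pronunciation == "blis"
    # consistent with the segmental facts
    assert sx.reading_consistency(demo_tables, "S", "z", WORD_FINAL) > \
        sx.reading_consistency(demo_tables, "S", "s", WORD_FINAL)
    assert sx.reading_consistency(demo_tables, "EASE", "is", RIME_WORD_FINAL) > \
        sx.reading_consistency(demo_tables, "EASE", "iz", RIME_WORD_FINAL)


def test_compare_pronunciations_contract(demo_tables, demo_words):
    w = word_by_spelling(demo_words, "CAT")
    ranked = sx.compare_pronunciations([w], demo_tables)
    assert ranked[0][0] == 1
    with pytest.raises(ValueError):
        sx.compare_pronunciations([], demo_tables)
    other = word_by_spelling(demo_words, "COT")
    with pytest.raises(ValueError):
        sx.compare_pronunciations([w, other], demo_tables)
    # undefined candidates rank last; ties share a rank
    zz = sx.parse_mapping_notation("ZZOY", "ZZ>ʒ|OY>ɔɪ")
    zz2 = sx.parse_mapping_notation("ZZOY", "ZZ>ʃ|OY>ɔɪ")
    ranked = sx.compare_pronunciations([zz, zz2], demo_tables)
    assert [r[0] for r in ranked] == [1, 1]
    assert all(r[2] is None for r in ranked)
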