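"""Count-table construction, merging, and the counting invariants."""

import pytest

import sublex as sx
from sublex.alignment import WORD_INITIAL
from sublex.tables import TABLE_SPECS, CountTables


def tables_equal(a, b):
    return all(a.table(name) == b.table(name) for name, _ in TABLE_SPECS)


def test_direct_count_cat_cot(demo_words):
    words = [w for w in demo_words if w.spelling in ("CAT", "COT")]
    t = sx.build_count_tables(words)
    assert t.phonographeme[("C", "k", WORD_INITIAL)] == 2
    assert t.grapheme[("C", WORD_INITIAL)] == 2


def test_rogue_guess_gone_inventory(demo_words):
    """The parsimonious parsing shares GU and O_E across the three words."""
    trio = [w for w in demo_words if w.spelling in ("ROGUE", "GUESS", "GONE")]
    inv = sx.GraphemeInventory.from_corpus(trio)
    # the six graphemes of the shared-inventory analysis, plus the plain
    # vowel E that GUESS /gɛs/ requires
    assert inv.graphemes == {"R", "O_E", "GU", "SS", "G", "N", "E"}


@pytest.mark.parametrize("seed,n", [(7, 200), (3, 80)])
def test_build_matches_generator_truth_and_oracle(seed, n):
    words, truth = sx.generate_synthetic_corpus(sx.SynthSpec(seed=seed, n_words=n))
    built = sx.build_count_tables(words)
    oracle = sx.oracle_counts(words)
    assert tables_equal(truth, built)
    assert tables_equal(oracle, built)
    assert truth.n_words == built.n_words == n


def test_marginal_identities_instances_mode():
    words, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=5, n_words=120))
    t = sx.build_count_tables(words, mode="instances")
    for (g, pos), c in t.grapheme.items():
        joint = sum(
            v for (g2, _, p2), v in t.phonographeme.items() if g2 == g and p2 == pos
        )
        assert joint == c
    for (p, pos), c in t.phoneme.items():
        joint = sum(
            v for (_, p1, p2), v in t.phonographeme.items() if p1 == p and p2 == pos
        )
        assert joint == c
    for kind in ("onset", "rime"):
        for (u, pos), c in t.table(f"{kind}_graphemic").items():
            joint = sum(
                v
                for (g2, _, p2), v in t.table(kind).items()
                if g2 == u and p2 == pos
            )
            assert joint == c


def test_permutation_invariance(demo_words):
    t1 = sx.build_count_tables(demo_words)
    t2 = sx.build_count_tables(list(reversed(demo_words)))
    assert tables_equal(t1, t2)


def test_words_mode_bounded_by_instances_mode():
    words, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=9, n_words=150))
    ti = sx.build_count_tables(words, mode="instances")
    tw = sx.build_count_tables(words, mode="words")
    for name, _ in TABLE_SPECS:
        for key, c in tw.table(name).items():
            assert c <= ti.table(name)[key]


def test_merge_identity_and_concatenation_equality():
    a, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=1, n_words=60))
    b, _ = sx.generate_synthetic_corpus(sx.SynthSpec(seed=2, n_words=60))
    # drop records that collide across the two independent draws
    keys = {(w.spelling, w.pronunciation_id) for w in a}
    b = [w for w in b if (w.spelling, w.pronunciation_id) not in keys]
    ta, tb = sx.build_count_tables(a), sx.build_count_tables(b)
    merged = sx.merge_tables(ta, tb)
    assert tables_equal(merged, sx.build_count_tables(a + b))
    assert merged.n_words == len(a) + len(b)
    # identity with an empty table, and monotonicity
    empty = CountTables()
    assert tables_equal(sx.merge_tables(ta, empty), ta)
    for name, _ in TABLE_SPECS:
        for key, c in ta.table(name).items():
            assert merged.table(name)[key] >= c


def test_merge_mode_mismatch_rejected():
    with pytest.raises(ValueError):
        sx.merge_tables(CountTables(counting_mode="instances"),
                        CountTables(counting_mode="words"))


def test_duplicate_record_rejected(demo_words):
    with pytest.raises(ValueError):
        sx.build_count_tables([demo_words[0], demo_words[0]])
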