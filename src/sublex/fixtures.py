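"""Synthetic aligned mini-lexicons with known ground truth, plus a naive
counting oracle.

The generator emulates the structural phenomena of real English mappings —
multi-letter graphemes, mid-word and word-final silent-E (discontinuous)
graphemes, non-linear final E, letter-X clusters, homographs with multiple
pronunciations — without attempting realistic English distributional
statistics. Words are assembled syllable by syllable from a small synthetic
phoneme–grapheme inventory drawn from the real phoneme alphabet, with
syllable junctures rejection-sampled so that the Maximum Onset Principle
reproduces the intended boundaries.

Ground-truth count tables are tallied *during generation* from the
generator's own syllable structures, independently of the alignment and
tables modules; :func:`oracle_counts` is a separate naive enumeration over
finished words. Agreement of the three paths is the central correctness test
for the counting machinery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Sequence

from .alignment import (
    ONSET_SYLLABLE_INITIAL,
    ONSET_WORD_INITIAL,
    RIME_SYLLABLE_FINAL,
    RIME_WORD_FINAL,
    SYLLABLE_FINAL,
    SYLLABLE_INITIAL,
    SYLLABLE_MEDIAL,
    WORD_FINAL,
    WORD_INITIAL,
    AlignedWord,
    parse_mapping_notation,
)
from .phonology import default_inventory, default_onsets, is_legal_onset
from .tables import CountTables

__all__ = ["SynthSpec", "generate_synthetic_corpus", "oracle_counts"]

# synthetic inventory: phoneme -> candidate graphemes (first is primary)
CONSONANT_GRAPHEMES: dict[str, tuple[str, ...]] = {
    "p": ("P", "PP"),
    "b": ("B", "BB"),
    "t": ("T", "TT"),
    "d": ("D", "DD"),
    "k": ("K", "C", "CK"),
    "g": ("G", "GG"),
    "s": ("S", "SS", "C"),
    "z": ("Z", "S"),
    "m": ("M", "MM"),
    "n": ("N", "NN"),
    "l": ("L", "LL"),
    "f": ("F", "FF", "PH"),
    "v": ("V",),
    "ʃ": ("SH",),
    "tʃ": ("CH", "TCH"),
}
VOWEL_GRAPHEMES: dict[str, tuple[str, ...]] = {
    "æ": ("A",),
    "ɛ": ("E", "EA"),
    "ɪ": ("I", "Y"),
    "ɑ": ("O", "A"),
    "i": ("EE", "EA", "Y"),
    "eɪ": ("AI", "AY", "A"),
    "oʊ": ("OA", "OW", "O"),
    "u": ("OO", "U"),
    "ə": ("A", "E", "U"),
    "ʌ": ("U", "O"),
}
#: vowels eligible for a discontinuous (silent-E) spelling and that spelling
SILENT_E_GRAPHEMES: dict[str, str] = {
    "eɪ": "A_E",
    "oʊ": "O_E",
    "u": "U_E",
    "i": "E_E",
}
ONSET_CLUSTERS: tuple[tuple[str, ...], ...] = (
    ("s", "t"),
    ("s", "p"),
    ("p", "l"),
    ("k", "l"),
    ("b", "ɹ"),
    ("t", "ɹ"),
    ("f", "l"),
)
CLUSTER_GRAPHEMES = {"ɹ": ("R",)}  # /ɹ/ only appears inside onset clusters here


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic corpus; identical seeds reproduce identical
    corpora."""

    seed: int = 0
    n_words: int = 100
    p_multi_letter: float = 0.25  # multi-letter grapheme for a consonant
    p_silent_e: float = 0.15  # per eligible syllable
    p_nonlinear_e: float = 0.10  # per word (final syllable)
    p_x_cluster: float = 0.08  # per syllable juncture
    p_homograph: float = 0.05  # per word
    p_onset: float = 0.85
    p_onset_cluster: float = 0.15
    p_coda: float = 0.45
    syllable_weights: tuple[float, ...] = (0.50, 0.35, 0.15)
    abstract: bool = False  # 1:1 letter/phoneme mappings, no special cases

    def __post_init__(self) -> None:
        for name in (
            "p_multi_letter",
            "p_silent_e",
            "p_nonlinear_e",
            "p_x_cluster",
            "p_homograph",
            "p_onset",
            "p_onset_cluster",
            "p_coda",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")
        if not self.syllable_weights or min(self.syllable_weights) < 0:
            raise ValueError("syllable_weights must be non-negative and non-empty")


@dataclass
class _Seg:
    notation: str
    phonemes: tuple[str, ...]
    nonlinear: bool = False
    is_vowel: bool = False

    @property
    def phoneme_str(self) -> str:
        return "".join(self.phonemes)


@dataclass
class _Syll:
    onset: list[_Seg] = field(default_factory=list)
    nucleus: _Seg | None = None
    coda: list[_Seg] = field(default_factory=list)

    @property
    def segments(self) -> list[_Seg]:
        """Phonological order: onset, nucleus, coda."""
        return [*self.onset, self.nucleus, *self.coda]

    @property
    def orth_segments(self) -> list[_Seg]:
        """Orthographic order: a non-linear E displaces to the syllable end."""
        segs = self.segments
        return [s for s in segs if not s.nonlinear] + [s for s in segs if s.nonlinear]


class _Tally:
    """Ground-truth counters filled by the generator's own enumeration."""

    def __init__(self, mode: str):
        self.tables = CountTables(counting_mode=mode)

    def add_word(self, sylls: Sequence[_Syll]) -> None:
        keys: list[tuple[str, tuple]] = []
        orth: list[tuple[int, _Seg]] = []
        for si, syll in enumerate(sylls):
            orth.extend((si, seg) for seg in syll.orth_segments)
        n = len(orth)
        first_of, last_of = {}, {}
        for rank, (si, _) in enumerate(orth):
            first_of.setdefault(si, rank)
            last_of[si] = rank
        for rank, (si, seg) in enumerate(orth):
            if rank == 0:
                pos = WORD_INITIAL
            elif rank == n - 1:
                pos = WORD_FINAL
            elif rank == first_of[si] and si > 0:
                pos = SYLLABLE_INITIAL
            elif rank == last_of[si] and si < len(sylls) - 1:
                pos = SYLLABLE_FINAL
            else:
                pos = SYLLABLE_MEDIAL
            keys.append(("phonographeme", (seg.notation, seg.phoneme_str, pos)))
            keys.append(("grapheme", (seg.notation, pos)))
            keys.append(("phoneme", (seg.phoneme_str, pos)))
        for si, syll in enumerate(sylls):
            if syll.onset:
                letters = "".join(s.notation for s in syll.onset)
                phons = "".join(s.phoneme_str for s in syll.onset)
                pos = ONSET_WORD_INITIAL if si == 0 else ONSET_SYLLABLE_INITIAL
                keys.append(("onset", (letters, phons, pos)))
                keys.append(("onset_graphemic", (letters, pos)))
                keys.append(("onset_phonemic", (phons, pos)))
            rime_segs = [syll.nucleus, *syll.coda]
            # orthographic letters: weave a silent-E tail after the coda,
            # displace a non-linear E to the end
            nuc = syll.nucleus
            if "_" in nuc.notation:
                head, tail = nuc.notation.split("_")
                letters = head + "".join(s.notation for s in syll.coda) + tail
            elif nuc.nonlinear:
                letters = "".join(s.notation for s in syll.coda) + nuc.notation
            else:
                letters = "".join(s.notation for s in rime_segs)
            phons = "".join(s.phoneme_str for s in rime_segs)
            pos = RIME_WORD_FINAL if si == len(sylls) - 1 else RIME_SYLLABLE_FINAL
            keys.append(("rime", (letters, phons, pos)))
            keys.append(("rime_graphemic", (letters, pos)))
            keys.append(("rime_phonemic", (phons, pos)))
        if self.tables.counting_mode == "words":
            keys = list(dict.fromkeys(keys))
        for name, key in keys:
            self.tables.table(name)[key] += 1
        self.tables.n_words += 1


def _mapping_string(sylls: Sequence[_Syll]) -> str:
    parts: list[str] = []
    for si, syll in enumerate(sylls):
        toks = [
            f"{s.notation}{'~' if s.nonlinear else '>'}{s.phoneme_str}"
            for s in syll.segments
        ]
        parts.append("|".join(toks))
    return "-".join(parts)


def _spelling(sylls: Sequence[_Syll]) -> str:
    out: list[str] = []
    pending: str | None = None
    for syll in sylls:
        for seg in syll.orth_segments:
            if "_" in seg.notation:
                head, tail = seg.notation.split("_")
                out.append(head)
                pending = tail
            else:
                out.append(seg.notation)
                if pending is not None and not seg.is_vowel:
                    out.append(pending)
                    pending = None
    return "".join(out)


def generate_synthetic_corpus(
    spec: SynthSpec, mode: str = "instances"
) -> tuple[list[AlignedWord], CountTables]:
    """Generate a synthetic aligned corpus and its ground-truth count tables.

    Every word is validated through the mapping-notation parser, so each
    returned :class:`AlignedWord` satisfies the word-level invariants and has
    MOP-consistent syllable spans. The ground-truth tables come from the
    generator's own tally, not from the tables module.
    """
    spec = _dc_replace(
        spec,
        **(
            dict(
                p_multi_letter=0.0,
                p_silent_e=0.0,
                p_nonlinear_e=0.0,
                p_x_cluster=0.0,
                p_onset_cluster=0.0,
            )
            if spec.abstract
            else {}
        ),
    )
    rng = random.Random(spec.seed)
    inv = default_inventory()
    onsets = default_onsets()
    tally = _Tally(mode)
    words: list[AlignedWord] = []
    seen_records: set[tuple[str, str]] = set()
    pron_id_of: dict[str, int] = {}

    consonants = sorted(CONSONANT_GRAPHEMES)
    vowels = sorted(VOWEL_GRAPHEMES)

    def consonant_seg(symbol: str) -> _Seg:
        options = CONSONANT_GRAPHEMES.get(symbol) or CLUSTER_GRAPHEMES[symbol]
        if len(options) > 1 and rng.random() < spec.p_multi_letter:
            notation = rng.choice(options[1:])
        else:
            notation = options[0]
        return _Seg(notation=notation, phonemes=(symbol,))

    def vowel_seg(symbol: str) -> _Seg:
        options = VOWEL_GRAPHEMES[symbol]
        if len(options) > 1 and rng.random() < spec.p_multi_letter:
            notation = rng.choice(options[1:])
        else:
            notation = options[0]
        return _Seg(notation=notation, phonemes=(symbol,), is_vowel=True)

    def sample_onset_symbols() -> tuple[str, ...]:
        if rng.random() >= spec.p_onset:
            return ()
        if rng.random() < spec.p_onset_cluster:
            return rng.choice(ONSET_CLUSTERS)
        return (rng.choice(consonants),)

    def make_syllable(final: bool) -> _Syll:
        syll = _Syll()
        if final and rng.random() < spec.p_nonlinear_e:
            syll.onset = [consonant_seg(s) for s in sample_onset_symbols()]
            v = rng.choice(("ə", "ʌ"))
            syll.nucleus = _Seg(notation="E", phonemes=(v,), nonlinear=True, is_vowel=True)
            syll.coda = [consonant_seg(rng.choice(consonants))]
            return syll
        if rng.random() < spec.p_silent_e:
            syll.onset = [consonant_seg(s) for s in sample_onset_symbols()]
            v = rng.choice(sorted(SILENT_E_GRAPHEMES))
            syll.nucleus = _Seg(
                notation=SILENT_E_GRAPHEMES[v], phonemes=(v,), is_vowel=True
            )
            syll.coda = [consonant_seg(rng.choice(consonants))]
            return syll
        syll.onset = [consonant_seg(s) for s in sample_onset_symbols()]
        syll.nucleus = vowel_seg(rng.choice(vowels))
        if rng.random() < spec.p_coda:
            syll.coda = [consonant_seg(rng.choice(consonants))]
        return syll

    def juncture_ok(coda: list[_Seg], onset: list[_Seg]) -> bool:
        """The MOP must split coda+onset exactly where we intend."""
        run = [p for s in (*coda, *onset) for p in s.phonemes]
        intended = [p for s in onset for p in s.phonemes]
        for j in range(len(run) + 1):
            if is_legal_onset(run[j:], onsets, inv):
                return run[j:] == intended
        return not intended

    def make_word() -> list[_Syll] | None:
        n_syll = rng.choices(
            range(1, len(spec.syllable_weights) + 1), weights=spec.syllable_weights
        )[0]
        sylls = [make_syllable(final=(i == n_syll - 1)) for i in range(n_syll)]
        for i in range(n_syll - 1):
            if (
                rng.random() < spec.p_x_cluster
                and "_" not in sylls[i].nucleus.notation
                and not sylls[i].nucleus.nonlinear
            ):
                cluster = rng.choice((("k", "s"), ("g", "z")))
                sylls[i].coda = [_Seg(notation="X", phonemes=cluster)]
                sylls[i + 1].onset = []
                continue
            ok = juncture_ok(sylls[i].coda, sylls[i + 1].onset)
            for _ in range(40):
                if ok:
                    break
                sylls[i + 1].onset = [
                    consonant_seg(s) for s in sample_onset_symbols()
                ]
                ok = juncture_ok(sylls[i].coda, sylls[i + 1].onset)
            if not ok:
                return None
        return sylls

    def emit(sylls: list[_Syll]) -> bool:
        spelling = _spelling(sylls)
        mapping = _mapping_string(sylls)
        if (spelling, mapping) in seen_records:
            return False
        seen_records.add((spelling, mapping))
        pron_id = pron_id_of.get(spelling, 0)
        pron_id_of[spelling] = pron_id + 1
        word = parse_mapping_notation(spelling, mapping, pron_id)
        words.append(word)
        tally.add_word(sylls)
        return True

    attempts = 0
    while len(words) < spec.n_words and attempts < spec.n_words * 200:
        attempts += 1
        sylls = make_word()
        if sylls is None or not emit(sylls):
            continue
        if len(words) < spec.n_words and rng.random() < spec.p_homograph:
            variant = _homograph_variant(sylls, rng)
            if variant is not None:
                emit(variant)
    if len(words) < spec.n_words:
        raise RuntimeError(
            "degenerate synthetic spec: could not generate enough distinct words"
        )
    return words, tally.tables


def _homograph_variant(
    sylls: list[_Syll], rng: random.Random
) -> list[_Syll] | None:
    """Same spelling, one nucleus phoneme changed (an alternative pronunciation)."""
    import copy

    variant = copy.deepcopy(sylls)
    idx = rng.randrange(len(variant))
    nuc = variant[idx].nucleus
    if nuc.nonlinear:
        nuc.phonemes = ("ʌ",) if nuc.phonemes == ("ə",) else ("ə",)
    elif "_" in nuc.notation:
        others = [v for v in sorted(SILENT_E_GRAPHEMES) if v != nuc.phonemes[0]]
        # the notation (hence the spelling) stays; only the vowel changes
        nuc.phonemes = (rng.choice(others),)
    else:
        others = [v for v in sorted(VOWEL_GRAPHEMES) if v != nuc.phonemes[0]]
        nuc.phonemes = (rng.choice(others),)
    return variant


def oracle_counts(
    corpus: Iterable[AlignedWord], mode: str = "instances"
) -> CountTables:
    """Naive nested-loop enumeration of every unit occurrence.

    Intentionally simple and independent of the tables module's counting path
    (positions and onset/rime units are recomputed here from the raw segment
    and span structure, ignoring any stored position codes).
    """
    tables = CountTables(counting_mode=mode)
    for word in corpus:
        keys: list[tuple[str, tuple]] = []
        spans = word.syllable_spans
        orth: list[int] = []
        for a, b in spans:
            orth += [i for i in range(a, b) if not word.segments[i].nonlinear]
            orth += [i for i in range(a, b) if word.segments[i].nonlinear]
        syll_of = {}
        for si, (a, b) in enumerate(spans):
            for i in range(a, b):
                syll_of[i] = si
        first_of, last_of = {}, {}
        for rank, i in enumerate(orth):
            first_of.setdefault(syll_of[i], rank)
            last_of[syll_of[i]] = rank
        for rank, i in enumerate(orth):
            seg = word.segments[i]
            si = syll_of[i]
            if rank == 0:
                pos = WORD_INITIAL
            elif rank == len(orth) - 1:
                pos = WORD_FINAL
            elif rank == first_of[si] and si > 0:
                pos = SYLLABLE_INITIAL
            elif rank == last_of[si] and si < len(spans) - 1:
                pos = SYLLABLE_FINAL
            else:
                pos = SYLLABLE_MEDIAL
            g, p = seg.grapheme.notation, seg.phoneme_str
            keys.append(("phonographeme", (g, p, pos)))
            keys.append(("grapheme", (g, pos)))
            keys.append(("phoneme", (p, pos)))
        for si, (a, b) in enumerate(spans):
            nucleus = next(
                i for i in range(a, b) if word.segments[i].is_vowel_bearing
            )
            onset_idx = list(range(a, nucleus))
            rime_idx = list(range(nucleus, b))
            if onset_idx:
                letters = "".join(
                    word.segments[i].grapheme.letters for i in onset_idx
                )
                phons = "".join(word.segments[i].phoneme_str for i in onset_idx)
                pos = ONSET_WORD_INITIAL if si == 0 else ONSET_SYLLABLE_INITIAL
                keys.append(("onset", (letters, phons, pos)))
                keys.append(("onset_graphemic", (letters, pos)))
                keys.append(("onset_phonemic", (phons, pos)))
            # orthographic rime letters, woven naively
            rime_orth = [i for i in rime_idx if not word.segments[i].nonlinear] + [
                i for i in rime_idx if word.segments[i].nonlinear
            ]
            parts: list[str] = []
            pending = None
            for i in rime_orth:
                g = word.segments[i].grapheme
                if g.discontinuous:
                    has_follower = any(
                        word.segments[j].is_consonantal
                        and not word.segments[j].nonlinear
                        for j in rime_orth[rime_orth.index(i) + 1 :]
                    )
                    if has_follower:
                        parts.append(g.head)
                        pending = g.tail
                    else:
                        parts.append(g.notation)
                else:
                    parts.append(g.letters)
                    if pending is not None and word.segments[i].is_consonantal:
                        parts.append(pending)
                        pending = None
            letters = "".join(parts)
            phons = "".join(word.segments[i].phoneme_str for i in rime_idx)
            pos = RIME_WORD_FINAL if si == len(spans) - 1 else RIME_SYLLABLE_FINAL
            keys.append(("rime", (letters, phons, pos)))
            keys.append(("rime_graphemic", (letters, pos)))
            keys.append(("rime_phonemic", (phons, pos)))
        if mode == "words":
            keys = list(dict.fromkeys(keys))
        for name, key in keys:
            tables.table(name)[key] += 1
        tables.n_words += 1
    return tables
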