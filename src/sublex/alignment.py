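"""Phoneme–grapheme alignment, position coding, and the grapheme inventory.

A word is represented as an ordered sequence of aligned segments, each pairing
one grapheme (one or more letters, possibly discontinuous as in the silent-E
grapheme ``A_E``) with one phoneme — the letter X being the single exception,
a one-grapheme consonant cluster (/ks/, /gz/, ...). Segments are stored in
*phonological* order, which matches the mapping notation (``O>w|E~ʌ|N>n`` for
ONE); the orthographic order needed for position coding is derived from it
(a non-linear E's letter is displaced to the end of its syllable).

Mapping notation
----------------
``GRAPHEME>phoneme`` pairs separated by ``|``, with ``-`` in place of ``|`` at
syllable boundaries, ``~`` instead of ``>`` for a non-linear final E, ``_``
marking the gap of a discontinuous grapheme, and X clusters written with both
phonemes (``X>ks``). Examples::

    WEIGH   W>w|EIGH>eɪ
    ROGUE   R>ɹ|O_E>oʊ|GU>g
    ONE     O>w|E~ʌ|N>n
    MUSCLE  M>m|U>ʌ-SC>s|E~ə|L>l
    TAXI    T>t|A>æ|X>ks-I>i

Syllable spans always follow the Maximum Onset Principle parse of the
pronunciation, with one override: a letter-X cluster straddling a syllable
boundary is pinned to the earlier syllable (TAXI -> TAX-I).

Position coding uses the five-category both-ends scheme (word-initial,
syllable-initial, syllable-medial, syllable-final, word-final) at the
phonographeme grain, and a two-way word/syllable scheme for onsets and rimes.
"""

from __future__ import annotations

import io
import unicodedata
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

from .phonology import (
    InventoryError,
    OnsetTable,
    Phoneme,
    PhonemeInventory,
    _data_lines,
    _read_data_text,
    default_inventory,
    default_onsets,
    mop_syllabify,
)

__all__ = [
    "WORD_INITIAL",
    "SYLLABLE_INITIAL",
    "SYLLABLE_MEDIAL",
    "SYLLABLE_FINAL",
    "WORD_FINAL",
    "PG_POSITIONS",
    "ONSET_WORD_INITIAL",
    "ONSET_SYLLABLE_INITIAL",
    "RIME_WORD_FINAL",
    "RIME_SYLLABLE_FINAL",
    "OR_POSITIONS",
    "NONLINEAR_E_PHONEMES",
    "Grapheme",
    "AlignedSegment",
    "AlignedWord",
    "OnsetRimeUnit",
    "GraphemeInventory",
    "MappingError",
    "AlignmentFailure",
    "x_cluster_table",
    "parse_mapping_notation",
    "format_mapping_notation",
    "assign_positions",
    "derive_onset_rime_units",
    "auto_align",
    "read_corpus_tsv",
    "write_corpus_tsv",
]

# --- position codes ---------------------------------------------------------

WORD_INITIAL = "word_initial"
SYLLABLE_INITIAL = "syllable_initial"
SYLLABLE_MEDIAL = "syllable_medial"
SYLLABLE_FINAL = "syllable_final"
WORD_FINAL = "word_final"
PG_POSITIONS = (
    WORD_INITIAL,
    SYLLABLE_INITIAL,
    SYLLABLE_MEDIAL,
    SYLLABLE_FINAL,
    WORD_FINAL,
)

ONSET_WORD_INITIAL = "onset_word_initial"
ONSET_SYLLABLE_INITIAL = "onset_syllable_initial"
RIME_WORD_FINAL = "rime_word_final"
RIME_SYLLABLE_FINAL = "rime_syllable_final"
OR_POSITIONS = (
    ONSET_WORD_INITIAL,
    ONSET_SYLLABLE_INITIAL,
    RIME_WORD_FINAL,
    RIME_SYLLABLE_FINAL,
)

#: vowels a word-final non-linear E may realize
NONLINEAR_E_PHONEMES = ("ə", "ʌ")


class MappingError(ValueError):
    """A mapping string or aligned word fails structural validation."""


@lru_cache(maxsize=1)
def x_cluster_table() -> tuple[tuple[str, ...], ...]:
    """Admissible phoneme clusters for a letter-X grapheme."""
    return tuple(
        tuple(fields) for fields in _data_lines(_read_data_text("x_clusters.txt"))
    )


# --- core types -------------------------------------------------------------


@dataclass(frozen=True)
class Grapheme:
    """One or more letters functioning as the spelling of a single phoneme.

    ``notation`` is the canonical uppercase string, with ``_`` marking the gap
    of a discontinuous (silent-E) grapheme, e.g. ``A_E`` or ``EA_E``.
    """

    notation: str

    def __post_init__(self) -> None:
        if not self.notation or self.notation.count("_") > 1:
            raise MappingError(f"bad grapheme notation {self.notation!r}")
        if self.notation != self.notation.upper():
            raise MappingError(f"grapheme letters must be uppercase: {self.notation!r}")
        if self.discontinuous:
            head, tail = self.notation.split("_")
            if not head or not tail or not tail.endswith("E"):
                raise MappingError(
                    f"discontinuous grapheme must end in E: {self.notation!r}"
                )
        if not self.notation.replace("_", "").isalpha():
            raise MappingError(f"bad grapheme notation {self.notation!r}")

    @property
    def discontinuous(self) -> bool:
        return "_" in self.notation

    @property
    def head(self) -> str:
        """Letters before the gap (the whole notation if contiguous)."""
        return self.notation.split("_")[0]

    @property
    def tail(self) -> str:
        """Letters after the gap (empty if contiguous)."""
        return self.notation.split("_")[1] if self.discontinuous else ""

    @property
    def letters(self) -> str:
        return self.notation.replace("_", "")

    @property
    def has_x(self) -> bool:
        return "X" in self.notation

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation


@dataclass(frozen=True)
class AlignedSegment:
    """One grapheme paired with its phoneme(s).

    ``phonemes`` has length 1 except for letter-X graphemes (length 2).
    ``nonlinear`` marks a final-E segment realizing /ə/ or /ʌ/ whose letter is
    orthographically displaced after its syllable's final consonant(s).
    ``position`` is the phonographeme-grain position code, or ``None`` before
    :func:`assign_positions` runs.
    """

    grapheme: Grapheme
    phonemes: tuple[Phoneme, ...]
    nonlinear: bool = False
    position: str | None = None

    def __post_init__(self) -> None:
        if len(self.phonemes) not in (1, 2):
            raise MappingError("a segment maps to one phoneme (two only for X)")
        if len(self.phonemes) == 2:
            if not self.grapheme.has_x:
                raise MappingError(
                    f"two-phoneme mapping requires an X grapheme, got "
                    f"{self.grapheme.notation!r}"
                )
            cluster = tuple(p.symbol for p in self.phonemes)
            if cluster not in x_cluster_table():
                raise MappingError(f"inadmissible X cluster /{''.join(cluster)}/")
        if self.nonlinear:
            if self.grapheme.notation != "E" or len(self.phonemes) != 1:
                raise MappingError("non-linear marking is only for a final E grapheme")
            if self.phonemes[0].symbol not in NONLINEAR_E_PHONEMES:
                raise MappingError(
                    f"non-linear E realizes /ə/ or /ʌ/, got "
                    f"/{self.phonemes[0].symbol}/"
                )

    @property
    def phoneme_str(self) -> str:
        return "".join(p.symbol for p in self.phonemes)

    @property
    def is_vowel_bearing(self) -> bool:
        return any(p.is_vowel for p in self.phonemes)

    @property
    def is_consonantal(self) -> bool:
        return not self.is_vowel_bearing


def _derive_syllable_spans(
    segments: Sequence[AlignedSegment],
    onsets: OnsetTable | None = None,
    inventory: PhonemeInventory | None = None,
) -> tuple[tuple[int, int], ...]:
    """Partition segments into syllables via the MOP parse of the pronunciation.

    A segment straddling a boundary (only possible for letter-X clusters) is
    pinned to the earlier syllable.
    """
    seg_of_phoneme: list[int] = []
    phonemes: list[Phoneme] = []
    for i, seg in enumerate(segments):
        for p in seg.phonemes:
            phonemes.append(p)
            seg_of_phoneme.append(i)
    sylls = mop_syllabify(phonemes, onsets, inventory)
    syll_of_phoneme: list[int] = []
    for si, s in enumerate(sylls):
        syll_of_phoneme.extend([si] * len(s.phonemes))

    seg_syll = [
        min(
            syll_of_phoneme[j]
            for j in range(len(phonemes))
            if seg_of_phoneme[j] == i
        )
        for i in range(len(segments))
    ]
    for a, b in zip(seg_syll, seg_syll[1:]):
        if b < a:
            raise MappingError("segments are not in non-decreasing syllable order")
    spans: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(segments) + 1):
        if i == len(segments) or seg_syll[i] != seg_syll[start]:
            spans.append((start, i))
            start = i
    for start, end in spans:
        n_vowel = sum(1 for s in segments[start:end] if s.is_vowel_bearing)
        if n_vowel != 1:
            raise MappingError(
                f"syllable span {start}:{end} has {n_vowel} vowel-bearing "
                "segments (needs exactly 1)"
            )
    return tuple(spans)


@dataclass(frozen=True)
class AlignedWord:
    """A spelling/pronunciation pair decomposed into aligned segments.

    ``segments`` are in phonological order; ``syllable_spans`` partitions them
    into syllables (half-open index ranges) consistent with the MOP parse of
    the pronunciation, with the letter-X override. ``pronunciation_id``
    distinguishes multiple pronunciations of one spelling (homographs).
    """

    spelling: str
    segments: tuple[AlignedSegment, ...]
    syllable_spans: tuple[tuple[int, int], ...]
    pronunciation_id: int = 0
    initial_onset_flagged: bool = field(default=False, compare=False)

    @property
    def phonemes(self) -> tuple[Phoneme, ...]:
        return tuple(p for seg in self.segments for p in seg.phonemes)

    @property
    def pronunciation(self) -> str:
        return "".join(p.symbol for p in self.phonemes)

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_spans)

    def syllable_of_segment(self, i: int) -> int:
        for si, (a, b) in enumerate(self.syllable_spans):
            if a <= i < b:
                return si
        raise IndexError(i)

    def orthographic_order(self) -> tuple[int, ...]:
        """Segment indices in spelling order (non-linear E's move to syllable end)."""
        order: list[int] = []
        for a, b in self.syllable_spans:
            deferred = [i for i in range(a, b) if self.segments[i].nonlinear]
            order.extend(i for i in range(a, b) if not self.segments[i].nonlinear)
            order.extend(deferred)
        return tuple(order)

    def reconstruct_spelling(self) -> str:
        """Rebuild the spelling from the segments (validation round trip)."""
        out: list[str] = []
        pending_tail: str | None = None
        for i in self.orthographic_order():
            seg = self.segments[i]
            g = seg.grapheme
            if g.discontinuous:
                if pending_tail is not None:
                    raise MappingError("overlapping discontinuous graphemes")
                out.append(g.head)
                pending_tail = g.tail
            else:
                out.append(g.letters)
                if pending_tail is not None and seg.is_consonantal:
                    out.append(pending_tail)
                    pending_tail = None
        if pending_tail is not None:
            raise MappingError(
                "discontinuous grapheme has no following consonant grapheme"
            )
        return "".join(out)

    def validate(self) -> None:
        """Check the word-level invariants; raise :class:`MappingError` if broken."""
        rebuilt = self.reconstruct_spelling()
        if rebuilt != self.spelling:
            raise MappingError(
                f"letters unaccounted for: segments spell {rebuilt!r}, "
                f"record says {self.spelling!r}"
            )
        if not self.syllable_spans or self.syllable_spans[0][0] != 0:
            raise MappingError("syllable spans must start at segment 0")
        prev_end = 0
        for a, b in self.syllable_spans:
            if a != prev_end or b <= a:
                raise MappingError("syllable spans must be contiguous and non-empty")
            prev_end = b
        if prev_end != len(self.segments):
            raise MappingError("syllable spans must cover all segments")


@dataclass(frozen=True)
class OnsetRimeUnit:
    """An onset or rime with its letters, phonemes, and position code."""

    kind: str  # "onset" | "rime"
    letters: str
    phoneme_str: str
    position: str
    segment_indices: tuple[int, ...]


@dataclass(frozen=True)
class AlignmentFailure:
    """Report for a spelling/pronunciation pair that could not be aligned."""

    spelling: str
    pronunciation: str
    furthest_letter: int
    furthest_phoneme: int

    def __bool__(self) -> bool:
        return False


# --- mapping notation -------------------------------------------------------


def _tokenize_mapping(mapping: str) -> tuple[list[str], list[bool]]:
    """Split on ``|``/``-``; return tokens and a boundary flag per separator."""
    tokens: list[str] = []
    boundary_after: list[bool] = []
    cur = io.StringIO()
    for ch in mapping:
        if ch in "|-":
            tokens.append(cur.getvalue())
            boundary_after.append(ch == "-")
            cur = io.StringIO()
        else:
            cur.write(ch)
    tokens.append(cur.getvalue())
    return tokens, boundary_after


def parse_mapping_notation(
    spelling: str,
    mapping: str,
    pronunciation_id: int = 0,
    phoneme_inventory: PhonemeInventory | None = None,
    onsets: OnsetTable | None = None,
) -> AlignedWord:
    """Parse the toolkit's mapping notation into a validated AlignedWord.

    Syllable-boundary markers (``-``) are optional; when present they must
    agree with the MOP parse of the pronunciation (letter-X override applied).
    Positions are assigned before returning. The result round-trips through
    :func:`format_mapping_notation` bit-exactly for canonical records.
    """
    phoneme_inventory = phoneme_inventory or default_inventory()
    mapping = unicodedata.normalize("NFC", mapping.strip())
    spelling = spelling.strip().upper()
    tokens, boundary_after = _tokenize_mapping(mapping)
    segments: list[AlignedSegment] = []
    marked_breaks: set[int] = set()  # segment index starting a new syllable
    for t_idx, token in enumerate(tokens):
        nonlinear = "~" in token
        sep = "~" if nonlinear else ">"
        if sep not in token:
            raise MappingError(f"malformed mapping token {token!r} in {mapping!r}")
        notation, phon = token.split(sep, 1)
        try:
            phonemes = phoneme_inventory.tokenize(phon)
        except InventoryError as e:
            raise MappingError(f"in token {token!r}: {e}") from e
        segments.append(
            AlignedSegment(
                grapheme=Grapheme(notation.strip().upper()),
                phonemes=phonemes,
                nonlinear=nonlinear,
            )
        )
        if t_idx < len(boundary_after) and boundary_after[t_idx]:
            marked_breaks.add(t_idx + 1)

    spans = _derive_syllable_spans(segments, onsets, phoneme_inventory)
    if marked_breaks:
        derived_breaks = {a for a, _ in spans[1:]}
        if marked_breaks != derived_breaks:
            raise MappingError(
                f"marked syllable boundaries {sorted(marked_breaks)} disagree "
                f"with the MOP parse {sorted(derived_breaks)} for {spelling!r}"
            )
    word = AlignedWord(
        spelling=spelling,
        segments=tuple(segments),
        syllable_spans=spans,
        pronunciation_id=pronunciation_id,
    )
    word.validate()
    return assign_positions(word)


def format_mapping_notation(word: AlignedWord) -> str:
    """Serialize an AlignedWord to canonical mapping notation."""
    breaks = {a for a, _ in word.syllable_spans[1:]}
    parts: list[str] = []
    for i, seg in enumerate(word.segments):
        if i:
            parts.append("-" if i in breaks else "|")
        sep = "~" if seg.nonlinear else ">"
        parts.append(f"{seg.grapheme.notation}{sep}{seg.phoneme_str}")
    return "".join(parts)


# --- position coding --------------------------------------------------------


def assign_positions(word: AlignedWord) -> AlignedWord:
    """Assign the five-category both-ends position code to every segment.

    In orthographic order: the first segment of the word is word-initial and
    the last word-final (word edges take precedence; a single-segment word is
    coded word-initial); the first segment of a non-initial syllable is
    syllable-initial, the last segment of a non-final syllable
    syllable-final, everything else syllable-medial.
    """
    order = word.orthographic_order()
    n = len(order)
    span_of = {i: word.syllable_of_segment(i) for i in range(len(word.segments))}
    # per-syllable orthographic first/last segment
    first_in_span: dict[int, int] = {}
    last_in_span: dict[int, int] = {}
    for rank, i in enumerate(order):
        s = span_of[i]
        first_in_span.setdefault(s, rank)
        last_in_span[s] = rank
    n_spans = len(word.syllable_spans)
    positions: dict[int, str] = {}
    for rank, i in enumerate(order):
        s = span_of[i]
        if rank == 0:
            pos = WORD_INITIAL
        elif rank == n - 1:
            pos = WORD_FINAL
        elif rank == first_in_span[s] and s > 0:
            pos = SYLLABLE_INITIAL
        elif rank == last_in_span[s] and s < n_spans - 1:
            pos = SYLLABLE_FINAL
        else:
            pos = SYLLABLE_MEDIAL
        positions[i] = pos
    new_segments = tuple(
        replace(seg, position=positions[i]) for i, seg in enumerate(word.segments)
    )
    return replace(word, segments=new_segments)


def _unit_letters(word: AlignedWord, indices: Sequence[int]) -> str:
    """Orthographic string of a unit, weaving silent-E tails when the gap
    consonant is inside the unit and falling back to underscore notation when
    it is not."""
    idx = set(indices)
    # orthographic order restricted to the unit
    order = [i for i in word.orthographic_order() if i in idx]
    out: list[str] = []
    pending: str | None = None
    for i in order:
        seg = word.segments[i]
        g = seg.grapheme
        if g.discontinuous:
            follower_inside = any(
                word.segments[j].is_consonantal and not word.segments[j].nonlinear
                for j in order[order.index(i) + 1 :]
            )
            if follower_inside:
                out.append(g.head)
                pending = g.tail
            else:
                out.append(g.notation)
        else:
            out.append(g.letters)
            if pending is not None and seg.is_consonantal:
                out.append(pending)
                pending = None
    return "".join(out)


def derive_onset_rime_units(word: AlignedWord) -> tuple[OnsetRimeUnit, ...]:
    """Emit per-syllable onset and rime units with their position codes.

    Onsets absent from a syllable are not emitted. A letter-X cluster pinned
    to the earlier syllable keeps both its phonemes in that syllable's rime.
    """
    units: list[OnsetRimeUnit] = []
    n_spans = len(word.syllable_spans)
    for si, (a, b) in enumerate(word.syllable_spans):
        nucleus = next(
            i for i in range(a, b) if word.segments[i].is_vowel_bearing
        )
        onset_idx = tuple(range(a, nucleus))
        rime_idx = tuple(range(nucleus, b))
        if onset_idx:
            units.append(
                OnsetRimeUnit(
                    kind="onset",
                    letters=_unit_letters(word, onset_idx),
                    phoneme_str="".join(
                        word.segments[i].phoneme_str for i in onset_idx
                    ),
                    position=ONSET_WORD_INITIAL if si == 0 else ONSET_SYLLABLE_INITIAL,
                    segment_indices=onset_idx,
                )
            )
        units.append(
            OnsetRimeUnit(
                kind="rime",
                letters=_unit_letters(word, rime_idx),
                phoneme_str="".join(word.segments[i].phoneme_str for i in rime_idx),
                position=RIME_WORD_FINAL if si == n_spans - 1 else RIME_SYLLABLE_FINAL,
                segment_indices=rime_idx,
            )
        )
    return tuple(units)


# --- grapheme inventory -----------------------------------------------------


class GraphemeInventory:
    """The attested (phoneme string, grapheme, position) mapping set.

    Built from an aligned corpus; used by :func:`auto_align` to segment new
    spellings and by position-admissibility checks (e.g. /p/ -> PP is
    attested syllable-initially but never word-initially).
    """

    def __init__(self, version: str = "0"):
        self.version = version
        self._entries: dict[tuple[str, str], dict[str, int]] = {}

    # -- building

    def add(self, phoneme_str: str, notation: str, position: str, count: int = 1) -> None:
        per_pos = self._entries.setdefault((phoneme_str, notation), {})
        per_pos[position] = per_pos.get(position, 0) + count

    def add_word(self, word: AlignedWord) -> None:
        for seg in word.segments:
            if seg.position is None:
                raise MappingError("assign positions before building an inventory")
            self.add(seg.phoneme_str, seg.grapheme.notation, seg.position)

    @classmethod
    def from_corpus(
        cls, words: Iterable[AlignedWord], version: str = "0"
    ) -> "GraphemeInventory":
        inv = cls(version=version)
        for w in words:
            inv.add_word(w)
        return inv

    # -- queries

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> Iterator[tuple[str, str, str, int]]:
        for (p, g), per_pos in sorted(self._entries.items()):
            for pos, c in sorted(per_pos.items()):
                yield p, g, pos, c

    def count(self, phoneme_str: str, notation: str, position: str | None = None) -> int:
        per_pos = self._entries.get((phoneme_str, notation), {})
        if position is None:
            return sum(per_pos.values())
        return per_pos.get(position, 0)

    def admissible(self, phoneme_str: str, notation: str, position: str) -> bool:
        """True iff the mapping is attested in this position."""
        return self.count(phoneme_str, notation, position) > 0

    @property
    def graphemes(self) -> set[str]:
        return {g for _, g in self._entries}

    # -- serialization

    def to_tsv(self) -> str:
        lines = ["phoneme\tgrapheme\tposition\tcount\ttotal"]
        for p, g, pos, c in self.entries():
            lines.append(f"{p}\t{g}\t{pos}\t{c}\t{self.count(p, g)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, version: str = "0") -> "GraphemeInventory":
        inv = cls(version=version)
        for i, line in enumerate(text.splitlines()):
            if not line.strip() or line.startswith("#") or i == 0:
                continue
            p, g, pos, c = line.split("\t")[:4]
            inv.add(p, g, pos, int(c))
        return inv


# --- automatic alignment ----------------------------------------------------


def auto_align(
    spelling: str,
    phonemes: Sequence[Phoneme] | str,
    inventory: GraphemeInventory,
    pronunciation_id: int = 0,
    phoneme_inventory: PhonemeInventory | None = None,
    onsets: OnsetTable | None = None,
    max_candidates: int = 500,
) -> AlignedWord | AlignmentFailure:
    """Align a spelling to a pronunciation using the grapheme inventory.

    A dynamic program over (letter index, phoneme index) enumerates
    segmentations of the spelling into attested graphemes whose concatenated
    phonemes reproduce the pronunciation, with special transitions for
    discontinuous silent-E graphemes, a word-final non-linear E, and letter-X
    clusters. Among complete alignments the winner maximizes, in order:
    position admissibility of every segment, the product of inventory
    attestation counts, parsimony (fewest segments), then leftmost-longest
    graphemes. Returns an :class:`AlignmentFailure` naming the
    furthest-reached indices when no complete path exists.
    """
    phoneme_inventory = phoneme_inventory or default_inventory()
    spelling = spelling.strip().upper()
    if isinstance(phonemes, str):
        phonemes = phoneme_inventory.tokenize(phonemes)
    phonemes = tuple(phonemes)
    n_l, n_p = len(spelling), len(phonemes)
    if not n_l or not n_p:
        raise MappingError("auto_align needs a non-empty spelling and pronunciation")

    # index the inventory by letters
    contiguous: dict[str, set[str]] = {}
    discont: dict[str, set[tuple[str, str]]] = {}  # head -> {(tail, phoneme_str)}
    for (p, g) in inventory._entries:
        gr = Grapheme(g)
        if gr.discontinuous:
            discont.setdefault(gr.head, set()).add((gr.tail, p))
        else:
            contiguous.setdefault(gr.notation, set()).add(p)
    max_glen = max((len(g) for g in contiguous), default=0)
    max_hlen = max((len(h) for h in discont), default=0)

    furthest = [0, 0]
    candidates: list[tuple[AlignedSegment, ...]] = []
    ends_in_e = spelling.endswith("E")

    from functools import lru_cache as _lru

    @_lru(maxsize=None)
    def expand(li: int, pi: int, pending_tail: str | None, owed_e: bool):
        """All suffix segment tuples from this state (possibly empty list)."""
        if li + pi > furthest[0] + furthest[1]:
            furthest[0], furthest[1] = li, pi
        results: list[tuple[AlignedSegment, ...]] = []
        # completion
        if pi == n_p and pending_tail is None:
            if owed_e and li == n_l - 1:
                return [()]
            if not owed_e and li == n_l:
                return [()]
        if pi >= n_p:
            return results
        # a) contiguous grapheme
        stop = n_l - 1 if owed_e else n_l
        for width in range(1, min(max_glen, stop - li) + 1):
            letters = spelling[li : li + width]
            if letters not in contiguous:
                continue
            for pstr in contiguous[letters]:
                seg_phons = phoneme_inventory.tokenize(pstr)
                k = len(seg_phons)
                if tuple(p.symbol for p in phonemes[pi : pi + k]) != tuple(
                    p.symbol for p in seg_phons
                ):
                    continue
                try:
                    seg = AlignedSegment(
                        grapheme=Grapheme(letters), phonemes=tuple(seg_phons)
                    )
                except MappingError:
                    continue
                new_li = li + width
                new_tail = pending_tail
                if pending_tail is not None:
                    if not seg.is_consonantal:
                        continue  # gap must be bridged by one consonant grapheme
                    if spelling[new_li : new_li + len(pending_tail)] != pending_tail:
                        continue
                    new_li += len(pending_tail)
                    new_tail = None
                for suffix in expand(new_li, pi + k, new_tail, owed_e):
                    results.append((seg, *suffix))
                    if len(candidates) + len(results) >= max_candidates:
                        return results
        # b) discontinuous silent-E grapheme
        if pending_tail is None:
            for width in range(1, min(max_hlen, stop - li) + 1):
                head = spelling[li : li + width]
                if head not in discont:
                    continue
                for tail, pstr in discont[head]:
                    seg_phons = phoneme_inventory.tokenize(pstr)
                    if len(seg_phons) != 1:
                        continue
                    if phonemes[pi].symbol != seg_phons[0].symbol:
                        continue
                    seg = AlignedSegment(
                        grapheme=Grapheme(f"{head}_{tail}"),
                        phonemes=tuple(seg_phons),
                    )
                    for suffix in expand(li + width, pi + 1, tail, owed_e):
                        results.append((seg, *suffix))
        # c) word-final non-linear E (letter consumed at the very end)
        if (
            ends_in_e
            and not owed_e
            and pending_tail is None
            and li < n_l - 1
            and phonemes[pi].symbol in NONLINEAR_E_PHONEMES
            and inventory.count(phonemes[pi].symbol, "E") > 0
        ):
            seg = AlignedSegment(
                grapheme=Grapheme("E"),
                phonemes=(phonemes[pi],),
                nonlinear=True,
            )
            for suffix in expand(li, pi + 1, None, True):
                results.append((seg, *suffix))
        return results

    for segs in expand(0, 0, None, False):
        candidates.append(segs)

    scored: list[tuple[tuple, AlignedWord]] = []
    for segs in candidates:
        try:
            spans = _derive_syllable_spans(segs, onsets, phoneme_inventory)
            word = AlignedWord(
                spelling=spelling,
                segments=tuple(segs),
                syllable_spans=spans,
                pronunciation_id=pronunciation_id,
            )
            word.validate()
            word = assign_positions(word)
        except (MappingError, ValueError):
            continue
        admissible = all(
            inventory.admissible(s.phoneme_str, s.grapheme.notation, s.position)
            for s in word.segments
        )
        product = 1
        for s in word.segments:
            product *= inventory.count(s.phoneme_str, s.grapheme.notation)
        lengths = tuple(len(s.grapheme.letters) for s in word.segments)
        scored.append(((admissible, product, -len(word.segments), lengths), word))

    if not scored:
        return AlignmentFailure(
            spelling=spelling,
            pronunciation="".join(p.symbol for p in phonemes),
            furthest_letter=furthest[0],
            furthest_phoneme=furthest[1],
        )
    scored.sort(key=lambda t: t[0], reverse=True)
    return scored[0][1]


# --- corpus file interface --------------------------------------------------

CORPUS_HEADER = ("spelling", "pronunciation", "mapping", "pron_id")


def read_corpus_tsv(
    text: str,
    phoneme_inventory: PhonemeInventory | None = None,
    onsets: OnsetTable | None = None,
    strict: bool = True,
) -> tuple[list[AlignedWord], list[tuple[int, str]]]:
    """Read a corpus TSV (``spelling pronunciation mapping pron_id``).

    ``#`` lines are comments. Rows whose mapping column is empty are skipped
    (they are auto-alignment candidates, not parsed records). Returns the
    parsed words and a list of (line number, message) for rejected rows; in
    strict mode the first rejection raises instead.
    """
    phoneme_inventory = phoneme_inventory or default_inventory()
    words: list[AlignedWord] = []
    errors: list[tuple[int, str]] = []
    seen: set[tuple[str, int]] = set()
    lines = text.splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "spelling":
            continue  # header row (comments may precede it)
        try:
            spelling = fields[0].strip().upper()
            pron = fields[1].strip() if len(fields) > 1 else ""
            mapping = fields[2].strip() if len(fields) > 2 else ""
            pron_id = int(fields[3]) if len(fields) > 3 and fields[3].strip() else 0
            if not mapping:
                continue
            word = parse_mapping_notation(
                spelling, mapping, pron_id, phoneme_inventory, onsets
            )
            if pron:
                expected = "".join(
                    p.symbol for p in phoneme_inventory.tokenize(pron)
                )
                if word.pronunciation != expected:
                    raise MappingError(
                        f"mapping spells /{word.pronunciation}/ but the "
                        f"pronunciation column says /{expected}/"
                    )
            key = (spelling, pron_id)
            if key in seen:
                raise MappingError(f"duplicate record {key}")
            seen.add(key)
            words.append(word)
        except (MappingError, InventoryError, ValueError, IndexError) as e:
            if strict:
                raise MappingError(f"line {lineno}: {e}") from e
            errors.append((lineno, str(e)))
    return words, errors


def write_corpus_tsv(words: Iterable[AlignedWord]) -> str:
    """Serialize words to the corpus TSV format (canonical notation)."""
    lines = ["\t".join(CORPUS_HEADER)]
    for w in words:
        lines.append(
            "\t".join(
                (
                    w.spelling,
                    w.pronunciation,
                    format_mapping_notation(w),
                    str(w.pronunciation_id),
                )
            )
        )
    return "\n".join(lines) + "\n"
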