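"""Phoneme inventory and Maximum Onset Principle syllabification.

The phonological side of the toolkit: a closed inventory of General American
phoneme symbols (diphthongs and affricates as single units), an English
onset-legality test, and syllabification of pronunciations by the Maximum
Onset Principle (MOP): intervocalic consonants are assigned to the onset of
the following syllable unless that onset would be phonotactically illegal.

Legality is decided against an explicit whitelist of attested English onsets
shipped as editable plain-text data (``data/onsets.txt``); the sonority
hierarchy (stop < fricative < nasal < liquid < glide < vowel) is carried on
each phoneme for diagnostics but is not the legality mechanism, because
verbal sonority rules under-determine the attested cluster set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator, Sequence
import unicodedata

__all__ = [
    "Phoneme",
    "PhonemeInventory",
    "OnsetTable",
    "Syllable",
    "InventoryError",
    "UnsyllabifiableError",
    "default_inventory",
    "default_onsets",
    "is_legal_onset",
    "mop_syllabify",
    "split_onset_rime",
    "arpabet_to_ipa",
]

SONORITY_RANKS = {
    "stop": 1,
    "fricative": 2,
    "nasal": 3,
    "liquid": 4,
    "glide": 5,
    "vowel": 6,
}


class InventoryError(KeyError):
    """A phoneme symbol is not in the closed inventory."""


class UnsyllabifiableError(ValueError):
    """A pronunciation with no vowel cannot be parsed into syllables."""


@dataclass(frozen=True)
class Phoneme:
    """One phonological segment.

    ``symbol`` is an NFC-normalized IPA token (possibly multi-code-point, e.g.
    ``eɪ`` or ``tʃ``); ``klass`` is ``vowel`` or ``consonant``; ``sonority`` is
    the ordinal sonority rank of the phoneme's manner class.
    """

    symbol: str
    klass: str
    sonority: int

    @property
    def is_vowel(self) -> bool:
        return self.klass == "vowel"

    @property
    def s_flag(self) -> bool:
        """True for /s/, the appendix consonant that heads legal clusters."""
        return self.symbol == "s"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.symbol


def _read_data_text(name: str) -> str:
    return resources.files("sublex.data").joinpath(name).read_text("utf-8")


def _data_lines(text: str) -> Iterator[list[str]]:
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            yield line.split("\t") if "\t" in line else line.split()


class PhonemeInventory:
    """Closed table of phoneme symbols with greedy IPA tokenization."""

    def __init__(self, phonemes: Iterable[Phoneme]):
        self._by_symbol: dict[str, Phoneme] = {}
        for p in phonemes:
            if p.symbol in self._by_symbol:
                raise ValueError(f"duplicate phoneme symbol {p.symbol!r}")
            self._by_symbol[p.symbol] = p
        self._max_len = max((len(s) for s in self._by_symbol), default=0)

    @classmethod
    def from_text(cls, text: str) -> "PhonemeInventory":
        phonemes = []
        for fields in _data_lines(text):
            symbol, klass, sclass = fields[0], fields[1], fields[2]
            phonemes.append(
                Phoneme(
                    symbol=unicodedata.normalize("NFC", symbol),
                    klass=klass,
                    sonority=SONORITY_RANKS[sclass],
                )
            )
        return cls(phonemes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self) -> Iterator[Phoneme]:
        return iter(self._by_symbol.values())

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __getitem__(self, symbol: str) -> Phoneme:
        try:
            return self._by_symbol[unicodedata.normalize("NFC", symbol)]
        except KeyError:
            raise InventoryError(f"unknown phoneme symbol {symbol!r}") from None

    def tokenize(self, s: str) -> tuple[Phoneme, ...]:
        """Split an IPA string into inventory phonemes (greedy longest match).

        Spaces are allowed (and ignored) as explicit separators.
        """
        s = unicodedata.normalize("NFC", s)
        out: list[Phoneme] = []
        i = 0
        while i < len(s):
            if s[i].isspace():
                i += 1
                continue
            for width in range(min(self._max_len, len(s) - i), 0, -1):
                cand = s[i : i + width]
                if cand in self._by_symbol:
                    out.append(self._by_symbol[cand])
                    i += width
                    break
            else:
                raise InventoryError(
                    f"unknown phoneme symbol at {s[i:]!r} in {s!r}"
                )
        return tuple(out)


class OnsetTable:
    """Whitelist of attested English onsets (tuples of phoneme symbols)."""

    def __init__(self, onsets: Iterable[Sequence[str]]):
        self._onsets = {tuple(o) for o in onsets}
        self._onsets.add(())  # vowel-initial syllables

    @classmethod
    def from_text(cls, text: str) -> "OnsetTable":
        return cls(tuple(fields) for fields in _data_lines(text))

    def __contains__(self, cluster: Sequence[str]) -> bool:
        return tuple(cluster) in self._onsets

    def __len__(self) -> int:
        return len(self._onsets) - 1


@lru_cache(maxsize=1)
def default_inventory() -> PhonemeInventory:
    return PhonemeInventory.from_text(_read_data_text("phonemes.tsv"))


@lru_cache(maxsize=1)
def default_onsets() -> OnsetTable:
    return OnsetTable.from_text(_read_data_text("onsets.txt"))


@lru_cache(maxsize=1)
def _arpabet_table() -> dict[str, tuple[str, ...]]:
    table: dict[str, tuple[str, ...]] = {}
    for fields in _data_lines(_read_data_text("arpabet_ipa.tsv")):
        table[fields[0]] = tuple(s for f in fields[1:] for s in f.split())
    return table


def arpabet_to_ipa(
    arpabet: Sequence[str] | str,
    inventory: PhonemeInventory | None = None,
) -> tuple[Phoneme, ...]:
    """Translate a CMU-dictionary-style pronunciation to inventory phonemes.

    Lexical stress digits are stripped (they play no role in the mappings),
    except that the table may key the unstressed variant explicitly
    (``AH0`` -> schwa).
    """
    inventory = inventory or default_inventory()
    if isinstance(arpabet, str):
        arpabet = arpabet.split()
    table = _arpabet_table()
    out: list[Phoneme] = []
    for tok in arpabet:
        tok = tok.upper()
        if tok in table:
            ipa = table[tok]
        else:
            stripped = tok.rstrip("012")
            if stripped not in table:
                raise InventoryError(f"unknown ARPAbet symbol {tok!r}")
            ipa = table[stripped]
        out.extend(inventory[s] for s in ipa)
    return tuple(out)


@dataclass(frozen=True)
class Syllable:
    """Onset + obligatory vowel nucleus + coda.

    ``initial_onset_flagged`` marks a word-initial onset that fails the
    legality test (loanword edge case) but was retained rather than rejected.
    """

    onset: tuple[Phoneme, ...]
    nucleus: Phoneme
    coda: tuple[Phoneme, ...]
    initial_onset_flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.nucleus.is_vowel:
            raise ValueError(f"nucleus must be a vowel, got {self.nucleus.symbol!r}")
        for p in (*self.onset, *self.coda):
            if p.is_vowel:
                raise ValueError("onset/coda must contain only consonants")

    @property
    def rime(self) -> tuple[Phoneme, ...]:
        return (self.nucleus, *self.coda)

    @property
    def phonemes(self) -> tuple[Phoneme, ...]:
        return (*self.onset, self.nucleus, *self.coda)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return "".join(p.symbol for p in self.phonemes)


def _symbols(cluster: Sequence[Phoneme | str]) -> tuple[str, ...]:
    return tuple(p.symbol if isinstance(p, Phoneme) else p for p in cluster)


def is_legal_onset(
    cluster: Sequence[Phoneme | str],
    onsets: OnsetTable | None = None,
    inventory: PhonemeInventory | None = None,
) -> bool:
    """True iff ``cluster`` is a permissible English syllable onset.

    The empty cluster is legal (vowel-initial syllables). Membership is
    checked against the attested-onset whitelist. Raises
    :class:`InventoryError` for symbols outside the phoneme inventory, and
    :class:`ValueError` if the cluster contains a vowel.
    """
    onsets = onsets or default_onsets()
    inventory = inventory or default_inventory()
    phonemes = [inventory[s] for s in _symbols(cluster)]
    for p in phonemes:
        if p.is_vowel:
            raise ValueError(f"onset cluster may not contain vowel {p.symbol!r}")
    return _symbols(phonemes) in onsets


def mop_syllabify(
    phonemes: Sequence[Phoneme | str],
    onsets: OnsetTable | None = None,
    inventory: PhonemeInventory | None = None,
) -> tuple[Syllable, ...]:
    """Parse a pronunciation into syllables by the Maximum Onset Principle.

    Each vowel heads one syllable. Every intervocalic consonant run is split
    so that the longest whitelist-legal suffix becomes the next syllable's
    onset and the remainder closes the previous syllable's coda
    (LOBSTER -> LOB-STER, not LO-BSTER nor LOBS-TER). A word-initial
    consonant run that is itself an illegal onset is kept as the first onset
    with ``initial_onset_flagged`` set.
    """
    onsets = onsets or default_onsets()
    inventory = inventory or default_inventory()
    ps = [inventory[s] for s in _symbols(phonemes)]
    vowel_idx = [i for i, p in enumerate(ps) if p.is_vowel]
    if not vowel_idx:
        raise UnsyllabifiableError(
            "pronunciation %r has no vowel" % "".join(p.symbol for p in ps)
        )

    syllables: list[Syllable] = []
    first_onset = tuple(ps[: vowel_idx[0]])
    flagged = bool(first_onset) and not is_legal_onset(first_onset, onsets, inventory)
    onset = first_onset
    for k, vi in enumerate(vowel_idx):
        if k + 1 < len(vowel_idx):
            run = tuple(ps[vi + 1 : vowel_idx[k + 1]])
            # longest legal suffix of the run becomes the next onset
            split = 0
            for j in range(len(run) + 1):
                if is_legal_onset(run[j:], onsets, inventory):
                    split = j
                    break
            coda, next_onset = run[:split], run[split:]
        else:
            coda, next_onset = tuple(ps[vi + 1 :]), ()
        syllables.append(
            Syllable(
                onset=onset,
                nucleus=ps[vi],
                coda=coda,
                initial_onset_flagged=flagged and k == 0,
            )
        )
        onset = next_onset
    return tuple(syllables)


def split_onset_rime(
    syllable: Syllable,
) -> tuple[tuple[Phoneme, ...], tuple[Phoneme, ...]]:
    """Split a syllable into (onset, rime); the rime is never empty."""
    return syllable.onset, syllable.rime
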