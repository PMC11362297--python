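"""Position-keyed, type-weighted count tables over an aligned corpus.

Every corpus record (a spelling/pronunciation pair) contributes with weight
one — counts are weighted by type, not token. Two counting modes exist:

``instances``
    every occurrence of a unit in a word counts; the joint phonographeme
    table then sums exactly to its grapheme and phoneme marginals, so the
    consistency measures normalize to 1 over attested alternatives. Default.
``words``
    a record increments each (unit, position) key at most once — the literal
    "number of words with ..." reading of the defining ratios. A word that
    contains the same grapheme twice in one position with different phonemes
    then breaks exact marginal additivity, which is why ``instances`` is the
    default.

Keys are unit strings: grapheme notation ("EA_E"), phoneme strings ("ks" for
the letter-X cluster, counted as a single phoneme-side key), and onset/rime
letter/phoneme strings, each paired with a position code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alignment import AlignedWord, derive_onset_rime_units

__all__ = ["CountTables", "build_count_tables", "merge_tables"]

MODES = ("instances", "words")

#: (table name, key arity) in serialization order
TABLE_SPECS = (
    ("phonographeme", 3),  # (grapheme, phoneme_str, position)
    ("grapheme", 2),  # (grapheme, position)
    ("phoneme", 2),  # (phoneme_str, position)
    ("onset", 3),  # (letters, phoneme_str, position)
    ("onset_graphemic", 2),
    ("onset_phonemic", 2),
    ("rime", 3),
    ("rime_graphemic", 2),
    ("rime_phonemic", 2),
)


@dataclass
class CountTables:
    """Type-weighted count tables at both grains, keyed by position."""

    counting_mode: str = "instances"
    version: str = "0"
    n_words: int = 0
    phonographeme: Counter = field(default_factory=Counter)
    grapheme: Counter = field(default_factory=Counter)
    phoneme: Counter = field(default_factory=Counter)
    onset: Counter = field(default_factory=Counter)
    onset_graphemic: Counter = field(default_factory=Counter)
    onset_phonemic: Counter = field(default_factory=Counter)
    rime: Counter = field(default_factory=Counter)
    rime_graphemic: Counter = field(default_factory=Counter)
    rime_phonemic: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.counting_mode not in MODES:
            raise ValueError(f"unknown counting mode {self.counting_mode!r}")

    def table(self, name: str) -> Counter:
        if name not in {n for n, _ in TABLE_SPECS}:
            raise KeyError(name)
        return getattr(self, name)

    def _word_keys(self, word: AlignedWord) -> Iterator[tuple[str, tuple]]:
        for seg in word.segments:
            if seg.position is None:
                raise ValueError("assign positions before counting")
            g = seg.grapheme.notation
            p = seg.phoneme_str
            yield "phonographeme", (g, p, seg.position)
            yield "grapheme", (g, seg.position)
            yield "phoneme", (p, seg.position)
        for unit in derive_onset_rime_units(word):
            joint = (unit.letters, unit.phoneme_str, unit.position)
            if unit.kind == "onset":
                yield "onset", joint
                yield "onset_graphemic", (unit.letters, unit.position)
                yield "onset_phonemic", (unit.phoneme_str, unit.position)
            else:
                yield "rime", joint
                yield "rime_graphemic", (unit.letters, unit.position)
                yield "rime_phonemic", (unit.phoneme_str, unit.position)

    def add_word(self, word: AlignedWord) -> None:
        keys = list(self._word_keys(word))
        if self.counting_mode == "words":
            keys = list(dict.fromkeys(keys))  # dedupe, order-preserving
        for name, key in keys:
            self.table(name)[key] += 1
        self.n_words += 1

    # -- serialization -------------------------------------------------------

    def to_tsv(self, name: str) -> str:
        """One table as TSV with an explicit position column, sorted for
        diffability."""
        _, arity = next(spec for spec in TABLE_SPECS if spec[0] == name)
        if arity == 3:
            header = "graphemic\tphonemic\tposition\tcount"
        else:
            header = "unit\tposition\tcount"
        lines = [header]
        for key in sorted(self.table(name)):
            lines.append("\t".join((*key, str(self.table(name)[key]))))
        return "\n".join(lines) + "\n"

    def load_tsv(self, name: str, text: str) -> None:
        for i, line in enumerate(text.splitlines()):
            if i == 0 or not line.strip() or line.startswith("#"):
                continue
            *key, c = line.split("\t")
            self.table(name)[tuple(key)] = int(c)


def build_count_tables(
    corpus: Iterable[AlignedWord],
    mode: str = "instances",
    version: str = "0",
) -> CountTables:
    """Count every unit of every position-assigned word in the corpus.

    Homographs must be present as separate records (distinct
    ``pronunciation_id``); duplicate (spelling, pronunciation_id) records are
    rejected.
    """
    tables = CountTables(counting_mode=mode, version=version)
    seen: set[tuple[str, int]] = set()
    for word in corpus:
        key = (word.spelling, word.pronunciation_id)
        if key in seen:
            raise ValueError(f"duplicate corpus record {key}")
        seen.add(key)
        tables.add_word(word)
    return tables


def merge_tables(a: CountTables, b: CountTables) -> CountTables:
    """Key-wise sum of two tables built in the same mode (corpus updates)."""
    if a.counting_mode != b.counting_mode:
        raise ValueError(
            f"cannot merge counting modes {a.counting_mode!r} and "
            f"{b.counting_mode!r}"
        )
    out = CountTables(
        counting_mode=a.counting_mode,
        version=f"{a.version}+{b.version}" if a.version != b.version else a.version,
        n_words=a.n_words + b.n_words,
    )
    for name, _ in TABLE_SPECS:
        merged = Counter(a.table(name))
        merged.update(b.table(name))
        out.table(name).update(merged)
    return out
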