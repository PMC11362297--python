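"""The ten sublexical measures, segmentally and as word-level summaries.

At each grain (phonographeme, onset/rime) the toolkit offers five measures:

* reading consistency p(P|G) — of corpus entries containing the graphemic
  unit in a position, the proportion mapped to the phonemic unit;
* spelling consistency p(G|P) — the converse, with the phonemic marginal as
  denominator;
* phonographeme (joint) frequency — the shared numerator of both
  consistencies, direction-independent by construction;
* graphemic unit frequency and phonemic unit frequency (the marginals).

Log frequencies are base 10. All counts are type-weighted. A measure whose
denominator (or count) is zero is *undefined*, never zero: unattested units
are excluded from word-level summaries and reported in ``n_undefined``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import (
    OR_POSITIONS,
    PG_POSITIONS,
    AlignedWord,
    derive_onset_rime_units,
)
from .tables import CountTables

__all__ = [
    "GRAINS",
    "MEASURE_NAMES",
    "MeasureRow",
    "MeasureSet",
    "GrainError",
    "reading_consistency",
    "spelling_consistency",
    "phonographeme_frequency",
    "unit_frequency",
    "log_frequency",
    "score_word",
    "compare_pronunciations",
]

GRAINS = ("phonographeme", "onset_rime")

MEASURE_NAMES = (
    "reading_consistency",
    "spelling_consistency",
    "phonographeme_frequency",
    "grapheme_frequency",
    "phoneme_frequency",
    "phonographeme_lg_frequency",
    "grapheme_lg_frequency",
    "phoneme_lg_frequency",
)

SUMMARY_STATS = ("mean", "min", "max", "sum")


class GrainError(ValueError):
    """A position code does not match the requested unit grain."""


def _or_prefix(position: str) -> str:
    return "onset" if position.startswith("onset") else "rime"


def _joint_and_marginals(
    tables: CountTables, position: str
) -> tuple[dict, dict, dict]:
    """(joint, graphemic marginal, phonemic marginal) tables for a position."""
    if position in PG_POSITIONS:
        return tables.phonographeme, tables.grapheme, tables.phoneme
    if position in OR_POSITIONS:
        kind = _or_prefix(position)
        return (
            tables.table(kind),
            tables.table(f"{kind}_graphemic"),
            tables.table(f"{kind}_phonemic"),
        )
    raise GrainError(f"unknown position code {position!r}")


def phonographeme_frequency(
    tables: CountTables, graphemic: str, phonemic: str, position: str
) -> int:
    """Joint count of the unit pair in a position (0 when unattested).

    Identical whichever direction it is read in: the number of entries with
    the graphemic unit mapped to the phonemic unit is the number with the
    phonemic unit mapped to the graphemic one.
    """
    joint, _, _ = _joint_and_marginals(tables, position)
    return joint.get((graphemic, phonemic, position), 0)


def unit_frequency(
    tables: CountTables,
    unit: str,
    key: str,
    position: str,
    side: str | None = None,
) -> int:
    """Marginal count of a single unit in a position.

    ``unit`` is ``phoneme``/``grapheme`` (phonographeme grain) or
    ``onset``/``rime`` (with ``side`` = ``graphemic`` or ``phonemic``).
    """
    if unit in ("phoneme", "grapheme"):
        if position not in PG_POSITIONS:
            raise GrainError(f"{unit} frequency needs a phonographeme-grain position")
        return tables.table(unit).get((key, position), 0)
    if unit in ("onset", "rime"):
        if position not in OR_POSITIONS or _or_prefix(position) != unit:
            raise GrainError(f"{unit} frequency needs a matching onset/rime position")
        if side not in ("graphemic", "phonemic"):
            raise ValueError("side must be 'graphemic' or 'phonemic' for onset/rime")
        return tables.table(f"{unit}_{side}").get((key, position), 0)
    raise ValueError(f"unknown unit kind {unit!r}")


def log_frequency(
    tables: CountTables,
    unit: str,
    key: str,
    position: str,
    side: str | None = None,
) -> float | None:
    """log10 of the marginal count; undefined (None) for zero counts."""
    c = unit_frequency(tables, unit, key, position, side)
    return math.log10(c) if c > 0 else None


def reading_consistency(
    tables: CountTables,
    graphemic: str,
    phonemic: str,
    position: str,
    smoothing: float = 0.0,
) -> float | None:
    """p(P|G): joint count over the graphemic marginal; None when the
    graphemic unit is unattested in this position."""
    joint, g_marg, _ = _joint_and_marginals(tables, position)
    denom = g_marg.get((graphemic, position), 0)
    if denom == 0:
        return None
    num = joint.get((graphemic, phonemic, position), 0)
    if smoothing:
        k = sum(1 for key in joint if key[0] == graphemic and key[2] == position)
        return (num + smoothing) / (denom + smoothing * max(k, 1))
    return num / denom


def spelling_consistency(
    tables: CountTables,
    graphemic: str,
    phonemic: str,
    position: str,
    smoothing: float = 0.0,
) -> float | None:
    """p(G|P): joint count over the phonemic marginal; None when the phonemic
    unit is unattested in this position."""
    joint, _, p_marg = _joint_and_marginals(tables, position)
    denom = p_marg.get((phonemic, position), 0)
    if denom == 0:
        return None
    num = joint.get((graphemic, phonemic, position), 0)
    if smoothing:
        k = sum(1 for key in joint if key[1] == phonemic and key[2] == position)
        return (num + smoothing) / (denom + smoothing * max(k, 1))
    return num / denom


# --- word scoring -----------------------------------------------------------


@dataclass(frozen=True)
class MeasureRow:
    """Measures for one segment or onset/rime unit; None marks undefined."""

    kind: str  # "segment" | "onset" | "rime"
    graphemic: str
    phonemic: str
    position: str
    values: dict[str, float | None]


@dataclass(frozen=True)
class MeasureSet:
    """Per-unit measure rows plus word-level summaries.

    Summaries are computed over defined values only; ``n_undefined`` counts
    units excluded because the measure was not possible (unattested in the
    corpus the tables were built from).
    """

    spelling: str
    grain: str
    rows: tuple[MeasureRow, ...]
    summaries: dict[str, dict[str, float | int | None]] = field(default_factory=dict)

    def summary(self, measure: str, stat: str) -> float | None:
        return self.summaries.get(measure, {}).get(stat)

    def to_tsv(self) -> str:
        cols = ("kind", "graphemic", "phonemic", "position", *MEASURE_NAMES)
        lines = ["\t".join(cols)]

        def fmt(v: float | int | None) -> str:
            if v is None:
                return "NA"
            if isinstance(v, int) or float(v).is_integer():
                return str(int(v))
            return f"{v:.6g}"

        for row in self.rows:
            lines.append(
                "\t".join(
                    (
                        row.kind,
                        row.graphemic,
                        row.phonemic,
                        row.position,
                        *(fmt(row.values.get(m)) for m in MEASURE_NAMES),
                    )
                )
            )
        for stat in SUMMARY_STATS:
            lines.append(
                "\t".join(
                    (
                        f"summary_{stat}",
                        self.spelling,
                        "",
                        "",
                        *(fmt(self.summary(m, stat)) for m in MEASURE_NAMES),
                    )
                )
            )
        return "\n".join(lines) + "\n"


def _row_values(
    tables: CountTables, graphemic: str, phonemic: str, position: str
) -> dict[str, float | None]:
    joint = phonographeme_frequency(tables, graphemic, phonemic, position)
    if position in PG_POSITIONS:
        g_freq = unit_frequency(tables, "grapheme", graphemic, position)
        p_freq = unit_frequency(tables, "phoneme", phonemic, position)
    else:
        kind = _or_prefix(position)
        g_freq = unit_frequency(tables, kind, graphemic, position, "graphemic")
        p_freq = unit_frequency(tables, kind, phonemic, position, "phonemic")
    values: dict[str, float | None] = {
        "reading_consistency": reading_consistency(
            tables, graphemic, phonemic, position
        ),
        "spelling_consistency": spelling_consistency(
            tables, graphemic, phonemic, position
        ),
        "phonographeme_frequency": joint if joint > 0 else None,
        "grapheme_frequency": g_freq if g_freq > 0 else None,
        "phoneme_frequency": p_freq if p_freq > 0 else None,
    }
    for name in ("phonographeme", "grapheme", "phoneme"):
        c = values[f"{name}_frequency"]
        values[f"{name}_lg_frequency"] = math.log10(c) if c else None
    return values


def _summarize(rows: Sequence[MeasureRow]) -> dict[str, dict[str, float | int | None]]:
    summaries: dict[str, dict[str, float | int | None]] = {}
    for m in MEASURE_NAMES:
        defined = [row.values[m] for row in rows if row.values.get(m) is not None]
        summaries[m] = {
            "mean": sum(defined) / len(defined) if defined else None,
            "min": min(defined) if defined else None,
            "max": max(defined) if defined else None,
            "sum": sum(defined) if defined else None,
            "n_defined": len(defined),
            "n_undefined": len(rows) - len(defined),
        }
    return summaries


def score_word(
    word: AlignedWord, tables: CountTables, grain: str = "phonographeme"
) -> MeasureSet:
    """All applicable measures for one aligned word (real or pseudoword).

    No lexicon membership is required: the word's units are looked up in the
    corpus tables and unattested ones are reported as undefined. At the
    onset/rime grain, syllables without an onset contribute no onset row
    (neither zero nor undefined).
    """
    if grain not in GRAINS:
        raise GrainError(f"unknown grain {grain!r}")
    rows: list[MeasureRow] = []
    if grain == "phonographeme":
        for seg in word.segments:
            if seg.position is None:
                raise ValueError("assign positions before scoring")
            rows.append(
                MeasureRow(
                    kind="segment",
                    graphemic=seg.grapheme.notation,
                    phonemic=seg.phoneme_str,
                    position=seg.position,
                    values=_row_values(
                        tables, seg.grapheme.notation, seg.phoneme_str, seg.position
                    ),
                )
            )
    else:
        for unit in derive_onset_rime_units(word):
            rows.append(
                MeasureRow(
                    kind=unit.kind,
                    graphemic=unit.letters,
                    phonemic=unit.phoneme_str,
                    position=unit.position,
                    values=_row_values(
                        tables, unit.letters, unit.phoneme_str, unit.position
                    ),
                )
            )
    rows_t = tuple(rows)
    return MeasureSet(
        spelling=word.spelling,
        grain=grain,
        rows=rows_t,
        summaries=_summarize(rows_t),
    )


def compare_pronunciations(
    candidates: Sequence[AlignedWord],
    tables: CountTables,
    grain: str = "phonographeme",
    measure: str = "reading_consistency",
    summary: str = "mean",
) -> list[tuple[int, AlignedWord, float | None]]:
    """Rank candidate pronunciations of one spelling by a summary statistic.

    Returns (rank, word, value) triples, best first; undefined summaries rank
    last; ties share a rank (competition ranking); the sort is stable in the
    input order.
    """
    if not candidates:
        raise ValueError("no candidate pronunciations given")
    spellings = {w.spelling for w in candidates}
    if len(spellings) > 1:
        raise ValueError(f"candidates must share one spelling, got {spellings}")
    scored = [
        (w, score_word(w, tables, grain).summary(measure, summary))
        for w in candidates
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (scored[i][1] is None, -(scored[i][1] or 0.0), i),
    )
    out: list[tuple[int, AlignedWord, float | None]] = []
    for pos, i in enumerate(order):
        w, v = scored[i]
        if pos and v == out[-1][2]:
            rank = out[-1][0]
        else:
            rank = pos + 1
        out.append((rank, w, v))
    return out
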