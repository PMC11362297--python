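"""sublex — English sublexical consistency and frequency norms.

A corpus-statistics engine for sound–spelling regularities: it parses
phoneme–grapheme aligned lexicons, syllabifies pronunciations by the Maximum
Onset Principle, assigns both-ends position codes, and computes type-weighted
frequency and bidirectional consistency measures — reading consistency
p(P|G) and spelling consistency p(G|P) — at the phonographeme and the
onset/rime grain, for any real word or pseudoword mapping.
"""

from importlib import resources as _resources

from .phonology import (
    InventoryError,
    OnsetTable,
    Phoneme,
    PhonemeInventory,
    Syllable,
    UnsyllabifiableError,
    arpabet_to_ipa,
    default_inventory,
    default_onsets,
    is_legal_onset,
    mop_syllabify,
    split_onset_rime,
)
from .alignment import (
    AlignedSegment,
    AlignedWord,
    AlignmentFailure,
    Grapheme,
    GraphemeInventory,
    MappingError,
    OnsetRimeUnit,
    assign_positions,
    auto_align,
    derive_onset_rime_units,
    format_mapping_notation,
    parse_mapping_notation,
    read_corpus_tsv,
    write_corpus_tsv,
)
from .tables import CountTables, build_count_tables, merge_tables
from .measures import (
    MeasureRow,
    MeasureSet,
    compare_pronunciations,
    log_frequency,
    phonographeme_frequency,
    reading_consistency,
    score_word,
    spelling_consistency,
    unit_frequency,
)
from .fixtures import SynthSpec, generate_synthetic_corpus, oracle_counts

__version__ = "1.0.0"


def demo_corpus_text() -> str:
    """The bundled hand-aligned demonstration corpus (TSV)."""
    return _resources.files("sublex.data").joinpath("mini_corpus.tsv").read_text(
        "utf-8"
    )


__all__ = [
    "Phoneme",
    "PhonemeInventory",
    "OnsetTable",
    "Syllable",
    "InventoryError",
    "UnsyllabifiableError",
    "arpabet_to_ipa",
    "default_inventory",
    "default_onsets",
    "is_legal_onset",
    "mop_syllabify",
    "split_onset_rime",
    "Grapheme",
    "AlignedSegment",
    "AlignedWord",
    "AlignmentFailure",
    "GraphemeInventory",
    "MappingError",
    "OnsetRimeUnit",
    "assign_positions",
    "auto_align",
    "derive_onset_rime_units",
    "format_mapping_notation",
    "parse_mapping_notation",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "CountTables",
    "build_count_tables",
    "merge_tables",
    "MeasureRow",
    "MeasureSet",
    "compare_pronunciations",
    "log_frequency",
    "phonographeme_frequency",
    "reading_consistency",
    "score_word",
    "spelling_consistency",
    "unit_frequency",
    "SynthSpec",
    "generate_synthetic_corpus",
    "oracle_counts",
    "demo_corpus_text",
    "__version__",
]
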