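import pytest

import sublex as sx


@pytest.fixture(scope="session")
def demo_words():
    words, errors = sx.read_corpus_tsv(sx.demo_corpus_text())
    assert not errors
    return words


@pytest.fixture(scope="session")
def demo_tables(demo_words):
    return sx.build_count_tables(demo_words)


@pytest.fixture(scope="session")
def demo_inventory(demo_words):
    return sx.GraphemeInventory.from_corpus(demo_words)


def word_by_spelling(words, spelling, pron_id=0):
    return next(
        w for w in words if w.spelling == spelling and w.pronunciation_id == pron_id
    )
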