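import pytest

from litscreen.corpus import assign_labels
from litscreen.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A compact labelled corpus with planted signal (60 pos / 140 neg)."""
    config = SynthConfig(n_pos=60, n_neg=140, seed=11)
    records, positive_ids, journals = generate_corpus(config)
    articles = assign_labels(records, positive_ids)
    return articles, journals


@pytest.fixture(scope="session")
def default_corpus():
    """The default-condition corpus: 180 pos / 420 neg, planted text and
    journal signal."""
    records, positive_ids, journals = generate_corpus(SynthConfig(seed=7))
    articles = assign_labels(records, positive_ids)
    return articles, journals
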