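import numpy as np
import pytest

from fdmine.synthetic_corpus import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """3 well-separated planted topics, 6 months, no noise."""
    cfg = SyntheticConfig(
        n_topics=3,
        docs_per_month=30,
        months=[f"2020-{m:02d}" for m in range(1, 7)],
        topic_vocab_size=80,
        background_vocab_size=150,
        topic_word_fraction=0.9,
        seed=7,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus():
    """Corpus with every noise type planted at rate 0.05."""
    cfg = SyntheticConfig(
        n_topics=3,
        docs_per_month=40,
        months=[f"2020-{m:02d}" for m in range(1, 6)],
        topic_vocab_size=60,
        background_vocab_size=120,
        duplicate_rate=0.05,
        nonenglish_rate=0.05,
        pre2020_rate=0.05,
        abstract_only_rate=0.05,
        seed=13,
    )
    return generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
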