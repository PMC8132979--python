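import pytest

from stroketext import SimConfig, generate_corpus, load_default_rules


@pytest.fixture(scope="session")
def default_rules():
    return load_default_rules()


@pytest.fixture(scope="session")
def clean_corpus_1000():
    """Seeded 1000-report corpus with default prevalences, no hard cases."""
    return generate_corpus(SimConfig(n_reports=1000, seed=101))


@pytest.fixture()
def small_corpus():
    return generate_corpus(SimConfig(n_reports=40, seed=7))
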