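import pytest

from cnerbayes import (FragmentNaiveBayes, GeneratorParams, document_fots,
                       generate_corpus)


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-document synthetic corpus (fixed seed) shared across tests."""
    return generate_corpus(GeneratorParams(n_docs=30, seed=7))


@pytest.fixture(scope="session")
def small_results(small_corpus):
    fots = [f for doc in small_corpus for f in document_fots(doc, 1)]
    return FragmentNaiveBayes(fots).fit()


@pytest.fixture(scope="session")
def small_calibration(small_results):
    return small_results.calibrate()
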