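import pytest

from phosphomine.fixtures import FixtureConfig, generate_corpus, paper_golden_set
from phosphomine.pipeline import annotate_document


@pytest.fixture(scope="session")
def golden():
    """The four published worked-example documents and their gold."""
    docs, gold = paper_golden_set()
    return docs, gold


@pytest.fixture(scope="session")
def golden_annotated(golden):
    docs, gold = golden
    return [annotate_document(d) for d in docs], gold


@pytest.fixture(scope="session")
def small_corpus():
    """150-document synthetic corpus, fixed seed."""
    return generate_corpus(FixtureConfig(n_documents=150, seed=7))
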