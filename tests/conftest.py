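import pytest

from brainrelex import fixtures


@pytest.fixture(scope="session")
def fixture_dict():
    return fixtures.load_fixture_dictionary()


@pytest.fixture(scope="session")
def small_corpus():
    return fixtures.generate_fixture_corpus(fixtures.FixtureSpec(n_docs=10, seed=7))


@pytest.fixture(scope="session")
def corpus50():
    """The standard end-to-end recovery corpus: 50 documents, seed 1."""
    return fixtures.generate_fixture_corpus(fixtures.FixtureSpec(n_docs=50, seed=1))
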