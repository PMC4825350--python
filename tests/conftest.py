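import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """(combined lexicon, thesaurus) built from the toy MeSH fixtures."""
    from cidminer.fixtures import toy_lexicon

    return toy_lexicon()


@pytest.fixture(scope="session")
def thesaurus(toy):
    return toy[1]


@pytest.fixture(scope="session")
def lexicon(toy):
    return toy[0]


@pytest.fixture(scope="session")
def supplementary():
    from cidminer.fixtures import toy_thesaurus

    return toy_thesaurus()[1]
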