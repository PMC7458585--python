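import pytest

from infodemic import datasets


@pytest.fixture(scope="session")
def global_table():
    """Bundled global keyword APC table: (estimates, iscale results)."""
    return datasets.load_keyword_apc("global")


@pytest.fixture(scope="session")
def all_keywords():
    return datasets.load_keyword_apc("all")


@pytest.fixture(scope="session")
def hashtag_counts():
    return datasets.load_hashtag_counts()
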