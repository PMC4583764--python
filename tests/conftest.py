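import pytest

import chromoclad as cc


@pytest.fixture(scope="session")
def bundled_matrix():
    return cc.load_bundled_matrix()


@pytest.fixture(scope="session")
def bundled_search(bundled_matrix):
    """The exact search on the bundled matrix (run once per session)."""
    return cc.branch_and_bound_search(bundled_matrix)


@pytest.fixture(scope="session")
def bundled_condensed(bundled_matrix, bundled_search):
    return cc.condense_trees(bundled_search.trees, bundled_matrix)


@pytest.fixture(scope="session")
def bundled_atlas():
    return cc.load_bundled_atlas()
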