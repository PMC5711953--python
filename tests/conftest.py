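import pytest

from blindtree import fixture, polarize_all


@pytest.fixture(scope="session")
def kangaroo_matrix():
    return fixture.fixture_matrix()


@pytest.fixture(scope="session")
def kangaroo_tree():
    return fixture.fixture_tree()


@pytest.fixture(scope="session")
def kangaroo_polarized(kangaroo_matrix, kangaroo_tree):
    return polarize_all(kangaroo_matrix, kangaroo_tree)


@pytest.fixture(scope="session")
def kangaroo_nodes():
    return fixture.fixture_nodes()
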