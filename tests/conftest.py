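import pytest

from gitkit.fixtures import FixtureSpec, generate, make_taxonomy


@pytest.fixture(scope="session")
def fixture_set():
    """Medium synthetic dataset shared across test modules."""
    return generate(FixtureSpec(seed=11, n_genes=120))


@pytest.fixture(scope="session")
def tree(fixture_set):
    return fixture_set.tree


@pytest.fixture(scope="session")
def git_records(fixture_set):
    """Integrated GIT for the shared dataset at default thresholds."""
    return fixture_set.run_integration()


@pytest.fixture(scope="session")
def big_tree():
    """A 500-node taxonomy for LCA stress tests."""
    return make_taxonomy(FixtureSpec(seed=7, n_taxa=500))
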