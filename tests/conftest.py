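import pytest

from virnomina import MutationConfig, TaxonomyIndex, default_roots


@pytest.fixture(scope="session")
def default_config() -> MutationConfig:
    return MutationConfig(seed=1)


@pytest.fixture(scope="session")
def identity_config() -> MutationConfig:
    """Forge config whose substitution steps change nothing."""
    return MutationConfig(seed=1, substitution_steps=({}, {}, {}))


@pytest.fixture(scope="session")
def empty_taxonomy() -> TaxonomyIndex:
    return TaxonomyIndex.empty()


@pytest.fixture(scope="session")
def roots():
    return default_roots()
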