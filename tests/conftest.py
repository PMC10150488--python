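import numpy as np
import pytest

from mirvote import (
    FixtureConfig,
    InteractionTable,
    build_context,
    build_corpus,
    generate_fixture,
)


@pytest.fixture(scope="session")
def toy_interactions() -> InteractionTable:
    """Four-interaction corpus: A targets {g1,g2}, B targets {g2,g3}."""
    return InteractionTable.from_pairs(
        "disease", [("A", "g1"), ("A", "g2"), ("B", "g2"), ("B", "g3")]
    )


@pytest.fixture(scope="session")
def toy_corpus(toy_interactions):
    return build_corpus(toy_interactions)


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced planted-cluster fixture for fast model-level tests."""
    return generate_fixture(
        FixtureConfig(n_mirna=30, n_disease=20, n_genes=120, n_clusters=3, seed=7)
    )


@pytest.fixture(scope="session")
def small_context(small_fixture):
    fx = small_fixture
    return build_context(
        fx.associations, fx.mirna_interactions, fx.disease_interactions, fx.semantic
    )


@pytest.fixture(scope="session")
def default_fixture():
    return generate_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def default_context(default_fixture):
    fx = default_fixture
    return build_context(
        fx.associations, fx.mirna_interactions, fx.disease_interactions, fx.semantic
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
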