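import pytest

from sialevo import GammaRates, ScenarioConfig, SubstitutionModel, generate_family_scenario


@pytest.fixture(scope="session")
def wag():
    return SubstitutionModel.wag()


@pytest.fixture(scope="session")
def gamma5():
    """Discrete gamma with the divergence-stage shape (alpha = 5)."""
    return GammaRates.discrete(5.0, 5)


@pytest.fixture(scope="session")
def gamma_tree():
    """Discrete gamma with the tree-stage shape (alpha = 2.6845)."""
    return GammaRates.discrete(2.6845, 5)


@pytest.fixture(scope="session")
def scenario():
    """The default full-size synthetic family bundle (83 sequences)."""
    return generate_family_scenario(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced five-clade bundle for fast end-to-end runs."""
    cfg = ScenarioConfig(
        clade_sizes={"NEU1": 4, "NEU2": 3, "NEU3": 3, "NEU4": 3, "NEU5": 3},
        n_sites=900, seed=5,
    )
    return generate_family_scenario(cfg)
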