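import numpy as np
import pytest

from phthalmix import TruthConfig, default_registry, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """Small synthetic cohort shared by IO/prep/model unit tests."""
    truth = TruthConfig(n_children=60, beta_exposure={"SumDEHP": -0.89})
    return simulate_cohort(truth, seed=11, registry=registry)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
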