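import numpy as np
import pytest

import sadcea


@pytest.fixture(scope="session")
def params() -> sadcea.ModelParameters:
    return sadcea.ModelParameters.defaults()


@pytest.fixture(scope="session")
def interventions():
    return sadcea.load_interventions()


@pytest.fixture(scope="session")
def by_id(interventions):
    return {it.id: it for it in interventions}


@pytest.fixture(scope="session")
def recovery_means():
    return sadcea.load_recovery_summaries()["mean"].to_dict()


@pytest.fixture(scope="session")
def posterior_small():
    """A 2,000-draw synthetic posterior shared across tests."""
    baseline, specs = sadcea.default_effect_specs()
    return sadcea.sample_recovery_posterior(specs, baseline, 2_000, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_150_101)
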