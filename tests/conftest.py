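import numpy as np
import pandas as pd
import pytest

from airineq import SynthConfig, simulate_population
from airineq.pipeline import prepare_inputs


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A compact population: 4 states x 5 counties x 60 households."""
    return SynthConfig(
        n_states=4, counties_per_state=5, households_per_county=60, seed=11
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_prepared(small_population):
    hh, mort, mon = small_population
    return prepare_inputs(hh, mort, mon)


@pytest.fixture(scope="session")
def default_population():
    """The full default synthetic population (~100k households)."""
    hh, mort, mon = simulate_population(SynthConfig())
    return prepare_inputs(hh, mort, mon)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def signed_income_vector(rng) -> np.ndarray:
    """Mixed-sign income vector with positive mean, like adjusted income."""
    y = rng.lognormal(10.5, 1.0, size=400)
    y[rng.random(400) < 0.08] *= -0.3
    assert y.mean() > 0
    return y
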