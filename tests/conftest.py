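import numpy as np
import pytest
from hypothesis import settings

from fplocal.datatypes import FitConfig
from fplocal.simulate import (
    SimulationConfig,
    generate_global_parameters,
    simulate_population,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gp():
    """A deterministic synthetic global-parameter fixture."""
    return generate_global_parameters(seed=1)


@pytest.fixture(scope="session")
def sim(gp):
    """One synthetic population (truth + surveys + counts), seed 3."""
    return simulate_population(gp, SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_fit(gp, sim):
    """A short but well-mixing fit of the synthetic population."""
    from fplocal.data_io import impute_sampling_errors
    from fplocal.inference import fit_model

    obs = impute_sampling_errors(sim.observations)
    config = FitConfig(
        first_year=1990, last_year=2014, chains=2,
        warmup_iterations=400, kept_iterations=400, seed=7,
    )
    return fit_model(obs, gp, sim.config.level_key, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
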