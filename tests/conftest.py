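import datetime

import numpy as np
import pytest

from hyenademog import SimConfig, simulate_population, build_cjs_history
from hyenademog.cjs import McmcConfig

PHI_EQUAL_SEXES = {
    ("cub", "F"): 0.75, ("cub", "M"): 0.75,
    ("subadult", "F"): 0.99, ("subadult", "M"): 0.99,
    ("adult", "F"): 0.86, ("adult", "M"): 0.86,
}


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset: 4 clans over 3 years (18 occasions)."""
    cfg = SimConfig(
        seed=42, n_clans=4, initial_clan_size=12, recruitment_rate=4.0,
        study_start=datetime.date(2014, 6, 1),
        study_end=datetime.date(2017, 6, 1),
        n_core_clans=2,
    )
    individuals, sightings, state = simulate_population(cfg)
    return cfg, individuals, sightings, state


@pytest.fixture(scope="session")
def small_history(small_sim):
    _, individuals, sightings, state = small_sim
    return build_cjs_history(sightings, individuals, state.grid)


@pytest.fixture()
def quick_mcmc():
    return McmcConfig(n_chains=2, n_iter=400, n_burnin=200, seed=7)
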