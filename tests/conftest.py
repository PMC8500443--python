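"""Shared fixtures: the localized parameter set, one season of synthetic
weather, and (session-scoped, because they are expensive) a noiseless
assimilation run and the full noisy two-season pipeline."""

import datetime as dt

import numpy as np
import pytest

from cropassim.assimilation import OptimizationConfig, optimize
from cropassim.crop_model import default_parameters, run_simulation
from cropassim.pipeline import PipelineConfig, run_pipeline
from cropassim.synthetic import (
    TreatmentDesign,
    generate_weather,
    season_spec_for,
    simulate_observations,
)

TRUTH_SENSITIVE = {
    "slatb0": 0.0014,
    "slatb0.5": 0.0019,
    "slatb2": 0.00085,
    "amaxtb1": 42.0,
    "amaxtb1.3": 50.0,
}


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def design16():
    return TreatmentDesign.for_season("2015-2016")


@pytest.fixture(scope="session")
def weather16(design16):
    return generate_weather(season_spec_for("2015-2016"), seed=101)


@pytest.fixture(scope="session")
def localized_trajectory(base_params, weather16, design16):
    return run_simulation(base_params, weather16, design16.sowing_date)


@pytest.fixture(scope="session")
def truth_params(base_params):
    """A known truth differing from the localized set only in the five
    sensitive parameters (all inside the search bounds)."""
    return base_params.with_sensitive(TRUTH_SENSITIVE)


@pytest.fixture(scope="session")
def truth_trajectory(truth_params, weather16, design16):
    return run_simulation(truth_params, weather16, design16.sowing_date)


@pytest.fixture(scope="session")
def noiseless_obs(truth_trajectory, truth_params, design16):
    return simulate_observations(
        truth_trajectory,
        design16.observation_dates,
        noise_cv=0.0,
        seed=1,
        truth_params=truth_params,
        treatment_id="truth/noiseless",
        yield_noise_cv=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_assimilation(noiseless_obs, weather16, base_params, design16):
    return optimize(
        noiseless_obs,
        weather16,
        base_params,
        OptimizationConfig(seed=7, n_restarts=12),
        sowing_date=design16.sowing_date,
    )


@pytest.fixture(scope="session")
def noisy_pipeline_summary():
    """Two seasons x 12 treatments with 10% UAV observation noise."""
    config = PipelineConfig(
        seasons=("2015-2016", "2016-2017"),
        seed=42,
        noise_cv=0.10,
        n_restarts=12,
    )
    return run_pipeline(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
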