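"""Shared fixtures: default parameters, canonical forcing, and the two
scenario experiments reused across the pipeline and acceptance tests."""

import pytest

import pft_heatwave as ph
from pft_heatwave.forcing import ScenarioSpec


@pytest.fixture(scope="session")
def params():
    return ph.default_params()


@pytest.fixture(scope="session")
def forcing_1y(params):
    """One year of default (subarctic) forcing, seed 0."""
    return ph.make_seasonal_forcing(1, region_profile="subarctic", seed=0)


@pytest.fixture(scope="session")
def traj_1y(forcing_1y, params):
    """Free run over the canonical one-year forcing."""
    return ph.run(forcing_1y, params, dt=0.25)


@pytest.fixture(scope="session")
def blob_report(params):
    """Blob-style experiment: silicate supply halved for 8 months, subarctic,
    all other forcing untouched."""
    scenario = ScenarioSpec(kind="blob", duration_months=8.0,
                            supply_factor_si=0.5, ramp_months=1.0)
    return ph.run_experiment(scenario, "subarctic", params, seed=3,
                             keep_trajectories=True)


@pytest.fixture(scope="session")
def elnino_report(params):
    """El Nino-style experiment: nitrate supply cut to 20% with +4 degC for
    5 months on the equatorial profile."""
    scenario = ScenarioSpec(kind="elnino", duration_months=5.0,
                            sst_amplitude=4.0, supply_factor_no3=0.2,
                            ramp_months=1.0)
    return ph.run_experiment(scenario, "equatorial", params, seed=3,
                             keep_trajectories=True)
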