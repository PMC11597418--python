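import numpy as np
import pandas as pd
import pytest

import paddyn as pn


@pytest.fixture(scope="session")
def default_truth():
    return pn.make_site("default", seed=1)


@pytest.fixture(scope="session")
def default_obs(default_truth):
    return pn.generate_observations(default_truth)


@pytest.fixture(scope="session")
def default_simulation(default_obs):
    return default_obs["simulation"]


@pytest.fixture(scope="session")
def scenario_run(default_truth):
    """50 paired years of all four treatments plus year classes (shared by
    ordering and summary tests)."""
    weather = pn.generate_weather(
        default_truth.weather_params, 50, np.random.default_rng(2024), start_year=2001
    )
    losses = pn.run_scenarios(default_truth, weather)
    classes = pn.classify_scenario_years(weather, "06-10", "09-30")
    return {"weather": weather, "losses": losses, "classes": classes}


@pytest.fixture()
def flat_weather():
    """One rain-free season-long weather table with constant temperatures."""
    dates = pd.date_range("2001-06-01", "2001-10-15", freq="D")
    return pd.DataFrame(
        {"date": dates, "prcp": 0.0, "tmax": 30.0, "tmin": 22.0}
    )
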