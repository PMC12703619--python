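import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aqilag import SimulationTruth, simulate_series, simulate_weather_pollutants


@pytest.fixture(scope="session")
def weather_2557():
    """One default seven-year weather/pollutant/AQI frame."""
    return simulate_weather_pollutants(2557, seed=1)


@pytest.fixture(scope="session")
def null_series():
    """Series with no injected effects and flat baseline."""
    truth = SimulationTruth(
        seasonal_amplitude=0.0, dow_effects=(0.0,) * 7, aqi_slope=0.0
    )
    series, _ = simulate_series(2557, seed=1, truth=truth)
    return series


@pytest.fixture(scope="session")
def default_series():
    series, truth = simulate_series(2557, seed=1)
    return series, truth


@pytest.fixture
def tiny_csv(tmp_path):
    """Three-day CSV with counts and one pollutant column."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "date": ["2015-01-01", "2015-01-02", "2015-01-03"],
            "deaths_total": [2, 3, 4],
            "pm25": [10.0, 12.0, 14.0],
        }
    ).to_csv(path, index=False)
    return path


def rng(seed):
    return np.random.default_rng(seed)
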