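import numpy as np
import pandas as pd
import pytest

from aggsdm import ClimateForcing, GridSpec, generate_environment, generate_survey


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(-122.5, -121.5, 36.5, 37.5, 0.1)  # 10×10


@pytest.fixture(scope="session")
def forcing2():
    return ClimateForcing({2001: 0.0, 2002: 2.0})


@pytest.fixture(scope="session")
def small_env(small_grid, forcing2):
    return generate_environment(small_grid, [2001, 2002], 30, forcing2, seed=42)


@pytest.fixture(scope="session")
def small_effort(small_grid):
    return generate_survey(small_grid, [2001, 2002], 200, seed=7, days_per_year=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sightings_frame():
    """Hand-built 3-km-bin sightings table with all behavior codes."""
    return pd.DataFrame(
        {
            "date": pd.to_datetime(["2001-04-05"] * 3),
            "lon": [-122.11, -122.11, -121.77],
            "lat": [36.84, 36.84, 37.21],
            "species": ["murre"] * 3,
            "count": [12, 5, 7],
            "behavior": ["flying", "water", "feeding"],
            "bin_id": [0, 1, 2],
        }
    )
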