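import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

# make the oracle modules importable as plain modules
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenario():
    """Three synthetic days on a tiny grid; cheap enough for many tests."""
    from urbanheat import ClimateScenario
    return ClimateScenario(
        grid_extent=(24.0, 25.0, 71.0, 72.0),
        date_range=pd.date_range("2013-06-01", periods=72, freq="h"),
        base_temperature=26.0, diurnal_amplitude=5.0,
        dewpoint_depression_mean=8.0, wind_mean=2.0,
        clear_sky_peak_flux=850.0, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def small_fields(small_scenario):
    from urbanheat import generate_fields
    return generate_fields(small_scenario)
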