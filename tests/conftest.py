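import numpy as np
import pandas as pd
import pytest

from fuzzyair.model import build_hospitalization_fis
from fuzzyair.simulate import GeneratorConfig, generate_series


@pytest.fixture(scope="session")
def fis():
    """The default 16-rule hospitalization model."""
    return build_hospitalization_fis()


@pytest.fixture(scope="session")
def plateau_settings():
    """Crisp temperature/wind points: one per high/low × strong/weak corner."""
    return [(40.0, 4.0), (40.0, 1.2), (15.0, 4.0), (15.0, 1.2)]


@pytest.fixture()
def small_series():
    """A short complete daily series with integer counts."""
    rng = np.random.default_rng(7)
    n = 60
    return pd.DataFrame({
        "date": pd.date_range("2012-01-01", periods=n, freq="D"),
        "pm10": rng.uniform(6, 120, n),
        "no2": rng.uniform(7, 110, n),
        "temperature": rng.uniform(12, 39, n),
        "wind": rng.uniform(1.1, 4.1, n),
        "hospitalizations": rng.poisson(1.6, n),
    })


@pytest.fixture(scope="session")
def default_series():
    """One full synthetic series under the default generator calibration."""
    return generate_series(GeneratorConfig(seed=42))
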