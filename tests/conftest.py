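import numpy as np
import pandas as pd
import pytest

import heatmort as hm


@pytest.fixture(scope="session")
def default_sim():
    """One default multi-cause 18-year simulation, shared across tests."""
    config = hm.SyntheticConfig(seed=2024)
    weather, deaths = hm.simulate(config)
    return config, weather, deaths


@pytest.fixture(scope="session")
def fast_sim():
    """A small 3-year single-cause simulation for cheap fitting tests."""
    config = hm.SyntheticConfig(
        n_years=3, seed=77, cause_baselines={"All cause": 98.67}, cause_parents={}
    )
    weather, deaths = hm.simulate(config)
    return config, weather, deaths


def make_exposure(tmax, start="2000-01-01", humidity=70.0, pressure=1009.0):
    """Build a minimal valid ExposureSeries from a tmax array."""
    tmax = np.asarray(tmax, dtype=float)
    n = len(tmax)
    return hm.ExposureSeries(
        pd.DataFrame(
            {
                "date": pd.date_range(start, periods=n, freq="D"),
                "tmax": tmax,
                "tmean": tmax - 4.0,
                "tmin": tmax - 7.7,
                "humidity": np.full(n, humidity),
                "pressure": np.full(n, pressure),
                "pm10": np.full(n, np.nan),
                "o3": np.full(n, np.nan),
            }
        )
    )


def make_mortality(dates, **cause_counts):
    frame = pd.DataFrame({"date": pd.DatetimeIndex(dates)})
    for label, counts in cause_counts.items():
        frame[label] = np.asarray(counts, dtype=int)
    return hm.MortalitySeries(frame)
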