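import numpy as np
import pandas as pd
import pytest

from smokeatlas import DailyField, GridSpec, make_world, tiny_config


@pytest.fixture(scope="session")
def tiny_world():
    """8x8-cell, 30-day synthetic world shared across tests."""
    return make_world(tiny_config(seed=1))


@pytest.fixture(scope="session")
def tiny_world_2yr():
    """Small world spanning two calendar years (for year fixed effects)."""
    return make_world(tiny_config(seed=2, start="2011-12-01", n_days=62))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return GridSpec(lat0=10.0, lon0=20.0, dlat=0.5, dlon=0.5, nlat=6, nlon=8)


def make_field(grid, n_days=5, rng=None, start="2015-01-01", name="pm25"):
    rng = rng or np.random.default_rng(0)
    dates = pd.date_range(start, periods=n_days, freq="D")
    vals = rng.uniform(1.0, 30.0, size=(n_days, grid.nlat, grid.nlon))
    return DailyField(grid, dates, vals, name=name)
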