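import numpy as np
import pandas as pd
import pytest

from pm_gridsense.grid import GridSpec, RasterField
from pm_gridsense.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact city (30×24 cells, 72 h, 12 stations) shared across tests."""
    cfg = ScenarioConfig(lon_max=114.3, lat_max=30.54, n_hours=72,
                         n_stations=12, n_traffic_lines=30, n_roads=60,
                         n_pois=150, n_checkin_anchors=150, seed=7)
    return generate_scenario(cfg)


@pytest.fixture
def tiny_grid():
    return GridSpec(lon_min=114.0, lat_min=30.0, n_cols=10, n_rows=8,
                    cell_size=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_field(grid, values, **kw):
    return RasterField(grid, np.asarray(values, float), **kw)


@pytest.fixture
def station_frame():
    return pd.DataFrame({
        "station_id": ["A", "B", "C"],
        "lon": [114.015, 114.065, 114.045],
        "lat": [30.025, 30.045, 30.065],
    })
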