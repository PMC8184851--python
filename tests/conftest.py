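import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from fragno2.synthetic import ScenarioConfig, StationPanel

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("fragno2").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A compact scenario: short history, small rasters, few stations."""
    return ScenarioConfig(
        n_stations=6,
        history_start="2018-01-01",
        raster_rows=32,
        raster_cols=32,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_constant_panel(value: float = 50.0, start="2018-01-01", end="2020-05-01",
                        station_id: str = "S001") -> StationPanel:
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    return StationPanel(
        station_id=station_id,
        dates=dates,
        no2_observed=np.full(n, value),
        temperature=np.full(n, 15.0),
        humidity=np.full(n, 65.0),
        wind_speed=np.full(n, 2.5),
    )
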