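import numpy as np
import pandas as pd
import pytest
import xarray as xr

import edhwheat as e


def make_climate(tmax, dates, lat=(40.0,), lon=(-100.0,), tmin=None, precip=None):
    """Wrap plain arrays into the daily-climate dataset layout."""
    tmax = np.asarray(tmax, dtype=float)
    if tmax.ndim == 1:
        tmax = tmax[None, None, :]
    tmin = tmax - 10.0 if tmin is None else np.broadcast_to(tmin, tmax.shape)
    precip = np.zeros_like(tmax) if precip is None else np.broadcast_to(precip, tmax.shape)
    return xr.Dataset(
        {
            "tmax": (("lat", "lon", "time"), tmax),
            "tmin": (("lat", "lon", "time"), tmin),
            "precip": (("lat", "lon", "time"), precip),
        },
        coords={"lat": list(lat), "lon": list(lon), "time": pd.DatetimeIndex(dates)},
    )


@pytest.fixture(scope="session")
def year_2001_dates():
    return pd.date_range("2001-01-01", "2001-12-31", freq="D")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured study configuration (8x8 grid, 59 years)."""
    cfg = e.SyntheticConfig(n_lat=8, n_lon=8)
    cfg.tillage_effect_regions = {
        "NT": e.TillageRegion(5, 8, 0, 8, beta_scale=0.3),
        "CT": e.TillageRegion(0, 3, 0, 8, beta_scale=0.3),
    }
    return cfg


@pytest.fixture(scope="session")
def small_suite(small_config):
    """Climate, EDH field and the S1/S2/S12/S13 scenarios on the small grid."""
    climate, edh, suite = e.generate_scenario_suite(
        small_config, scenarios=("S1", "S2", "S12", "S13")
    )
    return climate, edh, suite
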