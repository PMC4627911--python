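import numpy as np
import pandas as pd
import pytest

from topotreeline.landform import DEMGrid
from topotreeline.topoclimate import HourlyMetSeries


@pytest.fixture
def flat_dem():
    return DEMGrid(values=np.full((5, 5), 1000.0), cell_size=25.0)


def make_plane(n_rows=6, n_cols=7, a=0.0, b=0.0, c=500.0, cell_size=25.0):
    """DEM with z = a*easting + b*northing + c evaluated at cell centres."""
    dem = DEMGrid(values=np.zeros((n_rows, n_cols)), cell_size=cell_size)
    z = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        for col in range(n_cols):
            e, n = dem.cell_center(r, col)
            z[r, col] = a * e + b * n + c
    return dem.like(z)


def random_series(seed, n_days=3, site="s", point="p", month="jan"):
    """An arbitrary (not physically structured) valid hourly series."""
    rng = np.random.default_rng(seed)
    n = 24 * n_days
    solar = np.where(rng.random(n) < 0.5, rng.uniform(0, 900, n), 0.0)
    return HourlyMetSeries(
        site_id=site,
        point_id=point,
        month_label=month,
        temp_c=rng.uniform(-10, 25, n),
        wind_ms=rng.uniform(0, 20, n),
        rh_pct=rng.uniform(5, 100, n),
        solar_wm2=solar,
        netrad_wm2=np.where(solar > 0, solar - 80.0, rng.uniform(-120, -10, n)),
        rain_mm=rng.uniform(0, 12, n_days),
    )


@pytest.fixture
def points_df():
    return pd.DataFrame(
        {
            "point_id": ["p0", "p1", "p2"],
            "site_id": ["s0", "s0", "s0"],
            "easting": [62.5, 37.5, 87.5],
            "northing": [62.5, 37.5, 87.5],
        }
    )
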