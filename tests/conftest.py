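import datetime as dt

import numpy as np
import pytest

import stresszones as sz
from stresszones.climatology import ClimatologyStack, get_variable
from stresszones.grids import GridSpec


@pytest.fixture(scope="session")
def small_tmin_stack():
    """One synthetic year of tmin on a 20x30 grid: the default fixture."""
    cfg = sz.SyntheticClimateConfig(
        variable="tmin",
        grid_shape=(20, 30),
        date_range=(dt.date(2019, 1, 1), dt.date(2019, 12, 31)),
        base_value=-5.0,
        gradient_amplitude=20.0,
        seasonal_amplitude=10.0,
        noise_sd=1.5,
        seed=11,
    )
    return sz.generate_daily_climate(cfg)


@pytest.fixture(scope="session")
def tmin_counts(small_tmin_stack):
    return sz.sweep_thresholds(small_tmin_stack)


@pytest.fixture(scope="session")
def tmin_zones(tmin_counts):
    index = sz.pca_first_component(tmin_counts)
    index = sz.orient_stress(index, tmin_counts)
    return sz.classify_quantiles(index, k=5)


def make_stack(values, variable="tmin", mask=None, start=dt.date(2020, 3, 1)):
    """Wrap a (days, rows, cols) array as a ClimatologyStack on a unit grid."""
    values = np.asarray(values, dtype=np.float32)
    n, rows, cols = values.shape
    grid = GridSpec.from_extent((0.0, 0.0, float(cols), float(rows)), (rows, cols))
    dates = [start + dt.timedelta(days=i) for i in range(n)]
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    return ClimatologyStack(
        variable=get_variable(variable), grid=grid, dates=dates, values=values, mask=mask
    )
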