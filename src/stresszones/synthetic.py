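"""Seeded synthetic inputs: daily climate stacks and occurrence points.

The generator emulates the statistical structure the pipeline assumes of
real daily climate grids — a smooth spatial gradient, a seasonal cycle
and pixel-level noise — without attempting physical realism.  Each daily
layer is

    value = base_value
          + gradient_amplitude * position_along_axis        (0..1)
          + seasonal_amplitude * cos(2*pi*(doy - peak)/365)
          + iid Gaussian(0, noise_sd) per pixel-day

with the seasonal peak at mid-year (day 183) for every variable, which
puts the minimum-temperature trough in mid-winter.  Occurrence sets are
drawn on an existing stress-zone raster: each valid pixel is selected
with probability proportional to its zone's weight, and one point is
placed uniformly inside each selected pixel, so zone-concentration
strength is set directly by the weight ratios.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .climatology import ClimatologyStack, get_variable
from .errors import ConfigurationError, InfeasibleConfigurationError
from .grids import GridSpec

__all__ = [
    "SyntheticClimateConfig",
    "OccurrenceSimConfig",
    "VARIABLE_DEFAULTS",
    "default_climate_config",
    "generate_daily_climate",
    "generate_occurrences",
]

SEASONAL_PEAK_DOY = 183  # mid-year (early July)

#: Per-variable generator defaults chosen so values span each variable's
#: plausible range (and hence its default threshold sweep is non-trivial):
#: tmin ~ -22..22 degC, tmax ~ 15..50 degC, vpdmin ~ 0..10 hPa,
#: vpdmax ~ 10..30 hPa across the grid and the seasonal cycle.
VARIABLE_DEFAULTS: dict[str, dict] = {
    "tmin": dict(base_value=-10.0, gradient_amplitude=20.0, seasonal_amplitude=12.0, noise_sd=1.5),
    "tmax": dict(base_value=25.0, gradient_amplitude=15.0, seasonal_amplitude=10.0, noise_sd=1.5),
    "vpdmin": dict(base_value=2.0, gradient_amplitude=6.0, seasonal_amplitude=2.0, noise_sd=0.8),
    "vpdmax": dict(base_value=15.0, gradient_amplitude=10.0, seasonal_amplitude=5.0, noise_sd=1.5),
}


def default_climate_config(variable: str, **overrides) -> "SyntheticClimateConfig":
    """A SyntheticClimateConfig with realistic per-variable defaults."""
    params = dict(VARIABLE_DEFAULTS[str(variable)])
    params.update(overrides)
    return SyntheticClimateConfig(variable=str(variable), **params)


@dataclass(frozen=True)
class SyntheticClimateConfig:
    """Configuration of one synthetic daily climate stack.

    Amplitudes and ``noise_sd`` are in the variable's units (°C or hPa).
    ``gradient_axis`` is "ns" (north-south, the default) or "ew".
    ``smoothing_radius`` optionally blurs the noise field (pixels); the
    default 0 keeps noise iid.
    """

    variable: str = "tmin"
    grid_shape: tuple[int, int] = (40, 60)
    extent: tuple[float, float, float, float] = (-100.0, 30.0, -90.0, 40.0)
    date_range: tuple[dt.date, dt.date] = (dt.date(2016, 1, 1), dt.date(2020, 12, 31))
    base_value: float = 0.0
    gradient_amplitude: float = 20.0
    seasonal_amplitude: float = 10.0
    noise_sd: float = 1.0
    gradient_axis: str = "ns"
    smoothing_radius: float = 0.0
    drop_leap_days: bool = True
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ConfigurationError("grid_shape components must be >= 2")
        x0, y0, x1, y1 = self.extent
        if not (x0 < x1 and y0 < y1):
            raise ConfigurationError("extent must satisfy lon_min < lon_max and lat_min < lat_max")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        start, end = self.date_range
        if end < start:
            raise ConfigurationError("date_range must span at least one day")
        if self.gradient_axis not in ("ns", "ew"):
            raise ConfigurationError("gradient_axis must be 'ns' or 'ew'")
        get_variable(self.variable)


def _calendar(start: dt.date, end: dt.date, drop_leap_days: bool) -> list[dt.date]:
    days = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    if drop_leap_days:
        days = [d for d in days if not (d.month == 2 and d.day == 29)]
    return days


def generate_daily_climate(config: SyntheticClimateConfig) -> ClimatologyStack:
    """Generate a seeded synthetic daily stack; bit-for-bit reproducible."""
    config.validate()
    variable = get_variable(config.variable)
    rows, cols = config.grid_shape
    x0, y0, x1, y1 = config.extent
    grid = GridSpec.from_extent((x0, y0, x1, y1), (rows, cols))

    dates = _calendar(*config.date_range, config.drop_leap_days)
    n = len(dates)

    if config.gradient_axis == "ns":
        pos = np.repeat(np.arange(rows) / (rows - 1), cols).reshape(rows, cols)
    else:
        pos = np.tile(np.arange(cols) / (cols - 1), (rows, 1))
    spatial = config.base_value + config.gradient_amplitude * pos

    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - SEASONAL_PEAK_DOY) / 365.0)

    values = spatial[None, :, :] + seasonal[:, None, None]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        noise = rng.normal(0.0, config.noise_sd, size=(n, rows, cols))
        if config.smoothing_radius > 0:
            noise = ndimage.gaussian_filter(noise, sigma=(0, config.smoothing_radius, config.smoothing_radius))
        values = values + noise

    return ClimatologyStack(
        variable=variable,
        grid=grid,
        dates=dates,
        values=values.astype(np.float32),
        mask=np.ones((rows, cols), dtype=bool),
    )


@dataclass(frozen=True)
class OccurrenceSimConfig:
    """Zone-concentrated occurrence simulation.

    ``zone_weights`` maps stress-class labels 1..5 to nonnegative
    sampling weights; a pixel is drawn with probability proportional to
    the weight of its zone, so weights {1: 5, 2: 1, ...} concentrate
    points fivefold (per pixel) in zone 1.
    """

    n_points: int = 100
    zone_weights: dict = field(default_factory=lambda: {z: 1.0 for z in range(1, 6)})
    species: str = "Synthetica exemplaris"
    seed: int = 0

    def validate(self) -> None:
        if self.n_points < 0:
            raise ConfigurationError("n_points must be nonnegative")
        weights = {int(k): float(v) for k, v in self.zone_weights.items()}
        if not weights or not all(np.isfinite(list(weights.values()))):
            raise ConfigurationError("zone_weights must be finite")
        if any(v < 0 for v in weights.values()):
            raise ConfigurationError("zone_weights must be nonnegative")
        if not any(v > 0 for v in weights.values()):
            raise ConfigurationError("at least one zone weight must be positive")


def generate_occurrences(zones, config: OccurrenceSimConfig) -> pd.DataFrame:
    """Draw occurrence points concentrated in chosen stress zones.

    Returns an occurrence table (columns ``species``, ``longitude``,
    ``latitude``, ``status='raw'``) with one point placed uniformly at
    random inside each sampled pixel; WGS84 lon/lat.
    """
    config.validate()
    weights = {int(k): float(v) for k, v in config.zone_weights.items()}
    grid = zones.grid
    classes = zones.classes

    pixel_w = np.zeros(grid.shape, dtype=float)
    for z, w in weights.items():
        in_zone = zones.mask & (classes == z)
        if w > 0 and not in_zone.any():
            raise InfeasibleConfigurationError(
                f"zone {z} has positive weight but no valid pixels"
            )
        pixel_w[in_zone] = w

    empty = pd.DataFrame(
        {"species": pd.Series(dtype=str),
         "longitude": pd.Series(dtype=float),
         "latitude": pd.Series(dtype=float),
         "status": pd.Series(dtype=str)}
    )
    if config.n_points == 0:
        return empty

    flat = pixel_w.ravel()
    total = flat.sum()
    if total <= 0:
        raise InfeasibleConfigurationError("no pixel has positive sampling weight")
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(flat.size, size=config.n_points, p=flat / total)
    row, col = np.unravel_index(idx, grid.shape)
    u = rng.random(config.n_points)
    v = rng.random(config.n_points)
    lon = grid.x_min + (col + u) * grid.dx
    lat = grid.y_max - (row + v) * grid.dy
    return pd.DataFrame(
        {
            "species": config.species,
            "longitude": lon,
            "latitude": lat,
            "status": "raw",
        }
    )
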