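"""Daily climate stacks and threshold-sweep suitable-day counts.

The core primitive is an asymmetric daily suitability rule per climate
variable: minimum temperature and minimum vapor pressure deficit (VPD)
are *suitable at or above* a threshold, while maximum temperature and
maximum VPD are *suitable at or below* it.  For tmin with a 5 °C
threshold, a pixel below 5 °C scores 0 and a pixel at or above 5 °C
scores 1; for tmax with a 12 °C threshold, a pixel at or below 12 °C
scores 1 and above it 0.  Summing those daily binary layers over a
multi-year climatology gives, per pixel, the number of suitable days at
each threshold; sweeping the threshold across its full plausible range
yields a stack of count rasters that the zonation stage reduces by PCA.

The default five-year window (2016-2020) with leap days dropped gives
exactly 5 x 365 = 1825 days, so counts are bounded by 1825.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FormatError
from .grids import GridSpec, Raster, read_ascii_grid, write_ascii_grid

__all__ = [
    "ClimateVariable",
    "VARIABLES",
    "ClimatologyStack",
    "CountRaster",
    "CountStack",
    "read_daily_stack",
    "suitability_layer",
    "count_suitable_days",
    "sweep_thresholds",
    "write_count_stack",
    "read_count_stack",
]

SUITABLE_ABOVE = "suitable-above"
SUITABLE_BELOW = "suitable-below"

COUNT_NODATA = -1  # sentinel outside [0, n_days]


@dataclass(frozen=True)
class ClimateVariable:
    """One of the four climate dimensions and its thresholding polarity."""

    name: str
    units: str
    polarity: str  # SUITABLE_ABOVE or SUITABLE_BELOW
    default_sweep: tuple[float, float, float]  # (lo, hi, step)

    @property
    def suitable_above(self) -> bool:
        return self.polarity == SUITABLE_ABOVE


#: Registry of the four climate dimensions with their default threshold
#: sweeps (1-unit step over the full plausible range of each variable).
VARIABLES: dict[str, ClimateVariable] = {
    "tmin": ClimateVariable("tmin", "degC", SUITABLE_ABOVE, (-15.0, 15.0, 1.0)),
    "tmax": ClimateVariable("tmax", "degC", SUITABLE_BELOW, (25.0, 50.0, 1.0)),
    "vpdmin": ClimateVariable("vpdmin", "hPa", SUITABLE_ABOVE, (0.0, 10.0, 1.0)),
    "vpdmax": ClimateVariable("vpdmax", "hPa", SUITABLE_BELOW, (12.0, 30.0, 1.0)),
}


def get_variable(variable) -> ClimateVariable:
    if isinstance(variable, ClimateVariable):
        return variable
    try:
        return VARIABLES[str(variable)]
    except KeyError:
        raise ConfigurationError(
            f"unknown climate variable {variable!r}; expected one of {sorted(VARIABLES)}"
        ) from None


@dataclass
class ClimatologyStack:
    """Daily values of one climate variable on a fixed grid.

    ``values`` has shape (n_days, rows, cols); all layers share the grid,
    CRS and nodata mask, and ``dates`` is strictly increasing.
    """

    variable: ClimateVariable
    grid: GridSpec
    dates: list[dt.date]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise FormatError("stack values must have shape (n_days, rows, cols)")
        if len(self.dates) != self.values.shape[0]:
            raise FormatError("number of dates must match number of layers")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise FormatError("dates must be strictly increasing with no duplicates")

    @property
    def n_days(self) -> int:
        return len(self.dates)


@dataclass
class CountRaster:
    """Per-pixel count of suitable days at one threshold."""

    variable: ClimateVariable
    threshold: float
    grid: GridSpec
    counts: np.ndarray  # int16, COUNT_NODATA where invalid
    mask: np.ndarray
    n_days: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int16)
        self.mask = np.asarray(self.mask, dtype=bool)
        valid = self.counts[self.mask]
        if valid.size and (valid.min() < 0 or valid.max() > self.n_days):
            raise FormatError("counts out of [0, n_days] at valid pixels")

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.counts, mask=self.mask)


@dataclass
class CountStack:
    """One CountRaster per threshold of a sweep; thresholds strictly increasing."""

    variable: ClimateVariable
    thresholds: list[float]
    rasters: list[CountRaster]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.rasters):
            raise FormatError("thresholds and rasters must align")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise FormatError("thresholds must be strictly increasing")
        if self.rasters:
            g0, m0, n0 = self.rasters[0].grid, self.rasters[0].mask, self.rasters[0].n_days
            for r in self.rasters[1:]:
                if not r.grid.same_grid(g0) or r.n_days != n0 or not np.array_equal(r.mask, m0):
                    raise FormatError("all count rasters must share grid, mask and n_days")

    @property
    def grid(self) -> GridSpec:
        return self.rasters[0].grid

    @property
    def mask(self) -> np.ndarray:
        return self.rasters[0].mask

    @property
    def n_days(self) -> int:
        return self.rasters[0].n_days

    def to_array(self) -> np.ndarray:
        """(n_thresholds, rows, cols) int array of counts."""
        return np.stack([r.counts for r in self.rasters])


# ---------------------------------------------------------------------------
# reading

_DATE_PATTERNS = [
    re.compile(r"(\d{4})-(\d{2})-(\d{2})"),
    re.compile(r"(\d{4})(\d{2})(\d{2})"),
]


def _parse_date(text: str) -> dt.date:
    for pat in _DATE_PATTERNS:
        m = pat.search(text)
        if m:
            try:
                return dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
            except ValueError:
                continue
    raise FormatError(f"cannot parse an ISO date from {text!r}")


def read_daily_stack(
    source,
    variable,
    drop_leap_days: bool = True,
) -> ClimatologyStack:
    """Read a directory (or explicit list) of single-day ASCII grids.

    Dates are parsed from filenames (``YYYY-MM-DD`` or ``YYYYMMDD``).
    Leap days (29 Feb) are dropped by default so that 2016-2020 yields
    exactly 1825 layers; pass ``drop_leap_days=False`` to keep them.
    """
    variable = get_variable(variable)
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.asc"))
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise FormatError("no input rasters found")

    dated = sorted((_parse_date(p.name), p) for p in paths)
    if drop_leap_days:
        dated = [(d, p) for d, p in dated if not (d.month == 2 and d.day == 29)]
    if not dated:
        raise FormatError("no layers remain after calendar filtering")

    first = read_ascii_grid(dated[0][1])
    layers = np.empty((len(dated), *first.grid.shape), dtype=np.float32)
    layers[0] = first.values
    mask = first.mask.copy()
    for i, (_, path) in enumerate(dated[1:], start=1):
        r = read_ascii_grid(path)
        if not r.grid.same_grid(first.grid):
            raise FormatError(f"{path}: grid does not match {dated[0][1]}")
        layers[i] = r.values
        mask &= r.mask
    return ClimatologyStack(
        variable=variable,
        grid=first.grid,
        dates=[d for d, _ in dated],
        values=layers,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# thresholding

def suitability_layer(stack: ClimatologyStack, day_index: int, threshold: float) -> Raster:
    """Binary suitable (1) / non-suitable (0) layer for one day.

    Suitable-above variables (tmin, vpdmin): value >= threshold -> 1.
    Suitable-below variables (tmax, vpdmax): value <= threshold -> 1.
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    if not -stack.n_days <= day_index < stack.n_days:
        raise ConfigurationError(f"day_index {day_index} out of range")
    day = stack.values[day_index]
    if stack.variable.suitable_above:
        binary = (day >= threshold).astype(np.int8)
    else:
        binary = (day <= threshold).astype(np.int8)
    return Raster(grid=stack.grid, values=binary, mask=stack.mask)


def count_suitable_days(stack: ClimatologyStack, threshold: float) -> CountRaster:
    """Per-pixel number of days meeting the suitability threshold."""
    if stack.n_days == 0:
        raise ConfigurationError("cannot count over an empty stack")
    if stack.variable.suitable_above:
        counts = (stack.values >= threshold).sum(axis=0)
    else:
        counts = (stack.values <= threshold).sum(axis=0)
    counts = counts.astype(np.int16)
    counts[~stack.mask] = COUNT_NODATA
    return CountRaster(
        variable=stack.variable,
        threshold=float(threshold),
        grid=stack.grid,
        counts=counts,
        mask=stack.mask,
        n_days=stack.n_days,
    )


def sweep_values(sweep: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = sweep
    if step <= 0:
        raise ConfigurationError("sweep step must be positive")
    if lo > hi:
        raise ConfigurationError("sweep must have lo <= hi")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def sweep_thresholds(stack: ClimatologyStack, sweep=None) -> CountStack:
    """Count suitable days at every threshold lo, lo+step, ..., <= hi.

    ``sweep`` defaults to the variable's full plausible range with a
    1-unit step (e.g. -15..15 °C for tmin -> 31 thresholds).
    """
    if sweep is None:
        sweep = stack.variable.default_sweep
    thresholds = sweep_values(sweep)
    if thresholds.size == 0:
        raise ConfigurationError("empty threshold sweep")
    rasters = [count_suitable_days(stack, float(t)) for t in thresholds]
    return CountStack(
        variable=stack.variable,
        thresholds=[float(t) for t in thresholds],
        rasters=rasters,
    )


# ---------------------------------------------------------------------------
# count-stack I/O (directory of ASCII grids, threshold in the filename)

def write_count_stack(stack: CountStack, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = directory / "countstack.txt"
    with open(meta, "w") as fh:
        fh.write(f"variable {stack.variable.name}\n")
        fh.write(f"n_days {stack.n_days}\n")
    for t, r in zip(stack.thresholds, stack.rasters):
        path = directory / f"{stack.variable.name}_t{t:+08.2f}.asc"
        write_ascii_grid(path, r.as_raster(), nodata=COUNT_NODATA, fmt="%d")
        paths.append(path)
    return paths


def read_count_stack(directory) -> CountStack:
    directory = Path(directory)
    meta = directory / "countstack.txt"
    if not meta.exists():
        raise FormatError(f"{directory}: missing countstack.txt metadata")
    fields = dict(line.split() for line in meta.read_text().splitlines() if line.strip())
    variable = get_variable(fields["variable"])
    n_days = int(fields["n_days"])
    entries = []
    for path in sorted(directory.glob(f"{variable.name}_t*.asc")):
        m = re.search(r"_t([+-][0-9.]+)\.asc$", path.name)
        if not m:
            raise FormatError(f"{path}: cannot parse threshold from filename")
        entries.append((float(m.group(1)), path))
    entries.sort()
    rasters = []
    for t, path in entries:
        r = read_ascii_grid(path)
        rasters.append(
            CountRaster(
                variable=variable,
                threshold=t,
                grid=r.grid,
                counts=r.values.astype(np.int16),
                mask=r.mask,
                n_days=n_days,
            )
        )
    return CountStack(variable=variable, thresholds=[t for t, _ in entries], rasters=rasters)
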