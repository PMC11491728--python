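"""Lightweight north-up raster grids with plain-text (ESRI ASCII) I/O.

Everything downstream — daily climate stacks, suitable-day counts, stress
indices and zone rasters — lives on a :class:`GridSpec`: a regular,
north-up grid in geographic coordinates (WGS84 lon/lat by default).
Pixels follow the half-open convention: a point exactly on a shared edge
belongs to the pixel to the right / below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeoreferenceError

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Georeference of a regular north-up grid.

    Parameters
    ----------
    rows, cols
        Grid shape.
    x_min, y_max
        Coordinates of the outer corner of the top-left pixel.
    dx, dy
        Pixel width and height in CRS units (both positive; rows run
        north to south).
    crs
        Coordinate reference system identifier; informational only.
    """

    rows: int
    cols: int
    x_min: float
    y_max: float
    dx: float
    dy: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.cols * self.dx

    @property
    def y_min(self) -> float:
        return self.y_max - self.rows * self.dy

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @classmethod
    def from_extent(
        cls,
        extent: tuple[float, float, float, float],
        shape: tuple[int, int],
        crs: str = "EPSG:4326",
    ) -> "GridSpec":
        """Build a grid covering ``extent`` = (x_min, y_min, x_max, y_max)."""
        x_min, y_min, x_max, y_max = extent
        if not (x_min < x_max and y_min < y_max):
            raise ValueError("extent must satisfy x_min < x_max and y_min < y_max")
        rows, cols = shape
        return cls(
            rows=rows,
            cols=cols,
            x_min=float(x_min),
            y_max=float(y_max),
            dx=(x_max - x_min) / cols,
            dy=(y_max - y_min) / rows,
            crs=crs,
        )

    def rowcol(self, x, y):
        """Map coordinates to (row, col); half-open pixel convention.

        Points outside the grid get row/col outside [0, rows) / [0, cols).
        Accepts scalars or arrays.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x_min) / self.dx).astype(int)
        row = np.floor((self.y_max - np.asarray(y, dtype=float)) / self.dy).astype(int)
        # the top / left outer edges belong to the first row / column
        row = np.where(np.asarray(y, dtype=float) == self.y_max, 0, row)
        col = np.where(np.asarray(x, dtype=float) == self.x_min, 0, col)
        return row, col

    def contains(self, x, y):
        """Boolean: do points fall inside the grid footprint?"""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y > self.y_min) & (y <= self.y_max)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (rows, cols) at pixel centers."""
        xs = self.x_min + (np.arange(self.cols) + 0.5) * self.dx
        ys = self.y_max - (np.arange(self.rows) + 0.5) * self.dy
        lon, lat = np.meshgrid(xs, ys)
        return lon, lat

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_max - other.y_max) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class Raster:
    """A single 2-D layer on a :class:`GridSpec` with a validity mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GeoreferenceError(
                f"raster values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise GeoreferenceError("mask shape does not match grid shape")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "dx", "dy", "nodata_value"}


def write_ascii_grid(path, raster: Raster, nodata: float = -9999.0, fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid.

    Non-square pixels use the GDAL AAIGrid ``dx``/``dy`` header extension
    in place of ``cellsize``.
    """
    g = raster.grid
    out = np.array(raster.values, dtype=float)
    out[~raster.mask] = nodata
    if abs(g.dx - g.dy) <= 1e-12 * max(g.dx, g.dy):
        size_lines = f"cellsize {g.dx!r}\n"
    else:
        size_lines = f"dx {g.dx!r}\ndy {g.dy!r}\n"
    header = (
        f"ncols {g.cols}\n"
        f"nrows {g.rows}\n"
        f"xllcorner {g.x_min!r}\n"
        f"yllcorner {g.y_min!r}\n"
        f"{size_lines}"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path, crs: str = "EPSG:4326") -> Raster:
    """Read an ESRI ASCII grid into a :class:`Raster`."""
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in _HEADER_KEYS:
            header[m.group(1).lower()] = float(m.group(2))
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII grid header field '{key}'")
    if "cellsize" in header:
        dx = dy = header["cellsize"]
    elif "dx" in header and "dy" in header:
        dx, dy = header["dx"], header["dy"]
    else:
        raise FormatError(f"{path}: missing 'cellsize' (or 'dx'/'dy') header field")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(lines[data_start:], dtype=float)
    values = values.reshape(rows, cols)
    nodata = header.get("nodata_value")
    mask = np.ones((rows, cols), dtype=bool) if nodata is None else values != nodata
    grid = GridSpec(
        rows=rows,
        cols=cols,
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + rows * dy,
        dx=dx,
        dy=dy,
        crs=crs,
    )
    return Raster(grid=grid, values=values, mask=mask)
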