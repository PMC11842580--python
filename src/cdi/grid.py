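"""Regular geographic grid model and the raster containers used throughout.

All rasters live on a north-up regular lon/lat grid (EPSG:4326) with
cell-center registration: cell (0, 0) is the north-western cell, rows run
south, columns run east.  The default cell size of 1/24 decimal degrees
(~5 km at the equator) matches the operational drought-monitoring grid,
but grids of any size/resolution are accepted.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dekads import Dekad

DEFAULT_CELL_SIZE = 1.0 / 24.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid, cell-center registered, north-up.

    ``lon_origin`` / ``lat_origin`` are the coordinates of the *outer
    corner* of the top-left cell (west edge, north edge), matching the
    GDAL geotransform convention.  Cell intervals are half-open
    ``[edge, edge + size)``.
    """

    n_rows: int
    n_cols: int
    lon_origin: float
    lat_origin: float
    cell_size: float = DEFAULT_CELL_SIZE
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must contain at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    # ------------------------------------------------------------------
    # coordinate transforms
    # ------------------------------------------------------------------
    def rowcol_to_lonlat(self, row, col):
        """Cell-center coordinates of (row, col); affine in both indices."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.lon_origin + (col + 0.5) * self.cell_size
        lat = self.lat_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def lonlat_to_rowcol(self, lon, lat):
        """Integer indices of the cell containing (lon, lat)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_origin) / self.cell_size).astype(int)
        row = np.floor((self.lat_origin - lat) / self.cell_size).astype(int)
        return row, col

    def lonlat_to_fractional_rowcol(self, lon, lat):
        """Continuous (row, col) such that integers fall on cell centers."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = (lon - self.lon_origin) / self.cell_size - 0.5
        row = (self.lat_origin - lat) / self.cell_size - 0.5
        return row, col

    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    # ------------------------------------------------------------------
    # interop
    # ------------------------------------------------------------------
    def to_geotransform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style 6-element geotransform."""
        return (self.lon_origin, self.cell_size, 0.0, self.lat_origin, 0.0, -self.cell_size)

    @classmethod
    def from_geotransform(cls, gt: Sequence[float], n_rows: int, n_cols: int) -> "GridSpec":
        if gt[2] != 0 or gt[4] != 0:
            raise ValueError("rotated grids are not supported")
        if gt[5] >= 0:
            raise ValueError("grid must be north-up (negative row step)")
        if abs(gt[1]) != abs(gt[5]):
            raise ValueError("anisotropic cells are not supported")
        return cls(n_rows=n_rows, n_cols=n_cols, lon_origin=gt[0], lat_origin=gt[3], cell_size=gt[1])


TimeTag = Union[Dekad, _dt.date, None]


@dataclass
class RasterField:
    """A single 2-D raster: values + validity mask on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    variable: str = ""
    time: TimeTag = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape mismatch")

    def masked(self) -> np.ndarray:
        """Values with invalid pixels as NaN."""
        out = self.values.astype(float).copy()
        out[~self.valid] = np.nan
        return out

    def with_values(self, values: np.ndarray, valid: Optional[np.ndarray] = None,
                    variable: Optional[str] = None) -> "RasterField":
        return RasterField(self.grid, values, valid if valid is not None else self.valid.copy(),
                           variable if variable is not None else self.variable, self.time)


@dataclass
class DailyStack:
    """A date-indexed stack of rasters sharing one grid.

    ``data`` is (time, row, col); ``valid`` marks usable pixels.
    """

    grid: GridSpec
    dates: list[_dt.date]
    data: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    variable: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (len(self.dates),) + self.grid.shape:
            raise ValueError("data shape does not match (n_dates, n_rows, n_cols)")
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        self._index = {d: i for i, d in enumerate(self.dates)}

    def __len__(self) -> int:
        return len(self.dates)

    def index_of(self, date: _dt.date) -> int:
        try:
            return self._index[date]
        except KeyError:
            raise KeyError(f"date {date} not in stack") from None

    def window(self, start: _dt.date, end: _dt.date) -> tuple[np.ndarray, np.ndarray]:
        """(data, valid) sub-stack for all days in [start, end]; raises if any day is absent."""
        n = (end - start).days + 1
        if n <= 0:
            raise ValueError("empty window")
        idx = [self.index_of(start + _dt.timedelta(days=k)) for k in range(n)]
        return self.data[idx], self.valid[idx]

    def field(self, date: _dt.date) -> RasterField:
        i = self.index_of(date)
        return RasterField(self.grid, self.data[i], self.valid[i], self.variable, date)
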