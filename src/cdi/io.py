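"""Raster IO: CF-style netCDF stacks and single-band GeoTIFFs.

netCDF files are written through xarray with coordinate variables and
Climate-and-Forecast-style attributes (``flag_values``/``flag_meanings``
for class maps).  GeoTIFFs are written through tifffile with the
standard GeoTIFF tags for a geographic (EPSG:4326) north-up grid:
ModelPixelScale, ModelTiepoint, the GeoKey directory and the GDAL
nodata tag; class maps embed a color palette.

Dekads are encoded in GeoTIFF filenames as ``{var}_{YYYY}{MM}{D}.tif``
with D in {1,2,3}; netCDF time axes carry the first day of each dekad
plus a ``dekad_of_year`` auxiliary variable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import tifffile
import xarray as xr

from .classifier import CLASS_COLORS, MISSING, CdiClass
from .dekads import Dekad
from .grid import DailyStack, GridSpec, RasterField

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_NODATA = 42113

# GTModelType=geographic, GTRasterType=PixelIsArea, GeographicType=EPSG:4326
_GEOKEYS_4326 = (1, 1, 0, 3,
                 1024, 0, 1, 2,
                 1025, 0, 1, 1,
                 2048, 0, 1, 4326)

CLASS_MEANINGS = " ".join(c.name.lower() for c in CdiClass)


# ----------------------------------------------------------------------
# GeoTIFF
# ----------------------------------------------------------------------

def write_geotiff(field: RasterField, path: str | Path, *, nodata: float = np.nan,
                  dtype=None, palette: bool = False) -> Path:
    """Write one raster band as GeoTIFF with EPSG:4326 geo tags."""
    path = Path(path)
    grid = field.grid
    values = field.values.copy()
    values[~field.valid] = nodata
    if dtype is not None:
        values = values.astype(dtype)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_origin, grid.lat_origin, 0.0)),
        (_TAG_GEOKEYS, "H", len(_GEOKEYS_4326), _GEOKEYS_4326),
        (_TAG_NODATA, "s", 0, str(nodata)),
    ]
    kwargs = {}
    if palette:
        cmap = np.zeros((3, 256), dtype=np.uint16)
        for cls, rgb in CLASS_COLORS.items():
            cmap[:, int(cls)] = [v * 257 for v in rgb]
        kwargs["colormap"] = cmap
    tifffile.imwrite(path, values, extratags=extratags, **kwargs)
    return path


def read_geotiff(path: str | Path, *, variable: str = "",
                 time: Dekad | _dt.date | None = None) -> RasterField:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_GEOKEYS in tags:
        keys = tuple(tags[_TAG_GEOKEYS])
        kv = {keys[i]: keys[i + 3] for i in range(4, len(keys), 4)}
        if kv.get(2048, 4326) != 4326 or kv.get(1024, 2) != 2:
            raise ValueError(f"{path}: not a geographic EPSG:4326 raster")
    try:
        sx = tags[_TAG_PIXEL_SCALE][0]
        tie = tags[_TAG_TIEPOINT]
    except KeyError:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from None
    grid = GridSpec(n_rows=values.shape[0], n_cols=values.shape[1],
                    lon_origin=tie[3], lat_origin=tie[4], cell_size=sx)
    nodata = tags.get(_TAG_NODATA)
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    if nodata is not None and nodata != "nan":
        valid &= values != float(nodata)
    return RasterField(grid, values, valid, variable, time)


def dekad_filename(variable: str, dekad: Dekad) -> str:
    return f"{variable}_{dekad.year:04d}{dekad.month:02d}{dekad.dekad_of_month}.tif"


_FILENAME_RE = re.compile(r"^(?P<var>.+)_(?P<y>\d{4})(?P<m>\d{2})(?P<d>[123])\.tif$")


def parse_dekad_filename(name: str) -> tuple[str, Dekad]:
    m = _FILENAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(f"{name!r} does not match '{{var}}_YYYYMMD.tif'")
    return m["var"], Dekad.from_month(int(m["y"]), int(m["m"]), int(m["d"]))


# ----------------------------------------------------------------------
# netCDF
# ----------------------------------------------------------------------

def _coords(grid: GridSpec, times) -> dict:
    return {
        "time": ("time", np.asarray(times, dtype="datetime64[ns]")),
        "lat": ("lat", grid.lat_centers(), {"units": "degrees_north", "standard_name": "latitude"}),
        "lon": ("lon", grid.lon_centers(), {"units": "degrees_east", "standard_name": "longitude"}),
    }


def write_stack_netcdf(stack: DailyStack, path: str | Path, *, units: str = "") -> Path:
    """Write a daily stack as a CF-style netCDF file."""
    path = Path(path)
    data = np.where(stack.valid, stack.data, np.nan).astype(np.float32)
    attrs = {"long_name": stack.variable}
    if units:
        attrs["units"] = units
    ds = xr.Dataset(
        {stack.variable or "value": (("time", "lat", "lon"), data, attrs)},
        coords=_coords(stack.grid, [np.datetime64(d) for d in stack.dates]),
        attrs={"Conventions": "CF-1.8", "crs": stack.grid.crs},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_stack_netcdf(path: str | Path, variable: str,
                      expected_grid: Optional[GridSpec] = None) -> DailyStack:
    """Read a daily stack; decodes the CF time axis to calendar dates."""
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds[variable].load()
    lat = np.asarray(da["lat"].values, dtype=float)
    lon = np.asarray(da["lon"].values, dtype=float)
    cell = float(abs(lon[1] - lon[0])) if lon.size > 1 else float(abs(lat[0] - lat[1]))
    data = np.asarray(da.values, dtype=float)
    if lat.size > 1 and lat[0] < lat[-1]:  # force north-up
        lat = lat[::-1]
        data = data[:, ::-1, :]
    grid = GridSpec(n_rows=lat.size, n_cols=lon.size,
                    lon_origin=float(lon[0]) - cell / 2,
                    lat_origin=float(lat[0]) + cell / 2, cell_size=cell)
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"{path}: grid does not match the expected grid")
    dates = [np.datetime64(t, "D").astype(_dt.date) for t in da["time"].values]
    return DailyStack(grid, dates, data, np.isfinite(data), variable)


def write_cdi_netcdf(maps: list[np.ndarray], dekads: list[Dekad], grid: GridSpec,
                     path: str | Path) -> Path:
    """Write a CDI class-map series with CF flag attributes."""
    path = Path(path)
    data = np.stack(maps).astype(np.int16)
    ds = xr.Dataset(
        {
            "cdi": (("time", "lat", "lon"), data, {
                "long_name": "combined drought indicator class",
                "flag_values": np.arange(7, dtype=np.int16),
                "flag_meanings": CLASS_MEANINGS,
                "_FillValue": np.int16(MISSING),
            }),
            "dekad_of_year": (("time",), np.array([d.ordinal for d in dekads], dtype=np.int16),
                              {"long_name": "dekad of year (1..36)"}),
        },
        coords=_coords(grid, [np.datetime64(d.start_date) for d in dekads]),
        attrs={"Conventions": "CF-1.8", "crs": grid.crs},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_cdi_netcdf(path: str | Path) -> tuple[list[np.ndarray], list[Dekad], GridSpec]:
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
        data = np.asarray(ds["cdi"].values)
        times = [np.datetime64(t, "D").astype(_dt.date) for t in ds["time"].values]
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
    cell = float(abs(lon[1] - lon[0])) if lon.size > 1 else float(abs(lat[0] - lat[1]))
    grid = GridSpec(n_rows=lat.size, n_cols=lon.size,
                    lon_origin=float(lon[0]) - cell / 2,
                    lat_origin=float(lat[0]) + cell / 2, cell_size=cell)
    maps = [layer.astype(np.uint8) for layer in data]
    return maps, [Dekad.from_date(t) for t in times], grid


def write_cdi_geotiff(class_map: np.ndarray, dekad: Dekad, grid: GridSpec,
                      directory: str | Path) -> Path:
    field = RasterField(grid, class_map.astype(float), class_map != MISSING, "cdi", dekad)
    path = Path(directory) / dekad_filename("cdi", dekad)
    return write_geotiff(field, path, nodata=int(MISSING), dtype=np.uint8, palette=True)


# ----------------------------------------------------------------------
# provenance
# ----------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(config: dict, path: str | Path) -> Path:
    path = Path(path)
    record = {"config": config, "config_hash": config_hash(config)}
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
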