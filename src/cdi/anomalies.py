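"""Z-score anomalies for soil moisture and vegetation (SMA, FAPAR anomaly).

Both indicators share the same standardization: an observed dekadal value
``I`` is expressed as a departure from its per-pixel, per-dekad baseline
climatology,

    Z = (I - mu) / sigma

where ``mu`` and ``sigma`` are the mean and sample standard deviation of
``I`` over the baseline years at that pixel and dekad-of-year.

* SMA standardizes the dekadal mean of the daily Soil Moisture Index
  (SMI in [0, 1], 0 = extremely dry, 1 = extremely wet); the operational
  baseline uses all years from 1995 onward.
* The FAPAR anomaly standardizes dekadal FAPAR composites built from
  8-day satellite composites via inverse-time-distance weighting; the
  operational baseline uses all years from 2012 onward.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .dekads import Dekad
from .grid import DailyStack, GridSpec, RasterField

#: minimum valid days inside a dekad for a usable dekadal SMI mean
DEFAULT_MIN_VALID_DAYS = 7
#: minimum baseline years for a usable climatology pixel
DEFAULT_MIN_YEARS = 5
#: guard against division blow-up where the baseline is near-constant
SIGMA_MIN = 1e-6
#: half-day offset used when inverse-distance weights would hit zero
TIME_WEIGHT_EPS = 0.5


@dataclass
class Climatology:
    """Per-pixel mean/sd for one dekad-of-year over a set of baseline years."""

    grid: GridSpec
    mean: np.ndarray
    sd: np.ndarray
    n_years: np.ndarray
    valid: np.ndarray
    variable: str = ""
    baseline: str = ""


def aggregate_smi_dekad(smi: DailyStack, dekad: Dekad, *,
                        min_valid_days: int = DEFAULT_MIN_VALID_DAYS) -> RasterField:
    """Dekadal Soil Moisture Index: the mean of the N daily SMI fields.

    Pixels with fewer than ``min_valid_days`` valid days are invalid.
    Raises if the stack does not cover the dekad.
    """
    try:
        data, valid = smi.window(dekad.start_date, dekad.end_date)
    except KeyError as exc:
        raise ValueError(f"SMI stack does not cover dekad {dekad}") from exc
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(valid, data, 0.0).sum(axis=0) / np.maximum(n_valid, 1)
    ok = n_valid >= min(min_valid_days, dekad.day_count)
    return RasterField(smi.grid, mean, ok, "smi_dekad", dekad)


def build_climatology(fields: list[RasterField], *,
                      min_years: int = DEFAULT_MIN_YEARS,
                      sigma_min: float = SIGMA_MIN) -> Climatology:
    """Per-pixel baseline mean and sd (n-1 denominator) over years.

    All fields must share one grid and represent the same dekad-of-year in
    different years.  Pixels with fewer than ``min_years`` valid years or
    sd <= ``sigma_min`` are flagged invalid.
    """
    if not fields:
        raise ValueError("empty baseline")
    grid = fields[0].grid
    for f in fields:
        if f.grid != grid:
            raise ValueError("baseline fields are on different grids")
    data = np.stack([f.values for f in fields])
    valid = np.stack([f.valid for f in fields])
    vals = np.where(valid, data, np.nan)
    n = valid.sum(axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        warnings.filterwarnings("ignore", "Degrees of freedom")
        mean = np.nanmean(np.where(valid, data, np.nan), axis=0)
        sd = np.full(grid.shape, np.nan)
        enough = n >= 2
        sd[enough] = np.nanstd(vals, axis=0, ddof=1)[enough]
    ok = (n >= min_years) & np.isfinite(sd) & (sd > sigma_min)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    sd = np.where(np.isfinite(sd), sd, 1.0)
    return Climatology(grid=grid, mean=mean, sd=sd, n_years=n, valid=ok,
                       variable=fields[0].variable)


def standardize(field: RasterField, clim: Climatology, *,
                variable: str | None = None) -> RasterField:
    """Z-score a dekadal field against its baseline climatology."""
    if field.grid != clim.grid:
        raise ValueError("field and climatology are on different grids")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (field.values - clim.mean) / clim.sd
    valid = field.valid & clim.valid
    z = np.where(valid, z, np.nan)
    name = variable if variable is not None else (field.variable + "_anomaly")
    return RasterField(field.grid, z, valid, name, field.time)


# ----------------------------------------------------------------------
# FAPAR: 8-day composites -> dekadal composites
# ----------------------------------------------------------------------

@dataclass
class Fapar8Day:
    """One 8-day FAPAR composite with its per-pixel quality flags."""

    field: RasterField
    start: _dt.date
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros(self.field.grid.shape, dtype=np.uint8)
        self.flags = np.asarray(self.flags)
        if self.flags.shape != self.field.grid.shape:
            raise ValueError("flags shape mismatch")

    @property
    def midpoint(self) -> _dt.datetime:
        return _dt.datetime.combine(self.start, _dt.time()) + _dt.timedelta(days=4.0)


#: flags accepted by default: 0 = good retrieval, 1 = usable (saturated/backup)
DEFAULT_ACCEPTED_FLAGS = frozenset({0, 1})


def qc_filter_fapar(comp: Fapar8Day, accepted: frozenset[int] = DEFAULT_ACCEPTED_FLAGS) -> Fapar8Day:
    """Invalidate pixels whose quality flag is not in the accepted set."""
    keep = np.isin(comp.flags, list(accepted))
    f = comp.field
    return Fapar8Day(RasterField(f.grid, f.values, f.valid & keep, f.variable, f.time),
                     comp.start, comp.flags)


def composite_fapar_dekad(composites: list[Fapar8Day], dekad: Dekad, *,
                          k_nearest: int = 2, eps: float = TIME_WEIGHT_EPS) -> RasterField:
    """Dekadal FAPAR from the temporally closest 8-day composites.

    The ``k_nearest`` composites by |composite midpoint - dekad midpoint|
    are blended with weights proportional to ``1 / (distance_days + eps)``,
    renormalized per pixel over the valid inputs.
    """
    if not composites:
        raise ValueError("no composites supplied")
    mid = dekad.midpoint
    dist = [abs((c.midpoint - mid).total_seconds()) / 86400.0 for c in composites]
    order = np.argsort(dist, kind="stable")[:k_nearest]
    chosen = [composites[i] for i in order]
    w = np.array([1.0 / (dist[i] + eps) for i in order])

    grid = chosen[0].field.grid
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    for comp, wi in zip(chosen, w):
        if comp.field.grid != grid:
            raise ValueError("composites are on different grids")
        v = comp.field.valid
        num += np.where(v, comp.field.values, 0.0) * wi
        den += np.where(v, wi, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    valid = den > 0
    out = np.where(valid, out, np.nan)
    return RasterField(grid, out, valid, "fapar_dekad", dekad)


def resample_bilinear(field: RasterField, target: GridSpec) -> RasterField:
    """Bilinear resampling of ``field`` onto ``target`` cell centers.

    Invalid source pixels drop out of the interpolation (weights are
    renormalized over the valid corners); a target pixel with no valid
    contributing corner is invalid.  Outputs are convex combinations of
    the contributing values, hence bounded by their local min/max.
    """
    src = field.grid
    lon, lat = np.meshgrid(target.lon_centers(), target.lat_centers())
    rf, cf = src.lonlat_to_fractional_rowcol(lon, lat)

    r0 = np.clip(np.floor(rf).astype(int), 0, src.n_rows - 1)
    c0 = np.clip(np.floor(cf).astype(int), 0, src.n_cols - 1)
    r1 = np.clip(r0 + 1, 0, src.n_rows - 1)
    c1 = np.clip(c0 + 1, 0, src.n_cols - 1)
    fr = np.clip(rf - r0, 0.0, 1.0)
    fc = np.clip(cf - c0, 0.0, 1.0)

    num = np.zeros(target.shape)
    den = np.zeros(target.shape)
    corners = [(r0, c0, (1 - fr) * (1 - fc)), (r0, c1, (1 - fr) * fc),
               (r1, c0, fr * (1 - fc)), (r1, c1, fr * fc)]
    for rr, cc, w in corners:
        v = field.valid[rr, cc]
        num += np.where(v, field.values[rr, cc], 0.0) * w
        den += np.where(v, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    valid = den > 1e-12
    out = np.where(valid, out, np.nan)
    return RasterField(target, out, valid, field.variable, field.time)
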