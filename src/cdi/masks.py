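"""Dynamic snow masks and static crop/growing-season masks.

Snow masks exclude model-based soil moisture anomalies where snow covers
the ground (the hydrological model's simple degree-day snow scheme makes
them unreliable there).  Daily snow presence is derived from NDSI fields
(0-100 plus cloud/fill codes) and composited to dekads with a
3-days-out-of-10 rule; fully cloud-covered pixels inherit the previous
dekad's value; fine-resolution masks are brought to the coarse grid by
modal resampling.

Crop masks exclude vegetation (FAPAR) anomalies over cropland outside
the growing season, where bare soil after harvest would otherwise mimic
drought stress.  A pixel is cropland if its crop fraction is at least 1%
and it is not rangeland; the growing season is the circular dekad
interval [SOS, EOS] from static phenology maps, giving 36 static
ternary maps (non-crop / crop out of season / crop in season).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dekads import Dekad
from .grid import GridSpec, RasterField

# daily ternary snow states
SNOW = np.int8(1)
NO_SNOW = np.int8(0)
MISSING = np.int8(-1)

# crop-season ternary states
NON_CROP = np.uint8(0)
CROP_OUT_OF_SEASON = np.uint8(1)
CROP_IN_SEASON = np.uint8(2)

#: NDSI above this value maps to snow; 1..uncertain_max is discarded
NDSI_SNOW_MIN = 10
#: snow must be seen on at least this many days of a dekad
DEFAULT_MIN_SNOW_DAYS = 3
#: minimum crop fraction (percent) for a cropland pixel
DEFAULT_CROP_FRACTION_PCT = 1.0


def classify_ndsi(ndsi: np.ndarray, *, special_codes: frozenset[int] = frozenset({201, 211, 237, 239, 250, 251, 252, 253, 254, 255}),
                  uncertain: str = "no_snow") -> np.ndarray:
    """Daily snow/no-snow/missing call from an NDSI field.

    NDSI 0 is snow-free ground, values in 1-10 are discarded as uncertain
    (mapped to no-snow by default, configurable to missing), values above
    10 are snow, and the product's special codes (clouds, fill, ...) are
    missing.  Values outside 0-100 that are not special codes raise.
    """
    ndsi = np.asarray(ndsi)
    special = np.isin(ndsi, list(special_codes)) | ~np.isfinite(np.asarray(ndsi, dtype=float))
    bad = ~special & ((ndsi < 0) | (ndsi > 100))
    if bad.any():
        raise ValueError(f"NDSI values out of range 0-100: e.g. {np.asarray(ndsi)[bad].flat[0]}")
    out = np.full(ndsi.shape, NO_SNOW, dtype=np.int8)
    out[~special & (ndsi > NDSI_SNOW_MIN)] = SNOW
    uncertain_px = ~special & (ndsi >= 1) & (ndsi <= NDSI_SNOW_MIN)
    if uncertain == "missing":
        out[uncertain_px] = MISSING
    elif uncertain != "no_snow":
        raise ValueError("uncertain must be 'no_snow' or 'missing'")
    out[special] = MISSING
    return out


@dataclass
class SnowMask:
    """Binary dekadal snow presence on the CDI grid."""

    grid: GridSpec
    snow: np.ndarray
    dekad: Dekad

    def __post_init__(self) -> None:
        self.snow = np.asarray(self.snow, dtype=bool)
        if self.snow.shape != self.grid.shape:
            raise ValueError("snow mask shape mismatch")


def composite_snow_dekad(days: list[np.ndarray], grid: GridSpec, dekad: Dekad,
                         previous: SnowMask | None = None, *,
                         min_snow_days: int = DEFAULT_MIN_SNOW_DAYS,
                         proportional: bool = False) -> SnowMask:
    """Dekadal snow mask from daily ternary snow fields.

    A pixel is snow if SNOW was observed on at least ``min_snow_days``
    days (or ``ceil(0.3 * N)`` in proportional mode, for dekads spanning
    N != 10 days).  A pixel with zero non-missing days copies the previous
    dekad's value; with no previous mask it defaults to snow-free.
    """
    if not days:
        raise ValueError("empty day list")
    stack = np.stack([np.asarray(d, dtype=np.int8) for d in days])
    if stack.shape[1:] != grid.shape:
        raise ValueError("daily snow fields do not match the grid")
    snow_days = (stack == SNOW).sum(axis=0)
    observed = (stack != MISSING).sum(axis=0)
    thr = int(np.ceil(0.3 * len(days))) if proportional else min_snow_days
    snow = snow_days >= thr
    unobserved = observed == 0
    if previous is not None:
        snow = np.where(unobserved, previous.snow, snow)
    else:
        snow = np.where(unobserved, False, snow)
    return SnowMask(grid, snow, dekad)


def resample_modal(fine: np.ndarray, fine_grid: GridSpec, target: GridSpec, *,
                   tie_value: bool = True) -> np.ndarray:
    """Modal (most frequent) aggregation of a fine binary mask to a coarser grid.

    Every fine cell votes in the target cell containing its center; the
    majority wins, with exact ties broken toward ``tie_value`` (snow by
    default — conservative, since masked pixels only suppress unreliable
    soil-moisture anomalies).
    """
    fine = np.asarray(fine, dtype=bool)
    if fine.shape != fine_grid.shape:
        raise ValueError("fine mask shape mismatch")
    if fine_grid.cell_size > target.cell_size:
        raise ValueError("fine grid must be at least as fine as the target")
    rows, cols = np.meshgrid(np.arange(fine_grid.n_rows), np.arange(fine_grid.n_cols), indexing="ij")
    lon, lat = fine_grid.rowcol_to_lonlat(rows, cols)
    tr, tc = target.lonlat_to_rowcol(lon, lat)
    inside = (tr >= 0) & (tr < target.n_rows) & (tc >= 0) & (tc < target.n_cols)
    if not inside.any():
        raise ValueError("grids do not overlap")
    flat = tr[inside] * target.n_cols + tc[inside]
    votes_true = np.bincount(flat, weights=fine[inside].astype(float), minlength=target.n_pixels)
    votes_all = np.bincount(flat, minlength=target.n_pixels)
    true_share = np.zeros(target.n_pixels)
    has = votes_all > 0
    true_share[has] = votes_true[has] / votes_all[has]
    if tie_value:
        out = true_share >= 0.5
    else:
        out = true_share > 0.5
    out[~has] = False
    return out.reshape(target.shape)


def season_contains(sos, eos, t) -> np.ndarray:
    """Inclusive membership of dekad-of-year ``t`` in the circular interval
    [SOS, EOS]; seasons wrapping the year boundary (SOS > EOS) are handled.
    """
    sos = np.asarray(sos)
    eos = np.asarray(eos)
    t = np.asarray(t)
    if ((sos < 1) | (sos > 36) | (eos < 1) | (eos > 36) | (t < 1) | (t > 36)).any():
        raise ValueError("dekad-of-year values must be in 1..36")
    no_wrap = sos <= eos
    return np.where(no_wrap, (t >= sos) & (t <= eos), (t >= sos) | (t <= eos))


@dataclass
class PhenologyMaps:
    """Static start/end of growing season, in dekads-of-year, per pixel."""

    sos: np.ndarray
    eos: np.ndarray


def build_crop_mask(crop_fraction: np.ndarray, rangeland: np.ndarray,
                    phenology: PhenologyMaps, *,
                    fraction_threshold_pct: float = DEFAULT_CROP_FRACTION_PCT) -> np.ndarray:
    """The 36 static ternary crop/growing-season masks, as (36, rows, cols).

    NON_CROP where the crop fraction is below the threshold, the pixel is
    rangeland, or phenology is missing; otherwise CROP_IN_SEASON for
    dekads inside [SOS, EOS] and CROP_OUT_OF_SEASON elsewhere.
    """
    frac = np.asarray(crop_fraction, dtype=float)
    rangeland = np.asarray(rangeland, dtype=bool)
    if ((frac < 0) | (frac > 100)).any():
        raise ValueError("crop fraction must be a percentage in 0-100")
    crop = (frac >= fraction_threshold_pct) & ~rangeland

    sos = np.asarray(phenology.sos, dtype=float)
    eos = np.asarray(phenology.eos, dtype=float)
    pheno_ok = np.isfinite(sos) & np.isfinite(eos)
    pheno_ok &= (sos >= 1) & (sos <= 36) & (eos >= 1) & (eos <= 36)
    if (crop & ~pheno_ok).any():
        import warnings
        warnings.warn("crop pixels without phenology were demoted to non-crop")
    crop &= pheno_ok

    sos_i = np.where(pheno_ok, sos, 1).astype(int)
    eos_i = np.where(pheno_ok, eos, 1).astype(int)
    out = np.zeros((36,) + frac.shape, dtype=np.uint8)
    for t in range(1, 37):
        in_season = season_contains(sos_i, eos_i, np.full(frac.shape, t, dtype=int))
        layer = np.full(frac.shape, NON_CROP, dtype=np.uint8)
        layer[crop & ~in_season] = CROP_OUT_OF_SEASON
        layer[crop & in_season] = CROP_IN_SEASON
        out[t - 1] = layer
    return out
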