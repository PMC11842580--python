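"""Standardized Precipitation Index (SPI) at ~30-day and ~90-day scales.

The SPI measures how unusual the precipitation accumulated over a fixed
timescale is relative to a reference climatology.  Because precipitation
totals are right-skewed and zero-inflated, the accumulated totals are fit
to a gamma distribution mixed with a point mass at zero:

    H(x) = q + (1 - q) * G(x; k, theta)          x > 0

where ``q`` is the probability of a zero total and ``G`` the gamma CDF.
The SPI is the standard-normal deviate of the fitted non-exceedance
probability, ``z = Phi^-1(H(x))``; zero totals are mapped through
``Phi^-1(q / 2)`` (the centre of the zero mass).  SPI-1 accumulates ~30
days and flags extreme meteorological drought below -2; SPI-3 accumulates
~90 days and flags moderate meteorological drought below -1.

Gamma parameters are estimated per pixel and per dekad over a 30-year
reference period (1981-2010 in the operational product) with the
closed-form maximum-likelihood approximation of Thom, with a
method-of-moments fallback for degenerate samples; exact MLE through
scipy is available per pixel.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dekads import Dekad
from .grid import DailyStack, GridSpec, RasterField

#: default clamp on |SPI| to keep extreme tails finite
DEFAULT_Z_MAX = 3.5
#: minimum baseline years for a usable fit
DEFAULT_MIN_YEARS = 20
#: minimum strictly positive totals for a usable gamma fit
DEFAULT_MIN_POSITIVE = 10

SCALE_WINDOW_DAYS = {1: 30, 3: 90}


@dataclass
class GammaFit:
    """Per-pixel gamma + zero-mass parameters for one terminal dekad."""

    shape: np.ndarray       # k > 0
    scale: np.ndarray       # theta > 0
    zero_prob: np.ndarray   # q in [0, 1)
    n_years: int
    valid: np.ndarray


@dataclass
class GammaClimatology:
    """Gamma fits keyed by dekad-of-year, for one accumulation scale."""

    grid: GridSpec
    scale: int
    baseline_years: tuple[int, int]
    fits: dict[int, GammaFit] = field(default_factory=dict)

    def fit_for(self, dekad: Dekad) -> GammaFit:
        try:
            return self.fits[dekad.ordinal]
        except KeyError:
            raise KeyError(f"no gamma fit for dekad ordinal {dekad.ordinal}") from None


def accumulate_precipitation(precip: DailyStack, dekad: Dekad, window_days: int) -> RasterField:
    """Per-pixel precipitation total over the ``window_days`` ending at the
    last day of ``dekad``.

    A pixel is invalid if any contributing day is invalid.  Raises if the
    stack does not cover the full window.
    """
    end = dekad.end_date
    start = end - _dt.timedelta(days=window_days - 1)
    try:
        data, valid = precip.window(start, end)
    except KeyError as exc:
        raise ValueError(f"precipitation stack does not cover {start}..{end}") from exc
    total = np.where(valid, data, 0.0).sum(axis=0)
    all_valid = valid.all(axis=0)
    return RasterField(precip.grid, total, all_valid, f"precip_total_{window_days}d", dekad)


def _thom_fit(positives: np.ndarray, count: np.ndarray):
    """Vectorized closed-form ML approximation for the gamma shape/scale.

    ``positives`` is (n, ...) with NaN where the total was zero/invalid;
    ``count`` the per-pixel number of finite positive entries.
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        mean = np.nanmean(positives, axis=0)
        logmean = np.log(mean)
        meanlog = np.nanmean(np.log(positives), axis=0)
        a = logmean - meanlog
        # a -> 0 when the sample is near-constant; cap shape to stay finite
        a = np.maximum(a, 1e-8)
        shape = (1.0 + np.sqrt(1.0 + 4.0 * a / 3.0)) / (4.0 * a)
        scale = mean / shape
    return shape, scale


def fit_gamma_climatology_dekad(totals: np.ndarray, valid: np.ndarray, *,
                                min_years: int = DEFAULT_MIN_YEARS,
                                min_positive: int = DEFAULT_MIN_POSITIVE,
                                method: str = "thom") -> GammaFit:
    """Fit the zero-inflated gamma model per pixel for one terminal dekad.

    Parameters
    ----------
    totals : (n_years, n_rows, n_cols) accumulated precipitation per baseline year
    valid : same shape, per-year validity
    method : "thom" (closed-form ML approximation, vectorized) or "mle"
        (scipy per-pixel maximum likelihood; slower)
    """
    totals = np.asarray(totals, dtype=float)
    if totals.ndim != 3 or totals.shape[0] == 0:
        raise ValueError("totals must be (n_years, n_rows, n_cols) with n_years >= 1")
    n_years = totals.shape[0]
    valid = np.asarray(valid, dtype=bool)

    finite = valid & np.isfinite(totals)
    n_obs = finite.sum(axis=0)
    positive = finite & (totals > 0)
    n_pos = positive.sum(axis=0)
    n_zero = (finite & (totals <= 0)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_obs > 0, n_zero / np.maximum(n_obs, 1), 1.0)

    pos_vals = np.where(positive, totals, np.nan)
    if method == "thom":
        shape, scale = _thom_fit(pos_vals, n_pos)
    elif method == "mle":
        shape = np.full(totals.shape[1:], np.nan)
        scale = np.full(totals.shape[1:], np.nan)
        for r in range(totals.shape[1]):
            for c in range(totals.shape[2]):
                x = pos_vals[:, r, c]
                x = x[np.isfinite(x)]
                if x.size < 2 or np.ptp(x) == 0:
                    continue
                try:
                    k, _, th = stats.gamma.fit(x, floc=0)
                    shape[r, c], scale[r, c] = k, th
                except Exception:
                    # moments fallback keeps the pixel usable
                    m, v = x.mean(), x.var(ddof=1)
                    if v > 0:
                        shape[r, c], scale[r, c] = m * m / v, v / m
    else:
        raise ValueError(f"unknown fitting method {method!r}")

    ok = (
        (n_obs >= min_years)
        & (n_pos >= min_positive)
        & (q < 1.0)
        & np.isfinite(shape) & (shape > 0)
        & np.isfinite(scale) & (scale > 0)
    )
    return GammaFit(shape=shape, scale=scale, zero_prob=q, n_years=n_years, valid=ok)


def build_spi_climatology(precip: DailyStack, scale: int, baseline_years: tuple[int, int],
                          *, ordinals: list[int] | None = None,
                          min_years: int = DEFAULT_MIN_YEARS,
                          min_positive: int = DEFAULT_MIN_POSITIVE,
                          method: str = "thom") -> GammaClimatology:
    """Fit gamma climatologies for every requested dekad-of-year.

    ``scale`` is 1 (30-day) or 3 (90-day); the accumulation window ends at
    the terminal dekad's last day in every baseline year.
    """
    window = SCALE_WINDOW_DAYS[scale]
    y0, y1 = baseline_years
    clim = GammaClimatology(grid=precip.grid, scale=scale, baseline_years=baseline_years)
    for t in (ordinals if ordinals is not None else range(1, 37)):
        totals, valids = [], []
        for year in range(y0, y1 + 1):
            f = accumulate_precipitation(precip, Dekad(year, t), window)
            totals.append(f.values)
            valids.append(f.valid)
        clim.fits[t] = fit_gamma_climatology_dekad(
            np.stack(totals), np.stack(valids),
            min_years=min_years, min_positive=min_positive, method=method)
    return clim


def spi_value(total, fit: GammaFit, *, z_max: float = DEFAULT_Z_MAX) -> np.ndarray:
    """Transform accumulated totals to SPI z-scores under a fitted model.

    ``z = Phi^-1(q + (1-q) G(total))`` for positive totals and
    ``Phi^-1(q/2)`` for zero totals, clamped to ``[-z_max, z_max]``.
    """
    total = np.asarray(total, dtype=float)
    with np.errstate(invalid="ignore"):
        g = stats.gamma.cdf(total, a=fit.shape, scale=fit.scale)
        p = fit.zero_prob + (1.0 - fit.zero_prob) * g
        p = np.where(total <= 0, fit.zero_prob / 2.0, p)
        # keep probabilities strictly inside (0, 1) before the normal quantile
        tiny = 1e-12
        p = np.clip(p, tiny, 1.0 - tiny)
        z = stats.norm.ppf(p)
    return np.clip(z, -z_max, z_max)


def spi_field(precip: DailyStack, scale: int, dekad: Dekad,
              climatology: GammaClimatology, *, z_max: float = DEFAULT_Z_MAX) -> RasterField:
    """SPI map for ``dekad`` at accumulation scale 1 or 3."""
    if climatology.scale != scale:
        raise ValueError(f"climatology was fitted for scale {climatology.scale}, not {scale}")
    fit = climatology.fit_for(dekad)
    acc = accumulate_precipitation(precip, dekad, SCALE_WINDOW_DAYS[scale])
    z = spi_value(acc.values, fit, z_max=z_max)
    valid = acc.valid & fit.valid
    return RasterField(precip.grid, z, valid, f"spi{scale}", dekad)


def spi_exceedance(spi1, spi3, *, spi1_extreme: float = -2.0, spi3_moderate: float = -1.0):
    """The combined precipitation-deficit flag: (SPI-1 < -2) OR (SPI-3 < -1)."""
    return (np.asarray(spi1) < spi1_extreme) | (np.asarray(spi3) < spi3_moderate)
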