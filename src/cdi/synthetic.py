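"""Synthetic input scenes for the drought-classification pipeline.

Generates physically plausible gridded stacks of every input the
indicator pipeline consumes — daily precipitation, daily Soil Moisture
Index, 8-day FAPAR composites with quality flags, daily NDSI snow
fields, and the static crop fraction / rangeland / phenology rasters —
entirely from a seed, so the whole pipeline is testable without any
satellite or reanalysis download.

The generative model is deliberately simple but preserves the causal
chain the classifier is built around:

* precipitation is zero-inflated gamma with a seasonal wet-day
  probability and intensity (wetter winters);
* the Soil Moisture Index is a squashed response to the trailing 30-day
  precipitation ratio (observed / expected), so soil-moisture deficits
  follow precipitation deficits with a short lag;
* FAPAR follows a seasonal growth curve damped by the trailing 90-day
  precipitation deficit, so vegetation stress lags soil stress;
* NDSI is high in winter at high-latitude rows, with cloud gaps;
* drought events scale precipitation by a multiplier over a region and
  dekad window, and propagate into the soil and vegetation drivers
  after configurable lags.

The defaults mirror the operational study conditions: SPI reference
period 1981-2010, soil-moisture baseline from 1995 onward, FAPAR
baseline from 2012 onward, on a 40x40 cell grid at 1/24 degrees.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .anomalies import Fapar8Day
from .dekads import Dekad
from .grid import DailyStack, GridSpec, RasterField
from .masks import PhenologyMaps

# NDSI special codes used by the generator (cloud, fill)
CLOUD_CODE = 250
FILL_CODE = 255


@dataclass
class DroughtEvent:
    """A precipitation-deficit event injected into a scene.

    ``multiplier`` scales precipitation in [0, 1) over ``region`` between
    ``start`` and ``end`` (dekads, inclusive).  The deficit reaches the
    soil-moisture driver ``soil_lag`` dekads later and the vegetation
    driver ``veg_lag`` dekads later, encoding the drought propagation
    chain precipitation -> soil moisture -> vegetation.
    """

    region: tuple[slice, slice]
    start: Dekad
    end: Dekad
    multiplier: float = 0.2
    soil_lag: int = 2
    veg_lag: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.multiplier < 1:
            raise ValueError("multiplier must be in [0, 1)")
        if self.soil_lag < 0 or self.veg_lag < 0:
            raise ValueError("lags must be >= 0")
        if self.end < self.start:
            raise ValueError("event ends before it starts")

    def region_mask(self, grid: GridSpec) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[self.region] = True
        return m

    def shifted(self, lag_dekads: int) -> tuple[_dt.date, _dt.date]:
        s, e = self.start, self.end
        for _ in range(lag_dekads):
            s, e = s.next(), e.next()
        return s.start_date, e.end_date


@dataclass
class SceneConfig:
    """Everything that determines a synthetic scene (given the seed)."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(
        n_rows=40, n_cols=40, lon_origin=10.0, lat_origin=62.0))
    seed: int = 0
    # year ranges (operational study conditions)
    spi_baseline: tuple[int, int] = (1981, 2010)
    smi_start: int = 1995
    fapar_start: int = 2012
    end_year: int = 2020
    # precipitation model
    wet_prob_base: float = 0.45
    wet_prob_amplitude: float = 0.15
    gamma_shape: float = 0.7
    gamma_scale_mm: float = 6.0
    scale_amplitude: float = 0.3
    peak_doy: int = 15            # wettest day of year
    # soil-moisture response
    smi_gain: float = 2.5
    smi_noise_sd: float = 0.25
    # vegetation response
    fapar_floor: float = 0.12
    fapar_season_peak: float = 0.55
    fapar_peak_doy: int = 196
    fapar_season_width: float = 70.0
    fapar_damage_gain: float = 0.7
    fapar_noise_sd: float = 0.04
    fapar_reject_prob: float = 0.05
    # snow model
    snow_lat_min: float = 60.8    # below: never snow
    snow_lat_full: float = 61.7   # above: full winter snow
    snow_peak_doy: int = 15
    snow_threshold: float = 0.5
    snow_noise_sd: float = 0.08
    cloud_prob: float = 0.10
    uncertain_prob: float = 0.03
    # crop layout
    crop_fraction_south: float = 60.0
    sos_south: int = 10
    eos_south: int = 27
    sos_winter: int = 31          # wrap-around winter crop strip
    eos_winter: int = 12

    def __post_init__(self) -> None:
        if self.spi_baseline[0] > self.spi_baseline[1]:
            raise ValueError("invalid SPI baseline range")
        if self.end_year < self.fapar_start:
            raise ValueError("end_year precedes the FAPAR record start")
        if self.smi_start < self.spi_baseline[0] or self.fapar_start < self.spi_baseline[0]:
            raise ValueError("SMI/FAPAR records cannot start before the precipitation record")


@dataclass
class SyntheticScene:
    """The full generated input stack."""

    config: SceneConfig
    events: list[DroughtEvent]
    precip: DailyStack            # from (spi_baseline[0] - 1) to end_year
    smi: DailyStack               # from smi_start to end_year
    fapar: list[Fapar8Day]        # from fapar_start to end_year
    ndsi: DailyStack              # evaluation years (last two)
    crop_fraction: np.ndarray
    rangeland: np.ndarray
    phenology: PhenologyMaps

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


def _dates(y0: int, y1: int) -> list[_dt.date]:
    d = _dt.date(y0, 1, 1)
    out = []
    while d.year <= y1:
        out.append(d)
        d += _dt.timedelta(days=1)
    return out


def _doy(dates: Sequence[_dt.date]) -> np.ndarray:
    return np.array([d.timetuple().tm_yday for d in dates], dtype=float)


def _seasonal(doy: np.ndarray, peak: float) -> np.ndarray:
    """Cosine seasonal factor in [-1, 1], maximal at ``peak``."""
    return np.cos(2.0 * np.pi * (doy - peak) / 365.25)


def _trailing_sum(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing-window sum along axis 0; first window-1 entries are NaN."""
    cs = np.cumsum(x, axis=0, dtype=np.float64)
    out = np.full_like(cs, np.nan)
    out[window - 1] = cs[window - 1]
    out[window:] = cs[window:] - cs[:-window]
    return out


def _apply_events(precip: np.ndarray, dates: list[_dt.date], grid: GridSpec,
                  events: list[DroughtEvent], lag_attr: Optional[str]) -> np.ndarray:
    """Scale precipitation over each event's (optionally lag-shifted) window."""
    if not events:
        return precip
    out = precip.copy()
    index = {d: i for i, d in enumerate(dates)}
    for ev in events:
        lag = 0 if lag_attr is None else getattr(ev, lag_attr)
        d0, d1 = ev.shifted(lag)
        mask = ev.region_mask(grid)
        d = max(d0, dates[0])
        while d <= min(d1, dates[-1]):
            out[index[d]][mask] *= ev.multiplier
            d += _dt.timedelta(days=1)
    return out


def config_to_dict(config: SceneConfig, events: Sequence[DroughtEvent] = ()) -> dict:
    """Plain-dict form of a scene configuration (YAML/JSON friendly)."""
    d = {k: v for k, v in vars(config).items() if k != "grid"}
    d["grid"] = {"n_rows": config.grid.n_rows, "n_cols": config.grid.n_cols,
                 "lon_origin": config.grid.lon_origin, "lat_origin": config.grid.lat_origin,
                 "cell_size": config.grid.cell_size}
    d["spi_baseline"] = list(config.spi_baseline)
    d["events"] = [{
        "rows": [ev.region[0].start, ev.region[0].stop],
        "cols": [ev.region[1].start, ev.region[1].stop],
        "start": [ev.start.year, ev.start.ordinal],
        "end": [ev.end.year, ev.end.ordinal],
        "multiplier": ev.multiplier, "soil_lag": ev.soil_lag, "veg_lag": ev.veg_lag,
    } for ev in events]
    return d


def config_from_dict(d: dict) -> tuple[SceneConfig, list[DroughtEvent]]:
    """Inverse of :func:`config_to_dict`."""
    d = dict(d)
    grid = GridSpec(**d.pop("grid"))
    raw_events = d.pop("events", [])
    d["spi_baseline"] = tuple(d.get("spi_baseline", (1981, 2010)))
    config = SceneConfig(grid=grid, **d)
    events = [DroughtEvent(
        region=(slice(*e["rows"]), slice(*e["cols"])),
        start=Dekad(*e["start"]), end=Dekad(*e["end"]),
        multiplier=e.get("multiplier", 0.2),
        soil_lag=e.get("soil_lag", 1), veg_lag=e.get("veg_lag", 3),
    ) for e in raw_events]
    return config, events


def generate_scene(config: SceneConfig = SceneConfig(),
                   events: Optional[list[DroughtEvent]] = None) -> SyntheticScene:
    """Generate the full input stack; bit-reproducible from the seed."""
    events = list(events or [])
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    nr, nc = grid.shape

    # ------------------------------------------------------------------
    # daily precipitation (zero-inflated gamma, seasonal)
    # ------------------------------------------------------------------
    p_dates = _dates(config.spi_baseline[0] - 1, config.end_year)
    doy = _doy(p_dates)
    season = _seasonal(doy, config.peak_doy)
    p_wet = np.clip(config.wet_prob_base + config.wet_prob_amplitude * season, 0.0, 0.98)
    scale = config.gamma_scale_mm * (1.0 + config.scale_amplitude * season)

    nd = len(p_dates)
    wet = rng.random((nd, nr, nc)) < p_wet[:, None, None]
    amount = rng.gamma(config.gamma_shape, 1.0, size=(nd, nr, nc)) * scale[:, None, None]
    base_precip = np.where(wet, amount, 0.0).astype(np.float32)

    precip_vals = _apply_events(base_precip, p_dates, grid, events, None)
    precip = DailyStack(grid, p_dates, precip_vals,
                        np.ones_like(precip_vals, dtype=bool), "precip")

    # expected trailing totals, for the deficit "ratio" drivers
    mu_daily = p_wet * config.gamma_shape * scale
    mu30 = _trailing_sum(mu_daily[:, None, None], 30)[:, 0, 0]
    mu90 = _trailing_sum(mu_daily[:, None, None], 90)[:, 0, 0]

    # ------------------------------------------------------------------
    # daily Soil Moisture Index (squashed trailing-30-day ratio)
    # ------------------------------------------------------------------
    smi_dates = _dates(config.smi_start, config.end_year)
    i0 = p_dates.index(smi_dates[0])
    soil_forcing = _apply_events(base_precip[i0 - 90:], p_dates[i0 - 90:], grid,
                                 events, "soil_lag")
    r30 = _trailing_sum(soil_forcing, 30)[90:]  # aligned to smi_dates
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio30 = r30 / mu30[i0:, None, None]
    eta = rng.normal(0.0, config.smi_noise_sd, size=ratio30.shape)
    logit = config.smi_gain * (ratio30 - 1.0) + eta
    smi_vals = (1.0 / (1.0 + np.exp(-logit))).astype(np.float32)
    smi = DailyStack(grid, smi_dates, smi_vals, np.isfinite(smi_vals), "smi")

    # ------------------------------------------------------------------
    # 8-day FAPAR composites (seasonal curve damped by 90-day deficit)
    # ------------------------------------------------------------------
    j0 = p_dates.index(_dt.date(config.fapar_start - 1, 1, 1))
    veg_forcing = _apply_events(base_precip[j0:], p_dates[j0:], grid, events, "veg_lag")
    r90 = _trailing_sum(veg_forcing, 90)
    veg_dates = p_dates[j0:]
    veg_index = {d: i for i, d in enumerate(veg_dates)}

    composites: list[Fapar8Day] = []
    for year in range(config.fapar_start, config.end_year + 1):
        for k in range(46):
            start = _dt.date(year, 1, 1) + _dt.timedelta(days=8 * k)
            if start.year != year:
                break
            mid = min(start + _dt.timedelta(days=4), _dt.date(year, 12, 31))
            doy_mid = mid.timetuple().tm_yday
            f_season = config.fapar_floor + (config.fapar_season_peak - config.fapar_floor) * \
                np.exp(-((doy_mid - config.fapar_peak_doy) / config.fapar_season_width) ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio90 = r90[veg_index[mid]] / mu90[j0 + veg_index[mid]]
            damage = np.clip(1.0 - ratio90, 0.0, 1.0)
            eps = rng.normal(0.0, config.fapar_noise_sd, size=(nr, nc))
            vals = np.clip(f_season * (1.0 - config.fapar_damage_gain * damage) + eps, 0.0, 1.0)
            flags = np.where(rng.random((nr, nc)) < config.fapar_reject_prob, 2, 0).astype(np.uint8)
            fld = RasterField(grid, vals, np.isfinite(vals), "fapar", start)
            composites.append(Fapar8Day(fld, start, flags))

    # ------------------------------------------------------------------
    # daily NDSI snow fields (evaluation years only)
    # ------------------------------------------------------------------
    n_dates = _dates(max(config.end_year - 1, config.fapar_start), config.end_year)
    lat = grid.lat_centers()
    lat_factor = np.clip((lat - config.snow_lat_min) /
                         max(config.snow_lat_full - config.snow_lat_min, 1e-9), 0.0, 1.0)
    ndsi_vals = np.zeros((len(n_dates), nr, nc), dtype=np.float32)
    # per-dekad noise keeps snow cover persistent within a dekad
    dekad_keys = [Dekad.from_date(d) for d in n_dates]
    noise_by_dekad: dict[Dekad, np.ndarray] = {}
    for t, (d, dk) in enumerate(zip(n_dates, dekad_keys)):
        if dk not in noise_by_dekad:
            noise_by_dekad[dk] = rng.normal(0.0, config.snow_noise_sd, size=(nr, nc))
        w = np.clip(_seasonal(np.array([float(d.timetuple().tm_yday)]),
                              config.snow_peak_doy)[0], 0.0, 1.0)
        score = lat_factor[:, None] * w + noise_by_dekad[dk]
        snow = score > config.snow_threshold
        ndsi_vals[t][snow] = 60.0 + 30.0 * lat_factor[:, None].repeat(nc, axis=1)[snow]
        uncertain = ~snow & (rng.random((nr, nc)) < config.uncertain_prob)
        ndsi_vals[t][uncertain] = 5.0
        cloud = rng.random((nr, nc)) < config.cloud_prob
        ndsi_vals[t][cloud] = CLOUD_CODE
    ndsi = DailyStack(grid, n_dates, ndsi_vals,
                      np.ones_like(ndsi_vals, dtype=bool), "ndsi")

    # ------------------------------------------------------------------
    # static crop layout: southern cropland, a wrap-season western strip,
    # a rangeland band, and a sub-threshold fraction strip
    # ------------------------------------------------------------------
    frac = np.zeros((nr, nc))
    south = slice(nr // 2, nr)
    frac[south, :] = config.crop_fraction_south
    frac[south, nc - 2:] = 0.5          # below the 1% threshold
    rangeland = np.zeros((nr, nc), dtype=bool)
    rangeland[south, nc - 4:nc - 2] = True
    sos = np.full((nr, nc), np.nan)
    eos = np.full((nr, nc), np.nan)
    sos[south, :] = config.sos_south
    eos[south, :] = config.eos_south
    winter_strip = (south, slice(0, max(nc // 8, 1)))
    sos[winter_strip] = config.sos_winter
    eos[winter_strip] = config.eos_winter
    phenology = PhenologyMaps(sos=sos, eos=eos)

    return SyntheticScene(config=config, events=events, precip=precip, smi=smi,
                          fapar=composites, ndsi=ndsi, crop_fraction=frac,
                          rangeland=rangeland, phenology=phenology)


# ----------------------------------------------------------------------
# golden fixtures: tiny frozen scenes for regression testing
# ----------------------------------------------------------------------

@dataclass
class GoldenFixture:
    """A tiny registered scene plus its frozen run summary."""

    name: str
    scene: SyntheticScene
    first: Dekad
    last: Dekad
    expected: dict


def _golden_configs() -> dict:
    short_baseline = dict(spi_baseline=(1999, 2018), smi_start=2003,
                          fapar_start=2012, end_year=2019)
    nordic = SceneConfig(
        grid=GridSpec(n_rows=10, n_cols=10, lon_origin=20.0, lat_origin=62.0),
        seed=101, **short_baseline)
    france = SceneConfig(
        grid=GridSpec(n_rows=10, n_cols=10, lon_origin=2.0, lat_origin=47.0),
        seed=202, eos_south=24, **short_baseline)
    allzero = SceneConfig(
        grid=GridSpec(n_rows=6, n_cols=6, lon_origin=5.0, lat_origin=50.0),
        seed=303, wet_prob_base=0.0, wet_prob_amplitude=0.0, **short_baseline)
    return {
        # full-winter snow cover at every latitude of the domain
        "nordic-snow": (nordic, []),
        # a precipitation deficit whose vegetation response outlives the
        # growing season (EOS at dekad 24)
        "france-offseason": (france, [DroughtEvent(
            region=(slice(5, 10), slice(0, 8)),
            start=Dekad(2019, 14), end=Dekad(2019, 22), multiplier=0.2)]),
        # never rains: degenerate climatologies, everything invalid
        "all-zero": (allzero, []),
    }


def golden_fixture(name: str) -> GoldenFixture:
    """A registered <=10x10, one-evaluation-year fixture.

    The frozen expected summaries live in the packaged
    ``golden_expectations.json`` and are compared by the regression
    tests; regenerate them with ``scripts/regenerate_golden.py`` after
    an intentional behavior change.
    """
    import json
    from importlib import resources

    configs = _golden_configs()
    if name not in configs:
        raise KeyError(f"unknown golden fixture {name!r}; known: {sorted(configs)}")
    config, events = configs[name]
    scene = generate_scene(config, events)
    try:
        text = resources.files("cdi.data").joinpath("golden_expectations.json").read_text()
        expected = json.loads(text).get(name, {})
    except FileNotFoundError:
        expected = {}
    year = config.end_year
    return GoldenFixture(name=name, scene=scene, first=Dekad(year, 1),
                         last=Dekad(year, 36), expected=expected)


def run_summary(maps: list[np.ndarray]) -> dict:
    """Class histogram of a run, for golden-fixture comparison."""
    from .classifier import MISSING, CdiClass

    stack = np.stack(maps)
    counts = {c.name.lower(): int((stack == np.uint8(c)).sum()) for c in CdiClass}
    counts["missing"] = int((stack == MISSING).sum())
    return counts
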