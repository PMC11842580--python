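"""End-to-end orchestration: inputs -> indicators -> masks -> CDI series.

This is the programmatic pipeline behind the command-line interface and
the acceptance runs: it fits the climatologies (gamma for SPI, mean/sd
for SMA and FAPAR), derives the dekadal indicator fields and masks for a
span of dekads, and advances the per-pixel state machine through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import anomalies, masks, spi
from .anomalies import Climatology, Fapar8Day
from .classifier import (MISSING, CdiClass, DecisionTable, IndicatorBundle,
                         Thresholds, load_decision_table, step,
                         transition_matrix)
from .dekads import Dekad, dekad_range
from .grid import RasterField
from .masks import SnowMask
from .synthetic import SyntheticScene


@dataclass
class PipelineParams:
    """Tunable knobs of a pipeline run (defaults = operational choices)."""

    version: int = 4
    thresholds: Thresholds = field(default_factory=Thresholds)
    spi_min_years: int = 20
    spi_min_positive: int = 10
    spi_fit_method: str = "thom"
    clim_min_years: int = 5
    smi_min_valid_days: int = 7
    fapar_accepted_flags: frozenset = anomalies.DEFAULT_ACCEPTED_FLAGS
    min_snow_days: int = 3
    init_class: CdiClass = CdiClass.NO_DROUGHT


@dataclass
class SceneClimatologies:
    spi1: spi.GammaClimatology
    spi3: spi.GammaClimatology
    sma: dict[int, Climatology]
    fapar: dict[int, Climatology]


@dataclass
class CdiRun:
    """Outputs of one classifier run over a span of dekads."""

    dekads: list[Dekad]
    maps: list[np.ndarray]
    bundles: list[IndicatorBundle]
    snow_masks: dict[Dekad, SnowMask]
    crop_masks: np.ndarray
    params: PipelineParams

    def transition_matrix(self) -> np.ndarray:
        return transition_matrix(self.maps)

    def class_fields(self) -> list[RasterField]:
        grid = self.bundles[0].grid
        return [RasterField(grid, m.astype(float), m != MISSING, "cdi", d)
                for d, m in zip(self.dekads, self.maps)]


def fit_climatologies(scene: SyntheticScene, params: PipelineParams = PipelineParams(),
                      *, ordinals: Optional[list[int]] = None) -> SceneClimatologies:
    """Fit all per-dekad climatologies from a scene's baseline records."""
    cfg = scene.config
    ords = list(ordinals) if ordinals is not None else list(range(1, 37))

    spi1 = spi.build_spi_climatology(scene.precip, 1, cfg.spi_baseline, ordinals=ords,
                                     min_years=params.spi_min_years,
                                     min_positive=params.spi_min_positive,
                                     method=params.spi_fit_method)
    spi3 = spi.build_spi_climatology(scene.precip, 3, cfg.spi_baseline, ordinals=ords,
                                     min_years=params.spi_min_years,
                                     min_positive=params.spi_min_positive,
                                     method=params.spi_fit_method)

    sma_clim: dict[int, Climatology] = {}
    for t in ords:
        fields = [anomalies.aggregate_smi_dekad(scene.smi, Dekad(y, t),
                                                min_valid_days=params.smi_min_valid_days)
                  for y in range(cfg.smi_start, cfg.end_year + 1)]
        sma_clim[t] = anomalies.build_climatology(fields, min_years=params.clim_min_years)

    filtered = [anomalies.qc_filter_fapar(c, params.fapar_accepted_flags)
                for c in scene.fapar]
    by_year: dict[int, list[Fapar8Day]] = {}
    for c in filtered:
        by_year.setdefault(c.start.year, []).append(c)
    fapar_clim: dict[int, Climatology] = {}
    for t in ords:
        fields = [anomalies.composite_fapar_dekad(by_year[y], Dekad(y, t))
                  for y in sorted(by_year)]
        fapar_clim[t] = anomalies.build_climatology(fields, min_years=params.clim_min_years)

    return SceneClimatologies(spi1=spi1, spi3=spi3, sma=sma_clim, fapar=fapar_clim)


def snow_mask_series(scene: SyntheticScene, through: Dekad,
                     params: PipelineParams = PipelineParams()) -> dict[Dekad, SnowMask]:
    """Chained dekadal snow masks from the first NDSI dekad through ``through``."""
    first = Dekad.from_date(scene.ndsi.dates[0])
    if scene.ndsi.dates[0] != first.start_date:
        first = first.next()
    out: dict[Dekad, SnowMask] = {}
    prev: Optional[SnowMask] = None
    for dk in dekad_range(first, through):
        days = [masks.classify_ndsi(scene.ndsi.data[scene.ndsi.index_of(d)])
                for d in dk.days()]
        prev = masks.composite_snow_dekad(days, scene.grid, dk, prev,
                                          min_snow_days=params.min_snow_days)
        out[dk] = prev
    return out


def indicator_bundle(scene: SyntheticScene, clim: SceneClimatologies, dekad: Dekad,
                     snow: Optional[SnowMask], crop_layer: Optional[np.ndarray],
                     params: PipelineParams = PipelineParams()) -> IndicatorBundle:
    """All four indicator fields plus masks for one dekad."""
    spi1 = spi.spi_field(scene.precip, 1, dekad, clim.spi1)
    spi3 = spi.spi_field(scene.precip, 3, dekad, clim.spi3)
    smi_dek = anomalies.aggregate_smi_dekad(scene.smi, dekad,
                                            min_valid_days=params.smi_min_valid_days)
    sma = anomalies.standardize(smi_dek, clim.sma[dekad.ordinal], variable="sma")
    comps = [c for c in scene.fapar if c.start.year == dekad.year]
    comps = [anomalies.qc_filter_fapar(c, params.fapar_accepted_flags) for c in comps]
    fap = anomalies.composite_fapar_dekad(comps, dekad)
    fapar_anom = anomalies.standardize(fap, clim.fapar[dekad.ordinal],
                                       variable="fapar_anomaly")
    return IndicatorBundle(spi1=spi1, spi3=spi3, sma=sma, fapar=fapar_anom,
                           snow=snow, crop=crop_layer, dekad=dekad)


def run_cdi(scene: SyntheticScene, first: Dekad, last: Dekad,
            params: PipelineParams = PipelineParams(),
            table: Optional[DecisionTable] = None,
            clim: Optional[SceneClimatologies] = None) -> CdiRun:
    """Classify every dekad in [first, last], chaining the previous-class map."""
    if table is None:
        table = load_decision_table()
    dekads = dekad_range(first, last)
    if clim is None:
        clim = fit_climatologies(scene, params,
                                 ordinals=sorted({d.ordinal for d in dekads}))
    crop = masks.build_crop_mask(scene.crop_fraction, scene.rangeland, scene.phenology)
    snow = snow_mask_series(scene, last, params) if params.version >= 4 else {}

    prev = np.full(scene.grid.shape, np.uint8(params.init_class), dtype=np.uint8)
    maps: list[np.ndarray] = []
    bundles: list[IndicatorBundle] = []
    for dk in dekads:
        bundle = indicator_bundle(scene, clim, dk, snow.get(dk),
                                  crop[dk.ordinal - 1], params)
        new = step(prev, bundle, table, version=params.version,
                   thresholds=params.thresholds)
        maps.append(new)
        bundles.append(bundle)
        # MISSING pixels keep their previous state for the next step
        prev = np.where(new == MISSING, prev, new)
    return CdiRun(dekads=dekads, maps=maps, bundles=bundles, snow_masks=snow,
                  crop_masks=crop, params=params)


#: the five drought stages, in canonical propagation order
STAGES = ("none", "watch", "warning", "alert", "recovery")

_STAGE_OF_CLASS = {
    int(CdiClass.NO_DROUGHT): 0, int(CdiClass.WATCH): 1, int(CdiClass.WARNING): 2,
    int(CdiClass.ALERT): 3, int(CdiClass.RECOVERY): 4,
    int(CdiClass.TEMP_SM_RECOVERY): 4, int(CdiClass.TEMP_VEG_RECOVERY): 4,
}


def stage_counts(run: CdiRun, region: np.ndarray) -> np.ndarray:
    """Per-dekad pixel counts of the five drought stages over ``region``.

    Stages collapse the three recovery classes into one; MISSING pixels
    are excluded.  Shape (n_dekads, 5), ordered as :data:`STAGES`.
    """
    region = np.asarray(region, dtype=bool)
    out = np.zeros((len(run.maps), len(STAGES)), dtype=np.int64)
    for i, m in enumerate(run.maps):
        vals = m[region]
        vals = vals[vals != MISSING]
        for cls, stage in _STAGE_OF_CLASS.items():
            out[i, stage] += int((vals == cls).sum())
    return out


def stage_progression_ordered(run: CdiRun, region: np.ndarray) -> bool:
    """True when the drought stages peak in the canonical order.

    An injected drought should raise Watch, then Warning, then Alert,
    then the recovery classes, with the region back to no-drought at the
    end; because the recovery classes are one-dekad transition states,
    the check compares the dekad of each stage's occurrence *peak*
    rather than requiring every stage to dominate the regional mode.
    """
    counts = stage_counts(run, region)
    peaks = counts.argmax(axis=0)  # first dekad index of each stage's maximum
    ordered = peaks[1] < peaks[2] < peaks[3] < peaks[4]
    starts_and_ends_quiet = (counts[0].argmax() == 0) and (counts[-1].argmax() == 0)
    return bool(ordered and starts_and_ends_quiet)


def modal_trajectory(run: CdiRun, region: np.ndarray) -> list[int]:
    """Most frequent class over ``region`` per dekad, duplicates collapsed."""
    region = np.asarray(region, dtype=bool)
    seq: list[int] = []
    for m in run.maps:
        vals = m[region]
        vals = vals[vals != MISSING]
        if vals.size == 0:
            continue
        mode = int(np.bincount(vals, minlength=7).argmax())
        if not seq or seq[-1] != mode:
            seq.append(mode)
    return seq
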