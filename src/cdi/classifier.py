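"""The CDI per-pixel state machine.

Each dekad, every pixel is assigned one of seven classes by combining
(1) the exceedance state of the three anomaly indicators — SPI (both
scales), SMA and FAPAR anomaly — at time T with (2) the class the same
pixel held at T-1.  The mapping is an explicit 8-column x 7-row decision
table (columns = the 2^3 flag combinations, rows = previous class),
refined by three sub-condition predicates: a wet-precipitation escape
for the soil-moisture-only column, and partial-recovery bands
(anomaly in (-0.5, 0]) for soil moisture and vegetation.

Drought develops hierarchically — precipitation deficit (Watch), then
soil-moisture deficit (Warning), then vegetation stress (Alert) — and a
pixel can only leave the drought classes through the recovery classes,
never jumping straight back to no-drought.

Mask reductions implement the version history: version 3 adds static
crop masks (no vegetation flag over cropland out of the growing
season, leaving columns A/B/C/F reachable), version 4 adds dynamic snow
masks (no soil-moisture or vegetation flags under snow, leaving columns
A/B).  Version 2 applies no reduction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .dekads import Dekad
from .grid import RasterField
from .masks import CROP_OUT_OF_SEASON, SnowMask


class CdiClass(IntEnum):
    NO_DROUGHT = 0
    WATCH = 1
    WARNING = 2
    ALERT = 3
    RECOVERY = 4
    TEMP_SM_RECOVERY = 5
    TEMP_VEG_RECOVERY = 6


#: out-of-band nodata code; never a class
MISSING = np.uint8(255)

DROUGHT_CLASSES = (CdiClass.WATCH, CdiClass.WARNING, CdiClass.ALERT)
RECOVERY_CLASSES = (CdiClass.RECOVERY, CdiClass.TEMP_SM_RECOVERY, CdiClass.TEMP_VEG_RECOVERY)

#: GeoTIFF/netCDF palette: warm colors mark increasing drought severity
CLASS_COLORS = {
    CdiClass.NO_DROUGHT: (255, 255, 255),
    CdiClass.WATCH: (255, 235, 80),       # yellow
    CdiClass.WARNING: (255, 160, 40),     # orange
    CdiClass.ALERT: (215, 25, 28),        # red
    CdiClass.RECOVERY: (130, 200, 120),
    CdiClass.TEMP_SM_RECOVERY: (170, 220, 230),
    CdiClass.TEMP_VEG_RECOVERY: (190, 230, 160),
}

COLUMNS = "ABCDEFGH"
#: column letter -> (spi_flag, sma_flag, fapar_flag)
COLUMN_FLAGS = {
    "A": (0, 0, 0), "B": (1, 0, 0), "C": (0, 1, 0), "D": (0, 0, 1),
    "E": (0, 1, 1), "F": (1, 1, 0), "G": (1, 0, 1), "H": (1, 1, 1),
}
FLAGS_COLUMN = {v: k for k, v in COLUMN_FLAGS.items()}

PREDICATES = ("wet_spi", "sma_partial", "fapar_partial")


@dataclass(frozen=True)
class Thresholds:
    """Reference thresholds of the decision framework (z-score units)."""

    spi1_extreme: float = -2.0
    spi3_moderate: float = -1.0
    sma: float = -1.0
    fapar: float = -1.0
    wet_spi1: float = 0.5
    wet_spi3: float = 0.0
    partial_low: float = -0.5   # exclusive
    partial_high: float = 0.0   # inclusive

    def __post_init__(self) -> None:
        if not self.spi1_extreme < self.spi3_moderate < 0:
            raise ValueError("SPI thresholds must satisfy extreme < moderate < 0")


@dataclass
class Flags:
    """Vectorized exceedance flags and sub-condition predicates."""

    spi: np.ndarray
    sma: np.ndarray
    fapar: np.ndarray
    wet_spi: np.ndarray
    sma_partial: np.ndarray
    fapar_partial: np.ndarray
    valid: np.ndarray

    def column_index(self) -> np.ndarray:
        """Per-pixel column as 0..7 indexing into ``COLUMNS``."""
        code = (self.spi.astype(int), self.sma.astype(int), self.fapar.astype(int))
        idx = np.zeros(self.spi.shape, dtype=np.int8)
        for letter, combo in COLUMN_FLAGS.items():
            sel = (code[0] == combo[0]) & (code[1] == combo[1]) & (code[2] == combo[2])
            idx[sel] = COLUMNS.index(letter)
        return idx

    def predicate(self, name: str) -> np.ndarray:
        if name not in PREDICATES:
            raise KeyError(f"unknown predicate {name!r}")
        return getattr(self, name)


@dataclass
class IndicatorBundle:
    """All classifier inputs for one dekad, on one grid."""

    spi1: RasterField
    spi3: RasterField
    sma: RasterField
    fapar: RasterField
    snow: Optional[SnowMask] = None
    crop: Optional[np.ndarray] = None  # ternary crop-season layer for this dekad
    dekad: Optional[Dekad] = None

    def __post_init__(self) -> None:
        grid = self.spi1.grid
        for f in (self.spi3, self.sma, self.fapar):
            if f.grid != grid:
                raise ValueError("indicator fields are on different grids")
        if self.dekad is None and isinstance(self.spi1.time, Dekad):
            self.dekad = self.spi1.time

    @property
    def grid(self):
        return self.spi1.grid


def compute_flags(bundle: IndicatorBundle, thr: Thresholds = Thresholds()) -> Flags:
    """Exceedance flags and sub-condition predicates for every pixel.

    SPI comparisons are strict (<); SMA/FAPAR use <=.  Pixels with
    invalid SPI are marked invalid (the pixel will be MISSING); invalid
    SMA or FAPAR behaves as masked — its flags are simply false.
    """
    spi1, spi3 = bundle.spi1, bundle.spi3
    sma, fapar = bundle.sma, bundle.fapar

    spi_valid = spi1.valid & spi3.valid
    s1 = np.where(spi1.valid, spi1.values, 0.0)
    s3 = np.where(spi3.valid, spi3.values, 0.0)
    sm = np.where(sma.valid, sma.values, 0.0)
    fp = np.where(fapar.valid, fapar.values, 0.0)

    spi_flag = spi_valid & ((s1 < thr.spi1_extreme) | (s3 < thr.spi3_moderate))
    wet_spi = spi_valid & (s1 > thr.wet_spi1) & (s3 > thr.wet_spi3)
    sma_flag = sma.valid & (sm <= thr.sma)
    fapar_flag = fapar.valid & (fp <= thr.fapar)
    sma_partial = sma.valid & (sm > thr.partial_low) & (sm <= thr.partial_high)
    fapar_partial = fapar.valid & (fp > thr.partial_low) & (fp <= thr.partial_high)

    return Flags(spi=spi_flag, sma=sma_flag, fapar=fapar_flag, wet_spi=wet_spi,
                 sma_partial=sma_partial, fapar_partial=fapar_partial, valid=spi_valid)


def apply_mask_reduction(flags: Flags, snow: Optional[np.ndarray],
                         crop_state: Optional[np.ndarray], version: int) -> Flags:
    """Reduce the reachable columns under snow (v>=4) and out-of-season
    crop (v>=3) masks; version 2 is the identity."""
    if version not in (2, 3, 4):
        raise ValueError(f"version must be 2, 3 or 4, got {version}")
    sma_flag = flags.sma.copy()
    fapar_flag = flags.fapar.copy()
    sma_partial = flags.sma_partial.copy()
    fapar_partial = flags.fapar_partial.copy()
    if version >= 3 and crop_state is not None:
        off = np.asarray(crop_state) == CROP_OUT_OF_SEASON
        fapar_flag[off] = False
        fapar_partial[off] = False
    if version >= 4 and snow is not None:
        s = np.asarray(snow, dtype=bool)
        sma_flag[s] = False
        fapar_flag[s] = False
        sma_partial[s] = False
        fapar_partial[s] = False
    return Flags(spi=flags.spi, sma=sma_flag, fapar=fapar_flag, wet_spi=flags.wet_spi,
                 sma_partial=sma_partial, fapar_partial=fapar_partial, valid=flags.valid)


# ----------------------------------------------------------------------
# decision table
# ----------------------------------------------------------------------

_CLASS_BY_NAME = {c.name.lower(): c for c in CdiClass}


@dataclass
class Rule:
    predicate: Optional[str]  # None = default
    outcome: CdiClass


@dataclass
class DecisionTable:
    """Total mapping (column, previous class, sub-conditions) -> class."""

    cells: dict[tuple[str, CdiClass], list[Rule]]
    source: str = ""

    def lookup(self, column: str, prev: CdiClass, predicates: dict[str, bool]) -> CdiClass:
        for rule in self.cells[(column, CdiClass(prev))]:
            if rule.predicate is None or predicates.get(rule.predicate, False):
                return rule.outcome
        raise LookupError(f"no default rule in cell ({column}, {prev})")

    def outcomes(self, column: str, prev: CdiClass) -> set[CdiClass]:
        """All classes reachable from one cell over every predicate outcome."""
        out = set()
        for rule in self.cells[(column, CdiClass(prev))]:
            out.add(rule.outcome)
            if rule.predicate is None:
                break
        return out


def _parse_cell(raw) -> list[Rule]:
    if isinstance(raw, str):
        return [Rule(None, _CLASS_BY_NAME[raw])]
    rules: list[Rule] = []
    for entry in raw:
        if "default" in entry:
            rules.append(Rule(None, _CLASS_BY_NAME[entry["default"]]))
        else:
            rules.append(Rule(entry["if"], _CLASS_BY_NAME[entry["then"]]))
    return rules


def load_decision_table(path: Optional[str] = None) -> DecisionTable:
    """Load the bundled decision table, or a user override from ``path``."""
    if path is None:
        text = resources.files("cdi.data").joinpath("decision_table.yaml").read_text()
        source = "bundled"
    else:
        with open(path) as fh:
            text = fh.read()
        source = str(path)
    doc = yaml.safe_load(text)
    cells: dict[tuple[str, CdiClass], list[Rule]] = {}
    for letter in COLUMNS:
        raw = doc["columns"][letter]
        if isinstance(raw, str):
            for prev in CdiClass:
                cells[(letter, prev)] = [Rule(None, _CLASS_BY_NAME[raw])]
        else:
            for prev in CdiClass:
                cells[(letter, prev)] = _parse_cell(raw[prev.name.lower()])
    return DecisionTable(cells=cells, source=source)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_table(table: DecisionTable) -> ValidationReport:
    """Structural audit of a decision table.

    Checks: totality over 8 columns x 7 rows; every outcome one of the
    seven classes; columns E/G/H map every previous class to ALERT;
    column B always yields WATCH; no cell ever maps a drought class
    (WATCH/WARNING/ALERT) to NO_DROUGHT; column C implements the
    wet-precipitation escape for NO_DROUGHT/RECOVERY and WARNING
    otherwise.
    """
    rep = ValidationReport()
    for letter in COLUMNS:
        for prev in CdiClass:
            cell = table.cells.get((letter, prev))
            if not cell:
                rep.violations.append(f"({letter}, {prev.name}): missing cell")
                continue
            if cell[-1].predicate is not None:
                rep.violations.append(f"({letter}, {prev.name}): no default rule")
            for rule in cell:
                if not isinstance(rule.outcome, CdiClass):
                    rep.violations.append(f"({letter}, {prev.name}): outcome not a class")
            outs = table.outcomes(letter, prev)
            if letter in "EGH" and outs != {CdiClass.ALERT}:
                rep.violations.append(f"({letter}, {prev.name}): must map to ALERT, got {outs}")
            if letter == "B" and outs != {CdiClass.WATCH}:
                rep.violations.append(f"({letter}, {prev.name}): must map to WATCH, got {outs}")
            if prev in DROUGHT_CLASSES and CdiClass.NO_DROUGHT in outs:
                rep.violations.append(
                    f"({letter}, {prev.name}): direct drought -> NO_DROUGHT transition")
    # column C wet-precipitation escape
    for prev in (CdiClass.NO_DROUGHT, CdiClass.RECOVERY):
        if table.lookup("C", prev, {"wet_spi": True}) != CdiClass.NO_DROUGHT:
            rep.violations.append(f"(C, {prev.name}): wet-SPI escape must yield NO_DROUGHT")
        if table.lookup("C", prev, {"wet_spi": False}) != CdiClass.WARNING:
            rep.violations.append(f"(C, {prev.name}): without wet SPI must yield WARNING")
    return rep


def classify_pixel(column: str, prev: CdiClass, predicates: dict[str, bool],
                   table: DecisionTable) -> CdiClass:
    """Single-cell lookup; pure function of its arguments."""
    return table.lookup(column, prev, predicates)


def step(prev_map: np.ndarray, bundle: IndicatorBundle, table: DecisionTable,
         *, version: int = 4, thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Advance the classifier one dekad.

    ``prev_map`` holds class codes (uint8, 255 = MISSING).  Pixels whose
    SPI inputs are invalid come out MISSING; a MISSING previous class is
    treated as NO_DROUGHT (cold start).
    """
    prev_map = np.asarray(prev_map)
    if prev_map.shape != bundle.grid.shape:
        raise ValueError("previous class map does not match the bundle grid")
    flags = compute_flags(bundle, thresholds)
    snow = bundle.snow.snow if bundle.snow is not None else None
    flags = apply_mask_reduction(flags, snow, bundle.crop, version)

    col_idx = flags.column_index()
    prev = np.where(prev_map == MISSING, np.uint8(CdiClass.NO_DROUGHT), prev_map)
    out = np.full(prev_map.shape, MISSING, dtype=np.uint8)
    preds = {name: flags.predicate(name) for name in PREDICATES}
    for ci, letter in enumerate(COLUMNS):
        for pc in CdiClass:
            sel = (col_idx == ci) & (prev == np.uint8(pc)) & flags.valid
            if not sel.any():
                continue
            remaining = sel.copy()
            for rule in table.cells[(letter, pc)]:
                if rule.predicate is None:
                    out[remaining] = np.uint8(rule.outcome)
                    break
                hit = remaining & preds[rule.predicate]
                out[hit] = np.uint8(rule.outcome)
                remaining &= ~hit
    return out


def transition_matrix(maps: list[np.ndarray]) -> np.ndarray:
    """7x7 counts of class transitions over consecutive dekad pairs.

    Entry (i, j) counts pixels going from class i at T-1 to class j at T;
    MISSING pixels are ignored.  This is the data behind the alluvial
    plots used to audit transition legality.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    counts = np.zeros((7, 7), dtype=np.int64)
    for a, b in zip(maps[:-1], maps[1:]):
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("maps in the series have different shapes")
        ok = (a != MISSING) & (b != MISSING)
        np.add.at(counts, (a[ok].astype(int), b[ok].astype(int)), 1)
    return counts


def forbidden_transition_count(counts: np.ndarray) -> int:
    """Number of observed direct drought -> NO_DROUGHT transitions."""
    return int(sum(counts[int(c), int(CdiClass.NO_DROUGHT)] for c in DROUGHT_CLASSES))
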