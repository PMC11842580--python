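# Methods

This note documents the model implemented by the package, the numerical
choices, the synthetic-data generator, and the design decisions taken
where the framework leaves room. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Temporal and spatial frame

The temporal unit is the **dekad**: each month splits into days 1–10,
11–20, and 21 to month end, giving exactly 36 dekads per year with day
counts in {8, 9, 10, 11}. Dekads are numbered
`ordinal = 3·(month − 1) + dekad_of_month`, so file names and netCDF
time axes are unambiguous. All rasters share a regular geographic grid
(EPSG:4326), cell-center registered, north-up, with half-open cell
intervals `[edge, edge + size)`; the default cell size is 1/24°
(~5 km). The production-scale European grid is *not* hard-coded —
`GridSpec` is user-supplied and tests use small grids.

## 2. Indicators

### SPI-1 / SPI-3

Accumulated precipitation over a window ending at the terminal dekad's
last day is modelled per pixel and dekad-of-year as a zero-inflated
gamma: `H(x) = q + (1 − q)·G(x; k, θ)`, with `q` the fraction of zero
totals in the baseline. The SPI is `Φ⁻¹(H(x))`; exact-zero totals map
through `Φ⁻¹(q/2)` (center of the zero mass, avoiding the bias of
mapping them to the full mass `q`). Choices:

* **Accumulation**: a rolling window of exactly 30 (SPI-1) or 90
  (SPI-3) days ending at the terminal dekad's last day. The alternative
  "calendar months" convention exists in the literature; the rolling
  window is used here because it gives every dekad its own terminal
  total instead of repeating one monthly value three times.
* **Fitting**: the closed-form maximum-likelihood approximation of Thom
  (`A = ln x̄ − ln x‾; k = (1 + √(1 + 4A/3)) / 4A; θ = x̄/k`), fully
  vectorized; a unit test checks it agrees with exact scipy MLE to
  within 5 % on gamma samples, and exact per-pixel MLE (with a
  method-of-moments fallback on non-convergence) is selectable via
  `method="mle"`. `A` is floored at 1e−8 to keep near-constant samples
  finite.
* **Validity**: a pixel/dekad fit requires ≥ 20 baseline years and ≥ 10
  strictly positive totals, and `q < 1`; otherwise the pixel is invalid
  and the classifier marks it MISSING.
* **Clamping**: |SPI| is capped at 3.5 to keep extreme tails finite;
  fitted probabilities are clipped to `(1e−12, 1 − 1e−12)` before the
  normal quantile.
* **Baseline**: 30 years (default 1981–2010), a deliberate fixed
  reference period rather than "all available data".

### Soil Moisture Anomaly (SMA)

The dekadal Soil Moisture Index is the arithmetic mean of the N daily
SMI fields (`I = Σ SMI / N`); a pixel needs at least 7 valid days
(or N, if the dekad is shorter) — the framework does not state a
minimum, 7 of 10 keeps one cloudy/missing triple harmless. The anomaly
is the plain z-score `Z = (I − μ)/σ` against the per-pixel, per-dekad
mean and **sample** standard deviation (n − 1) over the baseline
(1995-onward by default). Pixels with fewer than 5 baseline years or
σ ≤ 1e−6 are invalid; the σ floor guards division blow-up on
near-constant baselines.

### FAPAR anomaly

8-day composites are first QC-masked (accepted flag set is
configurable; the default accepts {0, 1}, i.e. good and usable
retrievals — the exact operational flag semantics are product-specific).
Each dekad then takes the **two temporally closest** composites (the
minimum that can bracket a 10-day window; configurable to k nearest),
blended with weights ∝ `1/(d + 0.5)` where `d` is the distance in days
between the composite midpoint (start + 4 days in a 8-day period) and
the dekad midpoint; the half-day ε avoids division by zero when a
composite is exactly centered while preserving the distance ordering.
Weights renormalize per pixel over valid inputs. Where the source grid
is finer than the target, bilinear resampling (mask-aware: invalid
corners drop out and the remaining weights renormalize) runs *before*
standardization, so the climatology is built on the classification
grid. Standardization is then identical to the SMA (baseline
2012-onward).

## 3. Masks

### Snow

Daily NDSI (0–100 plus special codes) maps to a ternary state: 0 →
no-snow, 1–10 → **no-snow** (values discarded as uncertain, mirroring
the rule of the 8-day snow product this follows; configurable to
missing), > 10 → snow, cloud/fill codes → missing. A dekad pixel is
snow iff snow was observed on **≥ 3 days** — kept as an absolute count
for the 8/9/11-day dekads, with a proportional mode (≥ ⌈0.3·N⌉)
available. Partially cloudy pixels still count their observed snow days
against the threshold; only a pixel with *zero* observations in the
dekad inherits the previous dekad's value, and a pixel missing in the
very first dekad ever produced defaults to snow-free. Modal resampling
to the coarse grid has each fine cell vote in the target cell
containing its center; exact ties break **toward snow** — conservative,
since the mask only suppresses unreliable soil-moisture anomalies.

### Crop / growing season

A pixel is cropland iff its crop fraction is ≥ 1 % and it is not
rangeland; the threshold applies to the fraction raster on the
classification grid (aggregate first, then threshold). The growing
season is the inclusive circular dekad interval [SOS, EOS], wrapping
the year boundary for winter crops. The result is 36 static ternary
maps (non-crop / crop out of season / crop in season), identical for
every year. Crop pixels without phenology are demoted to non-crop with
a warning.

## 4. The classifier

Per pixel and dekad, three exceedance flags are computed —
`spi = (SPI-1 < −2) OR (SPI-3 < −1)`, `sma = (SMA ≤ −1)`,
`fapar = (FAPAR ≤ −1)` — plus three sub-condition predicates: the
wet-precipitation escape `(SPI-1 > 0.5) AND (SPI-3 > 0)` and the
partial-recovery bands `value ∈ (−0.5, 0]` for SMA and FAPAR. SPI
comparisons are strict `<` (per the printed column headings), SMA/FAPAR
use `≤`; the boundaries are unit-tested.

The flag triple selects one of eight columns (A = no exceedance …
H = all three); the column, the previous class and the predicates enter
an explicit decision table bundled as YAML and treated as data, so a
transcription fix is a configuration change, not code. Structural
constraints are enforced by `validate_table`: totality over 8×7 cells,
outputs among the seven classes, E/G/H → Alert for every previous
class, B → Watch, and **no direct drought → No-drought transition**.

Cells not pinned down by the framework's stated constraints were
completed as follows:

* **Column A** (all normal): Watch → Recovery; Warning →
  Temporary SM Recovery if SMA is in the partial band, else Recovery;
  Alert → Temporary Vegetation Recovery if FAPAR is in the partial
  band, else Recovery; Recovery → No drought; the temporary classes
  persist while their anomaly stays in the partial band and otherwise
  resolve to No drought. Sending Warning/Alert to Recovery (rather than
  persisting them) when their driving anomaly has risen *above* the
  exceedance threshold is required for consistency with the snow
  reduction: under snow only columns A/B are reachable and Warning and
  Alert must disappear, which they could not do if column A persisted
  them.
* **Column C** (soil-moisture deficit only): No drought/Recovery escape
  to No drought under the wet-SPI condition, everything else → Warning.
* **Column D** (vegetation deficit only, e.g. pests or hail rather than
  drought): persists the previous class — the framework's running text
  does not constrain it, and persistence is the neutral choice
  consistent with "transitions are always modulated through recovery
  classes".
* **Column F** (precipitation + soil-moisture deficit) → Warning
  everywhere, matching the propagation hierarchy.

Version switching is strictly mask-local: v ≥ 3 clears the FAPAR flag
and partial band on out-of-season cropland (columns A/B/C/F remain);
v ≥ 4 additionally clears both SMA and FAPAR flags and bands under snow
(columns A/B remain); v2 applies no reduction. A property test checks
v2/v3/v4 agree exactly outside masked pixels.

Missing inputs: invalid SPI makes the pixel MISSING (encoded out of
band as 255, never an eighth class; MISSING pixels keep their previous
state for the next step); invalid SMA or FAPAR behaves as masked (flags
false), matching the mask-reduction semantics. The first dekad of a run
has no predecessor: all pixels start at No drought, and at least 3
dekads of spin-up are recommended before interpreting maps.

## 5. The synthetic scene generator

The generator emulates every input the pipeline consumes, from a single
seed:

* **Precipitation**: zero-inflated gamma per day and pixel; wet-day
  probability 0.45 ± 0.15 and intensity scale 6 mm ± 30 % follow a
  cosine seasonal cycle peaking mid-January (a wet-winter climate).
* **Soil moisture**: `SMI = logistic(2.5·(R₃₀/R̄₃₀ − 1) + η)`, where
  R₃₀ is the trailing 30-day precipitation total, R̄₃₀ its seasonal
  expectation and η daily N(0, 0.25) noise — the simplest mechanism
  that yields a realistic precipitation → soil-moisture lag. The
  hydrological model behind the operational soil-moisture record is
  deliberately not reimplemented.
* **FAPAR**: a seasonal growth curve (floor 0.12, summer peak 0.55)
  damped by the trailing 90-day precipitation deficit, plus N(0, 0.04)
  noise; 8-day composites restart each January 1st; 5 % of pixels per
  composite carry a rejected QC flag.
* **NDSI**: winter snow above a latitude ramp, persistent within a
  dekad, with 10 % cloud cover and 3 % "uncertain" (1–10) values.
* **Crops**: the southern half is 60 % cropland (season dekads 10–27)
  with a winter-crop strip (31 → 12, wrapping), a rangeland band and a
  0.5 % sub-threshold strip.
* **Events**: a `DroughtEvent` multiplies precipitation by `m ∈ [0, 1)`
  over a region and dekad window; the deficit enters the soil-moisture
  driver `soil_lag` dekads later and the vegetation driver `veg_lag`
  dekads later. Defaults are soil_lag = 2 dekads (~20 days — soil
  responds fast to dryness) and veg_lag = 5 dekads (~50 days —
  vegetation stress develops over one to two months).

Default year ranges mirror the operational records: precipitation from
1980 (one year before the 1981–2010 SPI baseline, for the 90-day
window), soil moisture from 1995, FAPAR from 2012, NDSI over the last
two years.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: pixels are statistically independent
(no spatial correlation of weather), there is no orography, land-sea
contrast or reanalysis bias, the soil response is a one-parameter
squash rather than a water-balance model, and FAPAR stress has no
memory beyond the 90-day window. The tests demonstrate that the
*algorithmic chain* is correct, not that the indicators are skilful on
any real landscape.

One consequence of z-scored indicators is worth stating: for a baseline
member, `P(Z ≤ −1) ≈ 0.16` by construction, so even an event-free
scene shows single-indicator exceedances — and therefore Warning
pixels — at roughly that climatological rate. The calibration test
accordingly checks that No drought is the modal class and that
Warning + Alert stay below 35 % of pixel-dekads, not that drought
classes vanish.

## 6. Trajectory auditing

Two complementary audits check the staged drought response:

* **Transition legality**: the 7×7 transition-count matrix (the data
  behind alluvial plots) of every run must contain zero direct
  drought → No-drought transitions. This is exact and per pixel.
* **Stage ordering**: over an injected event region, Watch, Warning,
  Alert and the recovery classes must *peak* in that order, starting
  and ending at No drought. The peak formulation is used because the
  recovery classes are one-dekad transition states: pixels recover
  asynchronously over a few dekads, so the region's modal class can
  step from Alert to No drought even though every single pixel passes
  through a recovery class (which the legality audit proves). Order is
  checked, not timing.

## 7. Problem sizes

Test scenes use 12×12 (event propagation) and 8×8 (baseline statistics)
grids with the full 30-year SPI baseline; the acceptance script runs
the end-to-end drought on the default 40×40 grid, 10,000-pixel random
trajectories for the legality audit, and n = 200 samples for gamma
recovery. These sizes were chosen so the whole suite completes in well
under a minute while keeping every statistical check comfortably
powered; all scale linearly in pixels if enlarged.

## 8. Known limitations

* The netCDF writer uses the classic (netCDF-3) format via the scipy
  backend: CF attributes and coordinates are written, but no HDF5
  compression or groups.
* GeoTIFF support covers single-band north-up EPSG:4326 rasters with
  the standard geo tags; rotated or projected grids are rejected.
* Ingestion of native sinusoidal-projection tile archives (HDF-EOS5)
  and tile mosaicking are out of scope; the pipeline consumes
  already-geographic rasters.
* The decision-table cells listed in §4 beyond the framework's stated
  constraints are this package's completion; the table file is data
  precisely so an authoritative transcription can replace it without a
  code change.
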