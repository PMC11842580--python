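import itertools

import numpy as np
import pytest

from cdi import classifier as clf
from cdi.classifier import (MISSING, CdiClass, IndicatorBundle, Thresholds,
                            apply_mask_reduction, compute_flags, load_decision_table,
                            step, transition_matrix, validate_table)
from cdi.dekads import Dekad
from cdi.grid import GridSpec, RasterField
from cdi.masks import (CROP_IN_SEASON, CROP_OUT_OF_SEASON, NON_CROP, SnowMask)


def make_bundle(grid, spi1=0.0, spi3=0.0, sma=0.5, fapar=0.5, snow=None, crop=None,
                valid=True):
    def field(v, name):
        vals = np.full(grid.shape, float(v))
        return RasterField(grid, vals, np.full(grid.shape, valid), name, Dekad(2020, 19))

    snow_mask = None
    if snow is not None:
        snow_mask = SnowMask(grid, np.full(grid.shape, bool(snow)), Dekad(2020, 19))
    crop_arr = None if crop is None else np.full(grid.shape, crop, dtype=np.uint8)
    return IndicatorBundle(spi1=field(spi1, "spi1"), spi3=field(spi3, "spi3"),
                           sma=field(sma, "sma"), fapar=field(fapar, "fapar"),
                           snow=snow_mask, crop=crop_arr)


def column_of(bundle, version=2):
    flags = compute_flags(bundle)
    snow = bundle.snow.snow if bundle.snow is not None else None
    flags = apply_mask_reduction(flags, snow, bundle.crop, version)
    return clf.COLUMNS[flags.column_index()[0, 0]]


class TestFlags:
    def test_spi_only_deficit_is_column_b(self, small_grid):
        assert column_of(make_bundle(small_grid, spi1=-2.5)) == "B"

    def test_sma_and_fapar_deficit_is_column_e(self, small_grid):
        assert column_of(make_bundle(small_grid, sma=-1.2, fapar=-1.3)) == "E"

    def test_all_normal_is_column_a_with_partials_at_zero(self, small_grid):
        b = make_bundle(small_grid, spi1=0.0, spi3=0.0, sma=0.0, fapar=0.0)
        flags = compute_flags(b)
        assert column_of(b) == "A"
        # 0 lies inside the partial-recovery band (-0.5, 0]
        assert flags.sma_partial.all() and flags.fapar_partial.all()

    @pytest.mark.parametrize("spi1,spi3,flagged", [
        (-2.0, 0.0, False),   # strict <: exactly -2 does not flag
        (-2.01, 0.0, True),
        (0.0, -1.0, False),   # strict <: exactly -1 does not flag
        (0.0, -1.01, True),
    ])
    def test_spi_comparisons_strict(self, small_grid, spi1, spi3, flagged):
        flags = compute_flags(make_bundle(small_grid, spi1=spi1, spi3=spi3))
        assert flags.spi.all() == flagged

    @pytest.mark.parametrize("sma,flagged", [(-1.0, True), (-0.99, False)])
    def test_sma_comparison_inclusive(self, small_grid, sma, flagged):
        assert compute_flags(make_bundle(small_grid, sma=sma)).sma.all() == flagged

    @pytest.mark.parametrize("value,partial", [
        (0.0, True), (-0.49, True), (-0.5, False), (0.01, False),
    ])
    def test_partial_band_boundaries(self, small_grid, value, partial):
        flags = compute_flags(make_bundle(small_grid, sma=value))
        assert flags.sma_partial.all() == partial

    def test_wet_spi_needs_both_scales(self, small_grid):
        assert compute_flags(make_bundle(small_grid, spi1=0.6, spi3=0.1)).wet_spi.all()
        assert not compute_flags(make_bundle(small_grid, spi1=0.6, spi3=0.0)).wet_spi.any()
        assert not compute_flags(make_bundle(small_grid, spi1=0.5, spi3=0.1)).wet_spi.any()

    def test_invalid_spi_invalidates_pixel(self, small_grid):
        b = make_bundle(small_grid, valid=True)
        b.spi1.valid[0, 0] = False
        assert not compute_flags(b).valid[0, 0]

    def test_invalid_sma_behaves_as_masked(self, small_grid):
        b = make_bundle(small_grid, sma=-2.0)
        b.sma.valid[:] = False
        flags = compute_flags(b)
        assert flags.valid.all()
        assert not flags.sma.any() and not flags.sma_partial.any()


class TestMaskReduction:
    ALL_COMBOS = [(-2.5 if s else 0.0, -1.5 if m else 0.5, -1.5 if f else 0.5)
                  for s, m, f in itertools.product([0, 1], repeat=3)]

    def test_snow_reduces_to_columns_a_b(self, small_grid):
        """Under snow (v4) every flag combination lands in columns A or B."""
        cols = set()
        for spi1, sma, fapar in self.ALL_COMBOS:
            b = make_bundle(small_grid, spi1=spi1, sma=sma, fapar=fapar, snow=True)
            cols.add(column_of(b, version=4))
        assert cols == {"A", "B"}

    def test_offseason_crop_reduces_to_a_b_c_f(self, small_grid):
        cols = set()
        for spi1, sma, fapar in self.ALL_COMBOS:
            b = make_bundle(small_grid, spi1=spi1, sma=sma, fapar=fapar,
                            crop=CROP_OUT_OF_SEASON)
            cols.add(column_of(b, version=3))
        assert cols == {"A", "B", "C", "F"}

    def test_snow_pixel_with_deficits_is_column_a(self, small_grid):
        b = make_bundle(small_grid, sma=-2.0, fapar=-2.0, snow=True)
        assert column_of(b, version=4) == "A"

    def test_offseason_crop_keeps_sma_column_c(self, small_grid):
        b = make_bundle(small_grid, sma=-1.5, fapar=-2.0, crop=CROP_OUT_OF_SEASON)
        assert column_of(b, version=3) == "C"

    def test_non_crop_keeps_fapar_assessment(self, small_grid):
        b = make_bundle(small_grid, fapar=-2.0, crop=NON_CROP)
        assert column_of(b, version=4) == "D"

    def test_version2_is_identity(self, small_grid):
        b = make_bundle(small_grid, sma=-2.0, fapar=-2.0, snow=True,
                        crop=CROP_OUT_OF_SEASON)
        assert column_of(b, version=2) == "E"

    def test_in_season_crop_not_reduced(self, small_grid):
        b = make_bundle(small_grid, fapar=-2.0, crop=CROP_IN_SEASON)
        assert column_of(b, version=4) == "D"

    def test_bad_version_rejected(self, small_grid):
        flags = compute_flags(make_bundle(small_grid))
        with pytest.raises(ValueError):
            apply_mask_reduction(flags, None, None, 5)


class TestDecisionTable:
    def test_bundled_table_validates(self, table):
        assert validate_table(table).passed

    def test_table_is_total_8x7(self, table):
        assert len(clf.COLUMNS) == 7 + 1
        assert set(table.cells) == {(l, p) for l in clf.COLUMNS for p in CdiClass}

    def test_seven_classes_three_recovery(self):
        assert len(CdiClass) == 7
        assert len(clf.RECOVERY_CLASSES) == 3
        assert MISSING not in set(CdiClass)

    def test_seeded_drought_to_no_drought_violation(self, table):
        import copy
        bad = copy.deepcopy(table)
        bad.cells[("A", CdiClass.ALERT)] = [clf.Rule(None, CdiClass.NO_DROUGHT)]
        rep = validate_table(bad)
        assert not rep.passed
        assert any("ALERT" in v and "NO_DROUGHT" in v for v in rep.violations)

    def test_missing_cell_fails_totality(self, table):
        import copy
        bad = copy.deepcopy(table)
        del bad.cells[("D", CdiClass.WATCH)]
        assert not validate_table(bad).passed

    def test_alert_columns_must_be_alert(self, table):
        import copy
        bad = copy.deepcopy(table)
        bad.cells[("H", CdiClass.WATCH)] = [clf.Rule(None, CdiClass.WARNING)]
        rep = validate_table(bad)
        assert any(v.startswith("(H, WATCH)") for v in rep.violations)


class TestClassifyPixel:
    def test_column_h_always_alert(self, table):
        for prev in CdiClass:
            assert clf.classify_pixel("H", prev, {}, table) == CdiClass.ALERT

    def test_wet_spi_escape_in_column_c(self, table):
        assert clf.classify_pixel("C", CdiClass.NO_DROUGHT, {"wet_spi": True},
                                  table) == CdiClass.NO_DROUGHT
        assert clf.classify_pixel("C", CdiClass.NO_DROUGHT, {"wet_spi": False},
                                  table) == CdiClass.WARNING
        assert clf.classify_pixel("C", CdiClass.WATCH, {"wet_spi": True},
                                  table) == CdiClass.WARNING

    def test_partial_soil_recovery_from_warning(self, table):
        assert clf.classify_pixel("A", CdiClass.WARNING, {"sma_partial": True},
                                  table) == CdiClass.TEMP_SM_RECOVERY

    def test_partial_vegetation_recovery_from_alert(self, table):
        assert clf.classify_pixel("A", CdiClass.ALERT, {"fapar_partial": True},
                                  table) == CdiClass.TEMP_VEG_RECOVERY

    def test_column_b_is_watch_stage(self, table):
        for prev in CdiClass:
            assert clf.classify_pixel("B", prev, {}, table) == CdiClass.WATCH

    def test_pure_function_full_enumeration(self, table):
        """Same (column, prev, sub-conditions) -> same class, twice over the
        whole 8x7x predicate space; outputs always among the 7 classes."""
        for letter in clf.COLUMNS:
            for prev in CdiClass:
                for combo in itertools.product([False, True], repeat=3):
                    preds = dict(zip(clf.PREDICATES, combo))
                    a = clf.classify_pixel(letter, prev, preds, table)
                    b = clf.classify_pixel(letter, prev, dict(preds), table)
                    assert a == b and a in set(CdiClass)


class TestStep:
    def test_all_normal_no_drought_fixed_point(self, small_grid, table):
        b = make_bundle(small_grid, sma=0.5, fapar=0.5)
        prev = np.full(small_grid.shape, np.uint8(CdiClass.NO_DROUGHT))
        out = step(prev, b, table)
        assert (out == np.uint8(CdiClass.NO_DROUGHT)).all()

    def test_missing_spi_propagates_missing(self, small_grid, table):
        b = make_bundle(small_grid)
        b.spi1.valid[:] = False
        out = step(np.full(small_grid.shape, np.uint8(CdiClass.WATCH)), b, table)
        assert (out == MISSING).all()

    def test_matches_scalar_classifier(self, small_grid, table):
        """Vectorized step equals pixelwise classify_pixel on random bundles."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            vals = {k: rng.normal(-0.5, 1.2, small_grid.shape)
                    for k in ("spi1", "spi3", "sma", "fapar")}
            b = make_bundle(small_grid)
            for k, v in vals.items():
                getattr(b, k).values[:] = v
            prev = rng.integers(0, 7, small_grid.shape).astype(np.uint8)
            out = step(prev, b, table, version=2)
            flags = compute_flags(b)
            cols = flags.column_index()
            for r in range(small_grid.n_rows):
                for c in range(small_grid.n_cols):
                    preds = {name: bool(flags.predicate(name)[r, c])
                             for name in clf.PREDICATES}
                    expected = clf.classify_pixel(clf.COLUMNS[cols[r, c]],
                                                  CdiClass(prev[r, c]), preds, table)
                    assert out[r, c] == np.uint8(expected)

    def test_snow_never_yields_warning_or_alert_v4(self, small_grid, table):
        rng = np.random.default_rng(31)
        prev = rng.integers(0, 7, small_grid.shape).astype(np.uint8)
        forbidden = {np.uint8(CdiClass.WARNING), np.uint8(CdiClass.ALERT)}
        for _ in range(20):
            b = make_bundle(small_grid, snow=True)
            for k in ("spi1", "spi3", "sma", "fapar"):
                getattr(b, k).values[:] = rng.normal(-0.5, 1.5, small_grid.shape)
            out = step(prev, b, table, version=4)
            assert not (set(np.unique(out)) & forbidden)
            prev = out

    def test_version_changes_are_mask_local(self, small_grid, table):
        """v2/v3/v4 agree wherever there is no snow and no out-of-season crop."""
        rng = np.random.default_rng(41)
        snow = np.zeros(small_grid.shape, dtype=bool)
        snow[0, :] = True
        crop = np.full(small_grid.shape, CROP_IN_SEASON, dtype=np.uint8)
        crop[1, :] = CROP_OUT_OF_SEASON
        unmasked = ~snow & (crop != CROP_OUT_OF_SEASON)
        prev = rng.integers(0, 7, small_grid.shape).astype(np.uint8)
        b = make_bundle(small_grid, snow=True, crop=CROP_IN_SEASON)
        b.snow.snow[:] = snow
        b.crop[:] = crop
        for k in ("spi1", "spi3", "sma", "fapar"):
            getattr(b, k).values[:] = rng.normal(-0.8, 1.5, small_grid.shape)
        outs = {v: step(prev, b, table, version=v) for v in (2, 3, 4)}
        np.testing.assert_array_equal(outs[2][unmasked], outs[3][unmasked])
        np.testing.assert_array_equal(outs[3][unmasked], outs[4][unmasked])
        assert (outs[2] != outs[4]).any()  # and they do differ under the masks


class TestTransitionMatrix:
    def test_constant_series_is_diagonal(self, small_grid):
        m = np.full(small_grid.shape, np.uint8(CdiClass.WATCH))
        counts = transition_matrix([m, m, m])
        assert counts[int(CdiClass.WATCH), int(CdiClass.WATCH)] == 2 * small_grid.n_pixels
        assert counts.sum() == 2 * small_grid.n_pixels

    def test_single_off_diagonal_transition(self):
        a = np.array([[np.uint8(CdiClass.WATCH)]])
        b = np.array([[np.uint8(CdiClass.WARNING)]])
        counts = transition_matrix([a, b])
        assert counts[int(CdiClass.WATCH), int(CdiClass.WARNING)] == 1
        assert counts.sum() == 1

    def test_missing_excluded(self):
        a = np.array([[np.uint8(CdiClass.WATCH), MISSING]])
        b = np.array([[np.uint8(CdiClass.WATCH), np.uint8(CdiClass.ALERT)]])
        assert transition_matrix([a, b]).sum() == 1

    def test_needs_two_maps(self):
        with pytest.raises(ValueError):
            transition_matrix([np.zeros((2, 2), dtype=np.uint8)])
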