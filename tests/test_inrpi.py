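import numpy as np
import pytest

from recpot import (
    INDICATOR_CODES,
    INDICATOR_POLARITY,
    WeightSet,
    classify,
    compute_inrpi,
    pooled_minmax,
    standardize,
)
from recpot.index import fit_geometric_interval
from recpot.layers import IndicatorStack, POSITIVE

from conftest import full_stack, make_grid, make_layer

PAPER_BREAKS = (0.31, 0.37, 0.46, 0.61)


def unit_weights(**named):
    """A combined WeightSet over all 15 codes, zero except the named ones."""
    w = {c: 0.0 for c in INDICATOR_CODES}
    w.update(named)
    return WeightSet(kind="combined", weights=w)


class TestStandardize:
    def test_positive_endpoints(self):
        lyr = make_layer("TEM", np.array([[1.0, 5.0], [3.0, 5.0]]))
        out = standardize(lyr)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == 1.0

    def test_negative_min_maps_to_one(self):
        lyr = make_layer("PRRI", np.array([[1.0, 5.0], [3.0, 4.0]]))
        out = standardize(lyr)
        assert out.values[0, 0] == 1.0
        assert out.values[0, 1] == 0.0

    def test_direct_evaluation(self):
        lyr = make_layer("TEM", np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(standardize(lyr).values, [[0.0, 0.5, 1.0]])

    def test_supplied_minmax_clips(self):
        lyr = make_layer("TEM", np.array([[-1.0, 5.0, 11.0]]))
        out = standardize(lyr, minmax=(0.0, 10.0))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_constant_layer_errors_with_name(self):
        lyr = make_layer("PRE", np.full((3, 3), 7.0))
        with pytest.raises(ValueError, match="PRE"):
            standardize(lyr)
        out = standardize(lyr, minmax=(0.0, 10.0))
        np.testing.assert_allclose(out.values, 0.7)


class TestComputeInrpi:
    def test_all_standardized_one_gives_one(self):
        overrides = {
            c: np.full((4, 4), 1.0 if INDICATOR_POLARITY[c] == POSITIVE else 0.0)
            for c in INDICATOR_CODES
        }
        stack = full_stack(shape=(4, 4), overrides=overrides)
        w = WeightSet(kind="combined", weights={c: 1 / 15 for c in INDICATOR_CODES})
        mm = {c: (0.0, 1.0) for c in INDICATOR_CODES}
        pm = compute_inrpi(stack, w, minmax_policy="global", minmax=mm)
        np.testing.assert_allclose(pm.grid.values, 1.0, atol=1e-12)

    def test_degenerate_weight_recovers_single_layer(self, rng):
        stack = full_stack(shape=(5, 5), seed=3)
        w = unit_weights(SHDI=1.0)
        pm = compute_inrpi(stack, w, minmax_policy="per_epoch")
        expect = standardize(stack["SHDI"])
        np.testing.assert_allclose(pm.grid.values, expect.values, atol=1e-12)

    def test_two_indicator_hand_evaluation(self):
        overrides = {
            "SHDI": np.full((2, 2), 0.2),
            "HQ": np.full((2, 2), 0.8),
        }
        stack = full_stack(shape=(2, 2), overrides=overrides)
        w = unit_weights(SHDI=0.25, HQ=0.75)
        mm = {c: (0.0, 1.0) for c in INDICATOR_CODES}
        pm = compute_inrpi(stack, w, minmax_policy="global", minmax=mm)
        np.testing.assert_allclose(pm.grid.values, 0.25 * 0.2 + 0.75 * 0.8, atol=1e-12)

    def test_missing_indicator_errors(self, rng):
        stack = full_stack(shape=(3, 3))
        partial = IndicatorStack(
            epoch="2000",
            layers={c: stack[c] for c in INDICATOR_CODES if c != "TA"},
        )
        w = WeightSet(kind="combined", weights={c: 1 / 15 for c in INDICATOR_CODES})
        with pytest.raises(ValueError, match="TA"):
            compute_inrpi(partial, w, minmax_policy="per_epoch")

    def test_requires_combined_kind(self):
        stack = full_stack(shape=(3, 3))
        w = WeightSet(kind="ahp", weights={c: 1 / 15 for c in INDICATOR_CODES})
        with pytest.raises(ValueError, match="combined"):
            compute_inrpi(stack, w, minmax_policy="per_epoch")

    def test_global_policy_requires_table(self):
        stack = full_stack(shape=(3, 3))
        w = WeightSet(kind="combined", weights={c: 1 / 15 for c in INDICATOR_CODES})
        with pytest.raises(ValueError, match="pooled"):
            compute_inrpi(stack, w, minmax_policy="global")

    def test_convex_combination_bounds(self, rng):
        stack = full_stack(shape=(8, 8), seed=5)
        w = WeightSet(kind="combined", weights={c: 1 / 15 for c in INDICATOR_CODES})
        pm = compute_inrpi(stack, w, minmax_policy="per_epoch")
        xs = np.stack([standardize(stack[c]).values for c in INDICATOR_CODES])
        assert np.all(pm.grid.values >= xs.min(axis=0) - 1e-9)
        assert np.all(pm.grid.values <= xs.max(axis=0) + 1e-9)

    def test_monotone_in_single_indicator(self, rng):
        # raising a positive indicator (within the fixed minmax) never lowers
        # the index; lowering a negative one never lowers it either
        stack = full_stack(shape=(6, 6), seed=9)
        w = WeightSet(kind="combined", weights={c: 1 / 15 for c in INDICATOR_CODES})
        mm = pooled_minmax([stack])
        pm = compute_inrpi(stack, w, minmax_policy="global", minmax=mm)
        for code, delta in (("TEM", +1.0), ("PRRI", -1.0)):
            vals = stack[code].grid.values.copy()
            vals[2, 2] += delta
            bumped_layers = dict(stack.layers)
            bumped_layers[code] = make_layer(code, vals)
            bumped = IndicatorStack(epoch="2000", layers=bumped_layers)
            pm2 = compute_inrpi(bumped, w, minmax_policy="global", minmax=mm)
            assert pm2.grid.values[2, 2] >= pm.grid.values[2, 2] - 1e-12


class TestClassify:
    def _pm(self, values):
        from recpot.index import PotentialMap

        return PotentialMap(grid=make_grid(values), epoch="2000")

    def test_published_breaks_bin_value(self):
        pm = self._pm(np.array([[0.50, 0.25], [0.70, 0.40]]))
        cm = classify(pm, mode="fixed", K=5, fixed_breaks=PAPER_BREAKS)
        assert cm.grid.values[0, 0] == 4  # 0.50 -> high potential
        assert cm.labels[3] == "high potential"

    def test_breakpoint_value_left_closed(self):
        pm = self._pm(np.array([[0.37, 0.3699999], [0.61, 0.22]]))
        cm = classify(pm, mode="fixed", K=5, fixed_breaks=PAPER_BREAKS)
        assert cm.grid.values[0, 0] == 3
        assert cm.grid.values[0, 1] == 2
        assert cm.grid.values[1, 0] == 5

    def test_uniform_data_recovers_equal_intervals(self, rng):
        vals = rng.uniform(0.0, 1.0, size=(60, 60))
        pm = self._pm(vals)
        cm = classify(pm, mode="geometric_interval", K=5)
        b = np.asarray(cm.breakpoints)
        assert np.all(np.diff(b) > 0)
        lo, hi = vals.min(), vals.max()
        equal = lo + (hi - lo) * np.arange(1, 5) / 5
        np.testing.assert_allclose(b, equal, atol=0.02)

    def test_geometric_ratio_one_is_equal_interval(self):
        from recpot.index import _geometric_breaks

        np.testing.assert_allclose(
            _geometric_breaks(0.0, 1.0, 1.0, 5), [0.2, 0.4, 0.6, 0.8], atol=1e-12
        )

    def test_area_conservation(self, rng):
        vals = rng.uniform(0, 1, size=(20, 20))
        mask = rng.random((20, 20)) < 0.2
        from recpot.index import PotentialMap

        pm = PotentialMap(grid=make_grid(vals, mask=mask), epoch="2000")
        cm = classify(pm, mode="fixed", K=5, fixed_breaks=PAPER_BREAKS)
        total = sum(cm.level_areas_km2().values())
        assert total == pytest.approx((~mask).sum() * 1.0, abs=1e-9)

    def test_break_count_mismatch_errors(self):
        pm = self._pm(np.array([[0.5]]))
        with pytest.raises(ValueError, match="breaks"):
            classify(pm, mode="fixed", K=5, fixed_breaks=(0.3, 0.5))

    def test_out_of_range_breaks_warn(self):
        pm = self._pm(np.array([[0.4, 0.5], [0.45, 0.55]]))
        with pytest.warns(UserWarning, match="outside"):
            classify(pm, mode="fixed", K=3, fixed_breaks=(0.1, 0.5))

    def test_geometric_interval_handles_skewed_data(self, rng):
        vals = rng.exponential(scale=0.1, size=(40, 40))
        breaks, g = fit_geometric_interval(vals.ravel(), 5)
        assert np.all(np.diff(breaks) > 0)
        assert breaks[0] > vals.min() and breaks[-1] < vals.max()
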