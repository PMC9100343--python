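import numpy as np
import pytest

from recpot import SamplePairs, band_profile, fit_breakpoint, sample_points
from recpot.index import PotentialMap

from conftest import make_grid


def two_piece(e, bp=3000.0, pre=0.02, post=-0.30, base=0.6):
    d = (e - bp) / 1000.0
    return base + pre * np.minimum(d, 0) + post * np.maximum(d, 0)


def brute_force_fit(e, y, candidates):
    """Independent oracle: explicit design-matrix least squares per candidate."""
    best = (np.inf, None, None)
    for c in candidates:
        X = np.column_stack([np.ones_like(e), e, np.maximum(e - c, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sse = float(r @ r)
        if sse < best[0]:
            best = (sse, c, beta)
    return best


def make_pm(values, mask=None):
    return PotentialMap(grid=make_grid(values, mask=mask), epoch="2000")


class TestSamplePoints:
    def test_same_seed_identical(self, rng):
        pm = make_pm(rng.uniform(0, 1, (20, 20)))
        dem = make_grid(rng.uniform(1000, 5000, (20, 20)))
        s1 = sample_points(pm, dem, 50, seed=5)
        s2 = sample_points(pm, dem, 50, seed=5)
        np.testing.assert_array_equal(s1.elevation_m, s2.elevation_m)
        np.testing.assert_array_equal(s1.inrpi, s2.inrpi)

    def test_exhaustive_sample_hits_every_cell(self, rng):
        vals = rng.uniform(0, 1, (8, 8))
        pm = make_pm(vals)
        dem = make_grid(rng.uniform(1000, 5000, (8, 8)))
        s = sample_points(pm, dem, 64, seed=1)
        assert sorted(s.inrpi) == sorted(vals.ravel())

    def test_oversampling_errors(self, rng):
        pm = make_pm(rng.uniform(0, 1, (4, 4)))
        dem = make_grid(rng.uniform(0, 1, (4, 4)))
        with pytest.raises(ValueError, match="valid cells"):
            sample_points(pm, dem, 17, seed=0)

    def test_sample_mean_within_two_se_of_field_mean(self, rng):
        field = rng.uniform(0, 1, (80, 80))
        pm = make_pm(field)
        dem = make_grid(rng.uniform(1000, 5000, (80, 80)))
        N, n = field.size, 5000
        mu, sd = field.mean(), field.std(ddof=0)
        se = sd * np.sqrt((N - n) / (N - 1) / n)  # without-replacement SE
        hits = 0
        for seed in range(10):
            s = sample_points(pm, dem, n, seed=seed)
            if abs(s.inrpi.mean() - mu) < 2 * se:
                hits += 1
        assert hits >= 9


class TestFitBreakpoint:
    def test_noise_free_exact_recovery(self, rng):
        e = np.sort(rng.uniform(1000, 5000, 400))
        e[200] = 3000.0  # ensure the true break is a candidate
        y = two_piece(e)
        s = SamplePairs(elevation_m=e, inrpi=y, seed=0)
        fit = fit_breakpoint(s)
        assert fit.breakpoint_m == pytest.approx(3000.0, abs=1e-9)
        assert fit.slope_pre == pytest.approx(0.02, abs=1e-6)
        assert fit.slope_post == pytest.approx(-0.30, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.material

    def test_noisy_recovery_scaled_replicates(self):
        # scaled-down replicate study; the full-size run lives in acceptance
        errs, slopes = [], []
        for rep in range(30):
            rr = np.random.default_rng(1000 + rep)
            e = rr.uniform(1000, 5000, 500)
            y = two_piece(e) + rr.normal(0, 0.03, e.size)
            fit = fit_breakpoint(SamplePairs(elevation_m=e, inrpi=y, seed=rep))
            errs.append(abs(fit.breakpoint_m - 3000.0))
            slopes.append(fit.slope_post)
        assert np.median(errs) < 100.0
        assert abs(np.median(slopes) + 0.30) < 0.02

    def test_exact_straight_line_flagged_immaterial(self, rng):
        e = rng.uniform(1000, 5000, 300)
        y = 0.9 - 0.0001 * e
        fit = fit_breakpoint(SamplePairs(elevation_m=e, inrpi=y, seed=0))
        assert not fit.material

    def test_noisy_straight_line_improvement_below_tolerance(self):
        rr = np.random.default_rng(77)
        e = rr.uniform(1000, 5000, 1000)
        y = 0.9 - 0.0001 * e + rr.normal(0, 0.02, e.size)
        fit = fit_breakpoint(SamplePairs(elevation_m=e, inrpi=y, seed=0))
        improvement = (fit.sse_single_line - fit.sse) / fit.sse_single_line
        assert improvement < fit.material_tol
        assert not fit.material

    def test_two_segment_sse_never_above_single_line(self, rng):
        for _ in range(5):
            e = rng.uniform(0, 1000, 100)
            y = rng.normal(0, 1, 100)
            fit = fit_breakpoint(SamplePairs(elevation_m=e, inrpi=y, seed=0))
            assert fit.sse <= fit.sse_single_line + 1e-9

    def test_fast_path_matches_brute_force_oracle(self, rng):
        e = rng.uniform(1000, 5000, 120)
        y = two_piece(e, bp=2600.0) + rng.normal(0, 0.05, 120)
        s = SamplePairs(elevation_m=e, inrpi=y, seed=0)
        fit = fit_breakpoint(s, min_segment=5)
        es = np.sort(e)
        candidates = np.unique(es[5:-5])
        sse_o, c_o, beta_o = brute_force_fit(e, y, candidates)
        assert fit.breakpoint_m == pytest.approx(c_o, abs=1e-9)
        assert fit.sse == pytest.approx(sse_o, rel=1e-8)
        assert fit.slope_pre == pytest.approx(beta_o[1] * 1000, rel=1e-6)
        assert fit.slope_post == pytest.approx((beta_o[1] + beta_o[2]) * 1000, rel=1e-6)

    def test_grid_step_candidates(self, rng):
        e = rng.uniform(1000, 5000, 300)
        y = two_piece(e) + rng.normal(0, 0.02, 300)
        fit = fit_breakpoint(SamplePairs(elevation_m=e, inrpi=y, seed=0), grid_step_m=50.0)
        assert fit.breakpoint_m % 50.0 == pytest.approx(0.0, abs=1e-9)
        assert abs(fit.breakpoint_m - 3000.0) <= 150.0

    def test_degenerate_elevations_error(self):
        s = SamplePairs(elevation_m=np.full(30, 2000.0), inrpi=np.zeros(30), seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_breakpoint(s)

    def test_too_few_points_error(self):
        s = SamplePairs(elevation_m=np.arange(10.0), inrpi=np.zeros(10), seed=0)
        with pytest.raises(ValueError, match="20"):
            fit_breakpoint(s)


class TestBandProfile:
    def test_constant_index(self, rng):
        pm = make_pm(np.full((10, 10), 0.4))
        dem = make_grid(rng.uniform(0, 5000, (10, 10)))
        df = band_profile(pm, dem, band_width_m=500.0)
        np.testing.assert_allclose(df["mean_inrpi"], 0.4)

    def test_linear_index_gives_band_midpoints(self):
        dem_vals = np.arange(10000, dtype=float).reshape(100, 100) / 2.0  # 0..4999.5
        dem = make_grid(dem_vals)
        pm = make_pm(dem_vals / 10000.0)
        df = band_profile(pm, dem, band_width_m=500.0)
        assert (df["mean_inrpi"].diff().dropna() > 0).all()
        # each band holds a symmetric run of values -> mean = band midpoint
        mids = (df["band_low_m"] + df["band_high_m"]) / 2.0
        np.testing.assert_allclose(df["mean_inrpi"], mids / 10000.0, atol=1e-4)

    def test_single_band_equals_global_mean(self, rng):
        vals = rng.uniform(0, 1, (10, 10))
        pm = make_pm(vals)
        dem = make_grid(rng.uniform(0, 4999, (10, 10)))
        df = band_profile(pm, dem, band_width_m=5000.0)
        assert len(df) == 1
        assert df.iloc[0]["mean_inrpi"] == pytest.approx(vals.mean())

    def test_areas_sum_to_valid_area(self, rng):
        mask = rng.random((10, 10)) < 0.3
        pm = make_pm(rng.uniform(0, 1, (10, 10)), mask=mask)
        dem = make_grid(rng.uniform(0, 5000, (10, 10)))
        df = band_profile(pm, dem, band_width_m=250.0)
        assert df["area_km2"].sum() == pytest.approx((~mask).sum() * 1.0)

    def test_bad_band_width(self, rng):
        pm = make_pm(np.ones((4, 4)))
        dem = make_grid(np.ones((4, 4)))
        with pytest.raises(ValueError, match="width"):
            band_profile(pm, dem, band_width_m=0.0)
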