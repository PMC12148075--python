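"""Sigmoid fitting, accuracy metrics, RANSAC screen, Bland-Altman."""

import numpy as np
import pytest

from mlrabm import (
    SigmoidFit,
    accuracy_metrics,
    bland_altman,
    delta_response,
    fit_sigmoid,
    map_control_doses,
    normalize_ifng,
    paired_ttest,
    ransac_screen,
    sigmoid,
)
from mlrabm.experiment import DEFAULT_DOSE_GRID

GRID = np.array(DEFAULT_DOSE_GRID)


class TestFitSigmoid:
    def test_noiseless_roundtrip_recovers_parameters(self):
        truth = dict(bottom=10.0, top=40.0, ec50=1e-11)
        y = sigmoid(GRID, **truth)
        fit = fit_sigmoid(GRID, y)
        assert fit.bottom == pytest.approx(truth["bottom"], rel=1e-6)
        assert fit.top == pytest.approx(truth["top"], rel=1e-6)
        assert fit.ec50 == pytest.approx(truth["ec50"], rel=1e-6)
        assert fit.span == fit.top - fit.bottom
        assert not fit.ec50_unidentifiable
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_curve_flagged_unidentifiable(self):
        fit = fit_sigmoid(GRID, np.full(len(GRID), 25.0))
        assert abs(fit.span) < 1e-6
        assert fit.ec50_unidentifiable

    def test_monotone_data_orders_top_above_bottom(self, rng):
        y = np.sort(rng.uniform(5, 60, len(GRID)))
        fit = fit_sigmoid(GRID, y)
        assert fit.top >= fit.bottom

    def test_requires_four_distinct_positive_doses(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.array([1e-9, 1e-8, 1e-7]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="positive"):
            fit_sigmoid(np.array([0.0, 1e-9, 1e-8, 1e-7]), np.zeros(4))

    def test_out_of_grid_ec50_flagged_extrapolated(self):
        y = sigmoid(GRID, 10.0, 40.0, 5e-7)  # EC50 above the tested range
        fit = fit_sigmoid(GRID, y)
        assert fit.ec50_extrapolated

    def test_noise_robust_ec50_recovery(self, rng):
        # With triplicate noise at 5 % of span, log-EC50 lands within 0.3
        # decades in >= 95 % of simulations.
        truth = dict(bottom=10.0, top=40.0, ec50=1e-11)
        span = truth["top"] - truth["bottom"]
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            doses = np.repeat(GRID, 3)
            y = sigmoid(doses, **truth) + rng.normal(0, 0.05 * span, len(doses))
            fit = fit_sigmoid(doses, y)
            hits += abs(np.log10(fit.ec50) - np.log10(truth["ec50"])) < 0.3
        assert hits / n_sim >= 0.95


class TestMapControlDoses:
    def test_controls_placed_one_decade_below(self):
        mapped = map_control_doses(np.array([0.0, 1e-12, 1e-11]))
        assert mapped[0] == pytest.approx(1e-13)
        assert np.all(mapped[1:] == [1e-12, 1e-11])

    def test_requires_a_positive_dose(self):
        with pytest.raises(ValueError):
            map_control_doses(np.zeros(3))


class TestAccuracyMetrics:
    def test_curve_against_itself_is_perfect(self):
        fit = SigmoidFit(bottom=10.0, top=40.0, ec50=1e-11, r_squared=1.0)
        pts = [(d, float(fit.predict(d))) for d in GRID]
        rep = accuracy_metrics(pts, fit)
        assert rep.rms == pytest.approx(0.0, abs=1e-12)
        assert rep.pct_accuracy == pytest.approx(100.0)

    def test_printed_formula_arithmetic(self):
        # span 20, RMS 2 -> %RMS 10, accuracy 90; corrected by 90 % self-accuracy
        fit = SigmoidFit(bottom=10.0, top=30.0, ec50=1e-10, r_squared=1.0)
        pts = [(0.0, 10.0 + 2.0), (0.0, 10.0 - 2.0)]  # residuals +-2 at the floor
        rep = accuracy_metrics(pts, fit, reference_self_accuracy=90.0)
        assert rep.pct_rms == pytest.approx(10.0, rel=1e-6)
        assert rep.pct_accuracy == pytest.approx(90.0, rel=1e-6)
        assert rep.corrected_pct_accuracy == pytest.approx(100.0, rel=1e-6)

    def test_corrected_accuracy_ratio(self):
        fit = SigmoidFit(bottom=0.0, top=20.0, ec50=1e-10, r_squared=1.0)
        pts = [(0.0, 2.0), (0.0, -2.0)]
        rep = accuracy_metrics(pts, fit, reference_self_accuracy=90.0)
        assert rep.corrected_pct_accuracy == pytest.approx(90.0 / 90.0 * 100.0)

    def test_zero_span_reference_rejected(self):
        flat = SigmoidFit(bottom=5.0, top=5.0, ec50=1e-10, r_squared=0.0)
        with pytest.raises(ValueError, match="span"):
            accuracy_metrics([(1e-10, 5.0)], flat)


class TestDeltaAndNormalize:
    @staticmethod
    def _table(responses_by_dose, reps=3):
        import pandas as pd

        rows = []
        for dose, mean in responses_by_dose.items():
            for r in range(reps):
                rows.append({"dose_M": dose, "replicate": r,
                             "pct_pd1_cd4": mean + (r - 1) * 0.5})
        return pd.DataFrame(rows)

    def test_lowest_dose_delta_is_zero_and_order_preserved(self):
        df = self._table({1e-12: 10.0, 1e-10: 12.0, 1e-8: 20.0})
        out = delta_response(df)
        assert out["delta"].tolist() == pytest.approx([0.0, 2.0, 10.0])

    def test_delta_preserves_response_ordering(self, rng):
        for _ in range(20):
            doses = 10.0 ** np.sort(rng.uniform(-13, -7, 5))
            vals = rng.uniform(0, 60, 5)
            out = delta_response(self._table(dict(zip(doses, vals))))
            assert np.array_equal(np.argsort(out["mean_response"]), np.argsort(out["delta"]))

    def test_missing_doses_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            delta_response(pd.DataFrame({"dose_M": [0.0], "pct_pd1_cd4": [1.0]}))

    def test_normalize_max_maps_to_one(self, rng):
        v = rng.uniform(0.1, 50, 30)
        out = normalize_ifng(v)
        assert out.max() == pytest.approx(1.0)
        assert np.allclose(out, normalize_ifng(3.7 * v))  # scale invariance

    def test_normalize_all_equal_gives_ones(self):
        assert np.allclose(normalize_ifng(np.full(5, 2.0)), 1.0)

    def test_normalize_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalize_ifng(np.zeros(4))


class TestRansac:
    def test_collinear_points_recovered_exactly(self):
        x = np.linspace(0, 10, 27)
        y = 2.0 * x + 1.0
        res = ransac_screen(x, y, seed=0)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.n_inliers == 27
        assert res.inlier_r == pytest.approx(1.0)
        assert np.allclose(res.pct_errors, 0.0, atol=1e-9)

    def test_planted_line_with_gross_outliers(self):
        rng = np.random.default_rng(7)
        n = 27
        x = np.linspace(0, 10, n)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.1, n)
        out_idx = rng.choice(n, size=round(0.2 * n), replace=False)
        y[out_idx] += rng.uniform(8, 20, len(out_idx)) * rng.choice([-1, 1], len(out_idx))
        res = ransac_screen(x, y, seed=1)
        assert abs(res.slope - 2.0) / 2.0 < 0.05
        planted_inliers = np.setdiff1d(np.arange(n), out_idx)
        recovered = res.inlier_mask[planted_inliers].mean()
        assert recovered >= 0.8
        assert not res.inlier_mask[out_idx].any()

    def test_all_inliers_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 27)
        y = -1.5 * x + 4.0 + rng.normal(0, 0.2, 27)
        res = ransac_screen(x, y, threshold=np.inf, seed=0)
        slope, intercept = np.polyfit(x, y, 1)
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)
        assert res.n_inliers == 27

    def test_matches_sklearn_consensus_line(self):
        # Independent reference implementation on the same contaminated data.
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(11)
        x = np.linspace(0, 10, 40)
        y = 0.8 * x + 2.0 + rng.normal(0, 0.05, 40)
        y[::7] += 15.0
        ours = ransac_screen(x, y, threshold=1.0, seed=2)
        ref = sklearn.RANSACRegressor(residual_threshold=1.0, random_state=0)
        ref.fit(x[:, None], y)
        assert ours.slope == pytest.approx(float(ref.estimator_.coef_[0]), rel=0.05)
        assert ours.intercept == pytest.approx(float(ref.estimator_.intercept_), abs=0.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ransac_screen([1.0], [2.0], min_samples=2)


class TestBlandAltman:
    def test_identical_series_zero_bias_and_limits(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.lower_limit == 0.0 and res.upper_limit == 0.0

    def test_constant_offset(self):
        a = np.array([5.0, 6.0, 7.0])
        res = bland_altman(a, a - 3.0)
        assert res.bias == pytest.approx(3.0)
        assert res.upper_limit == pytest.approx(3.0)

    def test_matches_direct_recomputation(self, rng):
        a, b = rng.normal(0, 5, 50), rng.normal(0, 5, 50)
        res = bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        assert res.upper_limit == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert res.lower_limit == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


def test_paired_ttest_agrees_with_scipy(rng):
    from scipy import stats

    a, b = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
    stat, p = paired_ttest(a, b)
    ref = stats.ttest_rel(a, b)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
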