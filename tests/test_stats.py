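"""Evaluation statistics: Dice, ROC/Youden, DeLong, agreement, histograms."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aigs.stats import (auc_mann_whitney, bland_altman, correlation_compare,
                        delong_test, dice_coefficient, histogram_summary,
                        roc_analysis, threshold_sweep, youden_threshold)


class TestDice:
    def test_identities(self, rng):
        m = rng.random((32, 32)) > 0.5
        assert dice_coefficient(m, m) == 1.0
        assert dice_coefficient(m, ~m) == 0.0
        assert dice_coefficient(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_worked_overlap(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True                      # |A| = 100
        b[70:130] = True                    # |B| = 60, overlap 30
        assert dice_coefficient(a, b) == pytest.approx(2 * 30 / 160)

    def test_symmetry_and_shape_check(self, rng):
        a = rng.random((16, 16)) > 0.3
        b = rng.random((16, 16)) > 0.7
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        with pytest.raises(ValueError):
            dice_coefficient(a, np.zeros((4, 4)))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = roc_analysis(scores, labels, n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.youden_j == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_uninformative_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(auc_mann_whitney(scores, labels) - 0.5) < 0.03

    def test_constant_scores_degenerate(self):
        scores = np.full(40, 0.7)
        labels = np.array([0, 1] * 20)
        res = roc_analysis(scores, labels, n_boot=200, seed=1)
        assert res.auc == 0.5
        lo, hi = res.ci["auc"]
        assert lo == hi == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_ci_brackets_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 80),
                                 rng.normal(1, 1, 80)])
        labels = np.array([0] * 80 + [1] * 80)
        res = roc_analysis(scores, labels, n_boot=400, seed=2)
        lo, hi = res.ci["auc"]
        assert lo <= res.auc <= hi

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_auc_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            return
        base = auc_mann_whitney(scores, labels)
        for f in (lambda x: 3 * x + 2, np.exp,
                  lambda x: x ** 3, lambda x: 1 / (1 + np.exp(-x))):
            assert auc_mann_whitney(f(scores), labels) == pytest.approx(base)


class TestYouden:
    def test_perfect_separation_j_is_one(self):
        t, j = youden_threshold(np.array([0.1, 0.2, 0.8, 0.9]),
                                np.array([0, 0, 1, 1]))
        assert j == 1.0
        assert 0.2 < t <= 0.8

    def test_eight_point_set_matches_exhaustive_sweep(self):
        scores = np.array([0.05, 0.2, 0.35, 0.4, 0.55, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        t, j = youden_threshold(scores, labels)
        best_j, best_t = -1.0, None
        for cand in np.unique(scores):        # ties -> larger threshold
            pred = scores >= cand
            jj = (pred[labels == 1].mean()
                  - pred[labels == 0].mean())
            if jj >= best_j:
                best_j, best_t = jj, cand
        # rescan to honour 'larger threshold wins ties'
        for cand in np.unique(scores)[::-1]:
            pred = scores >= cand
            jj = pred[labels == 1].mean() - pred[labels == 0].mean()
            if jj == best_j:
                best_t = cand
                break
        assert j == pytest.approx(best_j)
        assert t == pytest.approx(best_t)

    def test_j_nonnegative(self, rng):
        for _ in range(10):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            _, j = youden_threshold(scores, labels)
            assert j >= 0.0


class TestDeLong:
    def test_identical_scores_p_is_one(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a, b, p = delong_test(scores, scores, labels)
        assert a == b and p == 1.0

    def test_auc_matches_trapezoidal(self, rng):
        scores_a = rng.normal(0, 1, 200)
        scores_b = rng.normal(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        a, b, _ = delong_test(scores_a, scores_b, labels)
        assert a == pytest.approx(auc_mann_whitney(scores_a, labels),
                                  abs=1e-12)
        assert b == pytest.approx(auc_mann_whitney(scores_b, labels),
                                  abs=1e-12)

    def test_detects_a_real_auc_difference(self, rng):
        n = 400
        labels = np.array([0, 1] * (n // 2))
        good = labels * 1.5 + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        _, _, p = delong_test(good, noise, labels)
        assert p < 1e-4

    def test_agrees_with_bootstrap_difference_test(self, rng):
        n = 300
        labels = np.array([0, 1] * (n // 2))
        a = labels * 0.8 + rng.normal(0, 1, n)
        b = labels * 0.3 + rng.normal(0, 1, n)
        auc_a, auc_b, p_delong = delong_test(a, b, labels)
        # independent oracle: paired bootstrap of the AUC difference
        draws = []
        for _ in range(600):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.min() == lb.max():
                continue
            draws.append(auc_mann_whitney(a[idx], lb)
                         - auc_mann_whitney(b[idx], lb))
        draws = np.array(draws)
        p_boot = 2 * min((draws <= 0).mean(), (draws >= 0).mean())
        p_boot = max(p_boot, 1 / len(draws))
        assert np.sign(auc_a - auc_b) == np.sign(np.median(draws))
        assert abs(math.log10(max(p_delong, 1e-4))
                   - math.log10(max(p_boot, 1e-4))) <= 1.0


class TestBlandAltman:
    def test_identical_measurements(self, rng):
        a = rng.random(100)
        res = bland_altman(a, a)
        assert res.bias == 0.0 and res.sd == 0.0
        assert res.percent_within == 100.0

    def test_constant_offset(self, rng):
        a = rng.random(50)
        res = bland_altman(a, a + 0.3)
        assert res.bias == pytest.approx(-0.3)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.limits[0] == pytest.approx(res.limits[1])

    def test_gaussian_noise_within_limits(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.random(500)
            b = a + rng.normal(0, 0.05, 500)
            fracs.append(bland_altman(a, b).percent_within)
        assert all(92.0 <= f <= 98.0 for f in fracs)
        assert 93.0 <= np.mean(fracs) <= 97.0


class TestThresholdSweep:
    def test_extreme_thresholds(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        sweep = threshold_sweep(scores, labels,
                                [scores.min() - 0.1, scores.max() + 0.1])
        assert sweep.iloc[0].sensitivity == 1.0
        assert sweep.iloc[0].specificity == 0.0
        assert sweep.iloc[1].sensitivity == 0.0
        assert sweep.iloc[1].specificity == 1.0

    def test_piecewise_constant_with_breaks_at_scores(self, rng):
        scores = np.round(rng.random(12), 2)
        labels = rng.integers(0, 2, 12)
        labels[:2] = [0, 1]
        grid = np.linspace(-0.1, 1.1, 400)
        sweep = threshold_sweep(scores, labels, grid)
        curve = sweep[["sensitivity", "specificity"]].to_numpy()
        changes = np.nonzero((np.diff(curve, axis=0) != 0).any(axis=1))[0]
        for c in changes:
            lo, hi = grid[c], grid[c + 1]
            assert ((scores > lo) & (scores <= hi)).any()
        assert len(np.unique(curve, axis=0)) <= len(np.unique(scores)) + 1


class TestCorrelationCompare:
    def test_same_data_no_difference(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (120, 3)),
                          columns=["a", "b", "c"])
        res = correlation_compare(df, df.copy(), n_boot=200, seed=0)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(res.difference.to_numpy()[off], 0.0)
        assert (res.p_values.to_numpy()[off] > 0.5).all()
        pd.testing.assert_frame_equal(res.corr_a, res.corr_a.T)

    def test_perfectly_linear_pair(self, rng):
        x = rng.normal(0, 1, 80)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = correlation_compare(df, df.copy(), n_boot=50, seed=0)
        assert res.corr_a.loc["a", "b"] == pytest.approx(1.0)

    def test_method_selection_follows_normality(self, rng):
        heavy = rng.standard_cauchy(200)
        df_a = pd.DataFrame({"a": rng.normal(0, 1, 200), "b": heavy})
        df_b = pd.DataFrame({"a": rng.normal(0, 1, 200),
                             "b": rng.standard_cauchy(200)})
        res = correlation_compare(df_a, df_b, n_boot=50, seed=0)
        assert res.method.loc["a", "b"] == "spearman"
        gauss = pd.DataFrame(rng.normal(0, 1, (200, 2)),
                             columns=["a", "b"])
        res2 = correlation_compare(gauss, gauss.copy() * 1.0, n_boot=50,
                                   seed=0)
        assert res2.method.loc["a", "b"] == "pearson"

    def test_constant_column_flagged(self, rng):
        df_a = pd.DataFrame({"a": rng.normal(0, 1, 50),
                             "b": np.ones(50)})
        df_b = pd.DataFrame({"a": rng.normal(0, 1, 50),
                             "b": rng.normal(0, 1, 50)})
        res = correlation_compare(df_a, df_b, n_boot=50, seed=0)
        assert math.isnan(res.p_values.loc["a", "b"])

    def test_power_to_detect_large_difference(self):
        detected = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.normal(0, 1, n)
            ya = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(0, 1, n)
            xb = rng.normal(0, 1, n)
            yb = 0.2 * xb + math.sqrt(1 - 0.04) * rng.normal(0, 1, n)
            res = correlation_compare(pd.DataFrame({"x": x, "y": ya}),
                                      pd.DataFrame({"x": xb, "y": yb}),
                                      n_boot=400, seed=seed)
            if res.p_values.loc["x", "y"] < 0.05:
                detected += 1
        assert detected == 3


class TestHistogramSummary:
    def test_gaussian_fwhm(self, rng):
        res = histogram_summary(rng.normal(0, 1, 100_000), bins=80)
        assert res.fwhm == pytest.approx(2.355, rel=0.05)
        assert abs(res.peak) < 0.2

    def test_cumulative_ends_at_one(self, rng):
        res = histogram_summary(rng.exponential(1, 5000), bins=40)
        assert res.cumulative[-1] == pytest.approx(1.0)
        assert (np.diff(res.cumulative) >= 0).all()

    def test_constant_data_convention(self):
        res = histogram_summary(np.full(100, 3.7))
        assert res.peak == pytest.approx(3.7)
        assert res.fwhm == pytest.approx(res.bin_edges[1]
                                         - res.bin_edges[0])
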