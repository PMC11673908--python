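"""Mann-Whitney / effect-size / AUC identities, ROC sweep and thresholds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cyclogait import (
    compare_cohorts,
    confusion,
    correlate_with_bi,
    effect_label,
    mann_whitney,
    optimal_threshold,
    roc_curve,
    separation,
)
from cyclogait.errors import DegenerateROCError


def brute_force_u(x, y):
    """Pairwise-count oracle: sum of [x_i > y_j] + 1/2 [x_i == y_j]."""
    x, y = np.asarray(x), np.asarray(y)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * eq


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        s, r, auc = separation(u, 3, 3)
        assert (s, r, auc) == (0.0, 1.0, 1.0)

    def test_all_ties(self):
        u, _ = mann_whitney([5, 5, 5], [5, 5, 5])
        s, r, auc = separation(u, 3, 3)
        assert s == 0.5 and auc == 0.5 and r == 0.0

    def test_matches_pairwise_count_oracle(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 16, size=2)
            x = rng.integers(0, 8, size=n1).astype(float)  # integer scores force ties
            y = rng.integers(0, 8, size=n2).astype(float)
            u, _ = mann_whitney(x, y)
            assert u == pytest.approx(brute_force_u(x, y), abs=1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSeparation:
    @pytest.mark.parametrize(
        "auc, r_expected",
        [(0.987, 0.974), (0.838, 0.676)],  # printed AUC/r pairs for AB and ap D
    )
    def test_auc_r_identity_reproduces_printed_pairs(self, auc, r_expected):
        n1, n2 = 56, 70
        u = (1.0 - auc) * n1 * n2
        _, r, auc_back = separation(u, n1, n2)
        assert round(r, 3) == r_expected
        assert auc_back == pytest.approx(auc)

    def test_auc_equals_half_one_plus_r(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, size=2)
            u = rng.uniform(0, n1 * n2)
            _, r, auc = separation(u, int(n1), int(n2))
            assert auc == pytest.approx((1 + r) / 2, abs=1e-12)

    def test_out_of_range_u_is_error(self):
        with pytest.raises(ValueError):
            separation(10.0, 3, 3)


class TestEffectLabel:
    @pytest.mark.parametrize(
        "r, label",
        [
            (0.974, "large"),
            (0.38, "large"),
            (0.353, "medium"),
            (0.37, "medium"),
            (0.2, "small"),
            (0.3, "small"),
            (0.096, "very small"),
            (0.1, "very small"),
        ],
    )
    def test_labels(self, r, label):
        assert effect_label(r) == label

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            effect_label(1.2)


class TestRocCurve:
    def test_perfect_separation_reaches_corner(self):
        roc = roc_curve([3.0, 4.0, 5.0], [0.0, 1.0, 2.0])
        assert roc.auc_u == 1.0
        corner = np.any((roc.fpr == 0) & (roc.tpr == 1))
        assert corner and roc.orientation == "high"

    def test_monotone_sweep_with_unit_endpoints(self, rng):
        roc = roc_curve(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)
        assert (roc.tpr[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (1.0, 1.0)

    def test_identical_distributions_give_half_auc(self, rng):
        roc = roc_curve(rng.normal(size=800), rng.normal(size=800))
        assert roc.auc_u == pytest.approx(0.5, abs=0.03)

    def test_trapezoid_equals_u_based_auc_on_tie_free_data(self, rng):
        for _ in range(100):
            d = rng.normal(0.5, 1, size=rng.integers(5, 30))
            h = rng.normal(0.0, 1, size=rng.integers(5, 30))
            roc = roc_curve(d, h)
            assert roc.auc_trapezoid == pytest.approx(roc.auc_u, abs=1e-9)

    def test_agrees_with_sklearn(self, rng):
        d, h = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        roc = roc_curve(d, h)
        skl = roc_auc_score(np.r_[np.ones(50), np.zeros(60)], np.r_[d, h])
        assert roc.auc_u == pytest.approx(max(skl, 1 - skl), abs=1e-12)

    def test_all_identical_scores_degenerate(self):
        with pytest.raises(DegenerateROCError):
            roc_curve([1.0, 1.0], [1.0, 1.0])


def brute_force_threshold(d, h, orient):
    """Exhaustive scan over every midpoint/sentinel candidate threshold."""
    pooled = np.unique(np.r_[d, h])
    gap = max(pooled[-1] - pooled[0], 1.0)
    cands = np.r_[pooled[0] - gap, (pooled[:-1] + pooled[1:]) / 2, pooled[-1] + gap]
    best = -1.0
    for thr in cands:
        if orient == "high":
            tpr, fpr = np.mean(d >= thr), np.mean(h >= thr)
        else:
            tpr, fpr = np.mean(d <= thr), np.mean(h <= thr)
        best = max(best, np.sqrt(tpr * (1 - fpr)))
    return best


class TestOptimalThreshold:
    def test_complete_separation_gap_midpoint(self):
        roc = roc_curve([1.0, 2.0], [3.0, 4.0])
        thr, g = optimal_threshold(roc)
        assert g == pytest.approx(1.0)
        assert thr == pytest.approx(2.5)
        assert roc.orientation == "low"

    def test_single_point_cohorts(self):
        thr, g = optimal_threshold(roc_curve([0.0], [1.0]))
        assert (thr, g) == (0.5, 1.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            d = rng.normal(0.8, 1, size=rng.integers(3, 25))
            h = rng.normal(0.0, 1, size=rng.integers(3, 25))
            roc = roc_curve(d, h)
            _, g = optimal_threshold(roc)
            assert g == pytest.approx(brute_force_threshold(d, h, roc.orientation), abs=1e-12)

    def test_reported_g_dominates_every_candidate(self, rng):
        d, h = rng.normal(0.5, 1, 20), rng.normal(0, 1, 25)
        roc = roc_curve(d, h)
        _, g = optimal_threshold(roc)
        assert np.all(g >= np.sqrt(roc.tpr * (1 - roc.fpr)) - 1e-12)


class TestConfusion:
    def test_one_of_56_false_negatives(self):
        d = np.r_[np.full(55, 10.0), 0.0]  # one diabetic below threshold
        h = np.full(70, 1.0)
        tp, fn, tn, fp = confusion(d, h, 5.0, "high")
        assert (tp, fn) == (98.21, 1.79)

    def test_two_of_70_false_positives(self):
        d = np.full(56, 10.0)
        h = np.r_[np.full(68, 1.0), 8.0, 9.0]
        tp, fn, tn, fp = confusion(d, h, 5.0, "high")
        assert (tn, fp) == (97.14, 2.86)

    def test_threshold_below_everything(self, rng):
        d, h = rng.normal(size=10) + 10, rng.normal(size=10) + 10
        tp, fn, tn, fp = confusion(d, h, -100.0, "high")
        assert (tp, fp) == (100.0, 100.0) and (fn, tn) == (0.0, 0.0)

    def test_complements_sum_to_100(self, rng):
        d, h = rng.normal(size=37), rng.normal(size=23)
        tp, fn, tn, fp = confusion(d, h, 0.1, "low")
        assert tp + fn == pytest.approx(100.0, abs=0.011)
        assert tn + fp == pytest.approx(100.0, abs=0.011)


class TestOrientationInvariance:
    def test_negated_scores_flip_orientation_only(self, rng):
        d, h = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        a, b = roc_curve(d, h), roc_curve(-d, -h)
        assert {a.orientation, b.orientation} == {"high", "low"}
        assert a.auc_u == pytest.approx(b.auc_u, abs=1e-12)
        thr_a, g_a = optimal_threshold(a)
        thr_b, g_b = optimal_threshold(b)
        assert g_a == pytest.approx(g_b, abs=1e-12)
        assert confusion(d, h, thr_a, a.orientation) == confusion(-d, -h, thr_b, b.orientation)


class TestCompareCohorts:
    def _table(self, rng, shift=0.0, n=30, cols=("AB", "Ra")):
        return pd.DataFrame({c: rng.normal(shift, 1, size=n) for c in cols})

    def test_copied_cohorts_are_random_classifiers(self, rng):
        t = self._table(rng)
        out = compare_cohorts(t, t.copy())
        assert np.allclose(out["AUC"], 0.5, atol=1e-12)
        assert out["THR"].isna().all()

    def test_small_effect_rows_have_blank_threshold_cells(self, rng):
        d = pd.DataFrame({"weak": rng.normal(0.05, 1, 200), "strong": rng.normal(3, 1, 200)})
        h = pd.DataFrame({"weak": rng.normal(0.0, 1, 200), "strong": rng.normal(0, 1, 200)})
        out = compare_cohorts(d, h).set_index("parameter")
        assert out.loc["weak", "effect"] in ("very small", "small")
        assert np.isnan(out.loc["weak", "THR"])
        assert out.loc["strong", "effect"] == "large"
        assert np.isfinite(out.loc["strong", "THR"])
        assert out.loc["strong", "SE"] == out.loc["strong", "TP_pct"]

    def test_auc_identity_on_every_row(self, rng):
        d, h = self._table(rng, 0.5), self._table(rng)
        out = compare_cohorts(d, h)
        np.testing.assert_allclose(out["AUC"], (1 + out["r"]) / 2, atol=1e-12)

    def test_non_finite_values_dropped_with_warning(self, rng):
        d, h = self._table(rng, 1.0), self._table(rng)
        d.loc[0, "AB"] = np.nan
        with pytest.warns(UserWarning, match="non-finite"):
            out = compare_cohorts(d, h)
        assert np.isfinite(out.set_index("parameter").loc["AB", "AUC"])


class TestCorrelateWithBi:
    def test_exact_line_has_unit_r_squared(self):
        x = np.linspace(1, 10, 20)
        res = correlate_with_bi(x, 10 ** (2 * x + 1), transform=("identity", "log10"))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_axis_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_with_bi([1, 2, 3], [5.0, 5.0, 5.0], transform=("identity", "identity"))

    def test_nonpositive_under_log_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            correlate_with_bi([1, 2, 3], [1.0, -1.0, 2.0])

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 1, 100)
        y = 1.5 * x + 0.3 + rng.normal(0, 0.1, 100)
        res = correlate_with_bi(x, y, transform=("identity", "identity"))
        # closed-form OLS oracle
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.slope == pytest.approx(beta[0], abs=1e-10)
        assert res.intercept == pytest.approx(beta[1], abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
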