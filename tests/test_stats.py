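"""Diagnostic statistics against independent oracles.

The ROC/AUC and Youden machinery is checked against brute-force all-pairs
rank counting and exhaustive threshold scans; the logistic IRLS fit against
a hand-written Newton-Raphson solver and statsmodels; AUC additionally
against scikit-learn.
"""

import numpy as np
import pytest
from scipy import stats as sps

from ventriculometry import (
    chi_squared_proportions,
    compare_groups,
    confusion_metrics,
    logistic_fit,
    normality_check,
    roc_curve,
)
from ventriculometry.errors import (
    CollinearityError,
    DegenerateLabelsError,
    DegenerateTableError,
    InvalidScoreError,
    SeparationWarning,
    UndefinedRateError,
    UnsupportedSizeError,
)

from conftest import brute_force_auc


# ---------------------------------------------------------------------------
# oracles


def exhaustive_youden(scores, labels):
    """Scan every midpoint/sentinel threshold for max J = tpr - fpr.

    Counts are kept as exact rationals so mathematically tied J values are
    recognised as ties; ties broken by highest sensitivity, then lowest
    cutoff — all independent of the implementation's sweep machinery.
    """
    from fractions import Fraction

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    distinct = np.unique(scores)
    span = distinct[-1] - distinct[0]
    pad = span / 2 if span > 0 else max(1.0, abs(distinct[0]) / 2)
    cands = np.concatenate(
        [[distinct[0] - pad], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + pad]]
    )
    best = None
    for t in cands:
        pred = scores > t
        tpr = Fraction(int((pred & labels).sum()), n_pos)
        fpr = Fraction(int((pred & ~labels).sum()), n_neg)
        key = (tpr - fpr, tpr, -t)  # maximize J, then sens, then prefer low t
        if best is None or key > best[0]:
            best = (key, t, float(tpr - fpr))
    return best[1], best[2]


def newton_logistic(y, X, tol=1e-12, max_iter=200):
    """Independent Newton-Raphson MLE on the same design (with intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = Xd.T @ (y - mu)
        hess = (Xd.T * (mu * (1 - mu))) @ Xd
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# ROC / AUC


class TestROC:
    def test_perfect_separation_auc(self):
        assert roc_curve([0.3, 0.4, 0.1, 0.2], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_identical_distributions_half_credit(self):
        assert roc_curve([0.1, 0.2, 0.1, 0.2], [1, 1, 0, 0]).auc == pytest.approx(0.5)

    def test_interleaved_sample_matches_pair_counting(self):
        r = roc_curve([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)  # 3 wins of 4 pairs
        assert r.auc == pytest.approx(
            brute_force_auc([0.3, 0.1], [0.2, 0.05]), abs=1e-12
        )

    def test_auc_equals_rank_statistic_random_samples(self):
        """Trapezoid AUC == U/(n1*n2) with half-ties, including tied scores."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = rng.integers(2, 50, 2)
            # coarse grid forces ties between and within classes
            pos = rng.choice(np.linspace(0, 1, 11), n1)
            neg = rng.choice(np.linspace(0, 1, 11), n2)
            scores = np.concatenate([pos, neg])
            labels = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
            r = roc_curve(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_auc_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.normal(size=200) + np.repeat([1.0, 0.0], 100)
        labels = np.repeat([True, False], 100)
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        a0 = roc_curve(scores, labels).auc
        assert roc_curve(np.exp(scores), labels).auc == pytest.approx(a0, abs=1e-12)
        assert roc_curve(3 * scores - 7, labels).auc == pytest.approx(a0, abs=1e-12)

    def test_label_swap_complements_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = roc_curve(scores, labels).auc
        assert roc_curve(scores, ~labels).auc == pytest.approx(1 - a, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([0.1, 0.2], [1, 1])
        with pytest.raises(InvalidScoreError):
            roc_curve([0.1, np.nan], [1, 0])

    def test_binormal_limit(self):
        """Empirical AUC approaches Phi(dmu / sqrt(s1^2 + s2^2)) for Gaussian arms."""
        rng = np.random.default_rng(19)
        n = 100_000
        pos = rng.normal(0.332, 0.04, n)
        neg = rng.normal(0.234, 0.02, n)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        expected = sps.norm.cdf((0.332 - 0.234) / np.hypot(0.04, 0.02))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=0.005)


class TestYouden:
    def test_perfect_separation_cutoff_is_midpoint(self):
        r = roc_curve([0.4, 0.5, 0.1, 0.2], [1, 1, 0, 0])
        assert r.optimal_cutoff == pytest.approx(0.3)
        assert r.youden_j == pytest.approx(1.0)

    def test_no_discrimination_returns_low_sentinel(self):
        r = roc_curve([0.7, 0.7, 0.7, 0.7], [1, 1, 0, 0])
        assert r.degenerate
        assert r.youden_j == pytest.approx(0.0)
        assert r.optimal_cutoff < 0.7  # below-minimum sentinel

    def test_matches_exhaustive_scan(self):
        r = roc_curve([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0])
        cutoff, j = exhaustive_youden([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0])
        assert r.optimal_cutoff == pytest.approx(cutoff)
        assert r.youden_j == pytest.approx(j)

    def test_matches_exhaustive_scan_random(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, 2)
            scores = np.concatenate(
                [rng.choice(np.linspace(0, 1, 9), n1) + 0.1,
                 rng.choice(np.linspace(0, 1, 9), n2)]
            )
            labels = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
            r = roc_curve(scores, labels)
            cutoff, j = exhaustive_youden(scores, labels)
            assert r.youden_j == pytest.approx(j, abs=1e-12)
            assert r.optimal_cutoff == pytest.approx(cutoff, abs=1e-12)

    def test_cutoff_reproduces_recorded_operating_point(self):
        """Classifying at the returned cutoff re-yields the recorded tpr/fpr."""
        rng = np.random.default_rng(29)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 40)])
        labels = np.concatenate([np.ones(30, bool), np.zeros(40, bool)])
        r = roc_curve(scores, labels)
        pred = scores > r.optimal_cutoff
        m = r.metrics_at_cutoff
        assert (pred & labels).sum() == m.tp
        assert (pred & ~labels).sum() == m.fp


# ---------------------------------------------------------------------------
# confusion metrics


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((34, 1, 39, 0), (97.1, 100.0, 98.6)),
            ((33, 2, 34, 5), (94.3, 87.2, 90.5)),
        ],
    )
    def test_reported_percentages(self, counts, expected):
        pc = confusion_metrics(*counts).as_percent()
        assert (
            pc["sensitivity_pct"], pc["specificity_pct"], pc["accuracy_pct"]
        ) == expected

    def test_empty_margins_are_undefined(self):
        with pytest.raises(UndefinedRateError, match="sensitivity"):
            confusion_metrics(0, 0, 10, 0)
        with pytest.raises(UndefinedRateError, match="specificity"):
            confusion_metrics(5, 5, 0, 0)


# ---------------------------------------------------------------------------
# normality gate and group comparisons


class TestNormalityAndComparisons:
    def test_shapiro_range(self):
        with pytest.raises(UnsupportedSizeError):
            normality_check([1.0, 2.0])
        with pytest.raises(UnsupportedSizeError):
            normality_check(np.zeros(5001))

    def test_shapiro_on_normal_quantiles_passes(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, p = normality_check(q)
        assert p > 0.05
        # agrees with the scipy reference implementation it delegates to
        assert (w, p) == pytest.approx(tuple(sps.shapiro(q)))

    def test_shapiro_rejects_bimodal(self):
        jitter = 0.01 * sps.norm.ppf((np.arange(1, 26) - 0.5) / 25)
        x = np.concatenate([-3 + jitter, 3 + jitter])
        _, p = normality_check(x)
        assert p < 0.05

    def test_identical_groups_sit_at_null(self):
        a = np.arange(1.0, 21.0)
        res = compare_groups(a, a, "x")
        assert res.test == "t_test"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value >= 0.99

    def test_normal_shifted_groups_use_t_test(self):
        q = sps.norm.ppf((np.arange(1, 16) - 0.5) / 15)
        res = compare_groups(q, q + 2, "x")
        assert res.test == "t_test"
        assert res.p_value < 0.01
        assert all(p > 0.05 for p in res.normality_p)

    def test_skewed_groups_use_mann_whitney_with_correct_u(self):
        # heavy right skew in both groups fails the normality gate
        a = np.array([0.1, 0.2, 0.2, 0.3, 0.4, 0.5, 1.0, 3.0, 9.0, 30.0, 90.0, 300.0])
        b = np.array([0.1, 0.1, 0.2, 0.4, 0.6, 0.8, 2.0, 6.0, 20.0, 60.0, 200.0, 700.0])
        res = compare_groups(a, b, "x")
        assert res.test == "mann_whitney"
        u_brute = sum(
            float(x > y) + 0.5 * float(x == y) for x in a for y in b
        )
        assert res.statistic == pytest.approx(u_brute)

    def test_undersized_group_rejected(self):
        with pytest.raises(UnsupportedSizeError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChiSquared:
    def test_sex_table_p_value(self):
        """25/10 vs 15/24 males: p rounds to 0.004 without continuity correction."""
        res = chi_squared_proportions([[25, 10], [15, 24]], "sex")
        assert round(res.p_value, 3) == 0.004

    def test_identical_proportions_null(self):
        res = chi_squared_proportions([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a, b, c, d = 5, 15, 12, 8
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = chi_squared_proportions([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_proportions([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# logistic regression


class TestLogistic:
    def test_balanced_covariate_has_zero_coefficient(self):
        """Outcome independent of a balanced binary covariate: exact zero MLE."""
        y = np.array([1.0] * 25 + [0.0] * 25 + [1.0] * 25 + [0.0] * 25)
        x = np.array([0.0] * 50 + [1.0] * 50)
        fit = logistic_fit(y, x, names=("intercept", "stratum"))
        assert fit.converged and not fit.separation_detected
        assert abs(fit.coef("stratum")) < 1e-6

    def test_matches_newton_raphson_oracle(self):
        # interleaved outcomes: overlapping classes, no separation
        y = np.array([0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0], float)
        X = np.column_stack(
            [
                [70, 62, 75, 66, 71, 80, 68, 77, 73, 64, 78, 69],  # age-like
                [1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0],  # sex-like
            ]
        )
        fit = logistic_fit(y, X, names=("intercept", "age", "sex"))
        oracle = newton_logistic(y, X)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        X = np.column_stack([rng.normal(70, 8, 80), rng.random(80) < 0.5])
        eta = -10 + 0.15 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_fit(y, X, names=("intercept", "age", "sex"))
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-5)

    def test_perfect_separation_is_flagged(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)])
        with pytest.warns(SeparationWarning):
            fit = logistic_fit(y, x)
        assert fit.separation_detected

    def test_constant_covariate_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(CollinearityError):
            logistic_fit(y, np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(UnsupportedSizeError):
            logistic_fit(np.array([0.0, 1.0] * 4), np.arange(8.0))
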