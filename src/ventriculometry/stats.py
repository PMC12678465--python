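"""Diagnostic-accuracy statistics.

ROC analysis with Youden-optimal cutoff selection, confusion metrics,
normality-gated two-group comparisons, chi-squared for proportions, and
age/sex-adjusted logistic regression with separation detection.

Conventions
-----------
* The positive class is iNPH; higher index values are more iNPH-like, and a
  subject is called positive when ``score > threshold`` (strict).
* ROC threshold candidates are the midpoints between consecutive distinct
  sorted scores, plus a sentinel below the minimum and one above the maximum,
  which yields the same confusion counts as thresholding at observed values
  while remaining stable under ties.
* AUC is the trapezoid of the (FPR, TPR) curve; for finite samples this
  equals the Mann-Whitney statistic U/(n1*n2) with ties half-credited.
* Group comparisons follow a Shapiro-Wilk gate at alpha = 0.05: both groups
  normal -> unpaired t-test; otherwise Mann-Whitney U with the tie-corrected
  normal approximation (no exact enumeration, no continuity correction).
* Chi-squared is Pearson's without Yates continuity correction, df = 1.
* Logistic regression is maximum likelihood via IRLS (max 100 iterations,
  convergence when max |delta beta| < 1e-8) with Wald p-values; separation is
  flagged when any standardized coefficient magnitude exceeds 15 or the
  likelihood stabilizes while the coefficients keep growing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateLabelsError,
    DegenerateTableError,
    InvalidScoreError,
    SeparationWarning,
    UndefinedRateError,
    UnsupportedSizeError,
)

__all__ = [
    "ConfusionMetrics",
    "ROCResult",
    "YoudenCutoff",
    "ComparisonResult",
    "LogisticFit",
    "roc_curve",
    "youden_optimal",
    "confusion_metrics",
    "normality_check",
    "compare_groups",
    "chi_squared_proportions",
    "logistic_fit",
    "round_half_up",
]

_ALPHA_NORMALITY = 0.05
_SHAPIRO_MIN, _SHAPIRO_MAX = 3, 5000


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at `ndigits` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and rates of a 2x2 classification of positives (iNPH) vs negatives."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float

    def as_percent(self) -> dict[str, float]:
        """Rates as percentages rounded half-up to one decimal (report style)."""
        return {
            "sensitivity_pct": round_half_up(100 * self.sensitivity),
            "specificity_pct": round_half_up(100 * self.specificity),
            "accuracy_pct": round_half_up(100 * self.accuracy),
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Sensitivity, specificity and accuracy from 2x2 confusion counts.

    Raises :class:`UndefinedRateError` when the positive (tp+fn) or negative
    (tn+fp) margin is empty, naming the undefined rate.
    """
    counts = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
    for name, c in counts.items():
        if c < 0 or c != int(c):
            raise UndefinedRateError(f"count {name}={c}; counts must be non-negative integers")
    tp, fn, tn, fp = (int(c) for c in (tp, fn, tn, fp))
    if tp + fn == 0:
        raise UndefinedRateError("sensitivity")
    if tn + fp == 0:
        raise UndefinedRateError("specificity")
    return ConfusionMetrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + fn + tn + fp),
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class YoudenCutoff:
    """The Youden-optimal operating point of a ROC curve."""

    cutoff: float
    youden_j: float
    metrics: ConfusionMetrics
    degenerate: bool  # True when no threshold discriminates (max J = 0)


@dataclass(frozen=True)
class ROCResult:
    """A full ROC sweep with its Youden-optimal operating point.

    ``thresholds`` are in descending order, so the (fpr, tpr) curve runs from
    (0, 0) to (1, 1); ``tp_counts``/``fp_counts`` are the raw counts at each
    threshold under the strict ``score > threshold`` rule.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tp_counts: np.ndarray
    fp_counts: np.ndarray
    n_pos: int
    n_neg: int
    auc: float
    optimal_cutoff: float = field(default=math.nan)
    youden_j: float = field(default=math.nan)
    metrics_at_cutoff: ConfusionMetrics | None = field(default=None)
    degenerate: bool = field(default=False)


def roc_curve(scores, labels) -> ROCResult:
    """ROC sweep of an index against binary labels (iNPH = positive = True).

    Thresholds are midpoints between consecutive distinct scores plus
    below-minimum and above-maximum sentinels; AUC is the trapezoid of the
    (fpr, tpr) curve.  The Youden-optimal operating point is attached.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidScoreError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise InvalidScoreError("scores contain non-finite values")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes must be present to build a ROC curve")

    distinct = np.unique(scores)  # ascending
    span = distinct[-1] - distinct[0]
    pad = span / 2 if span > 0 else max(1.0, abs(distinct[0]) / 2)
    # descending thresholds: above-max sentinel, midpoints, below-min sentinel
    mids_desc = ((distinct[:-1] + distinct[1:]) / 2)[::-1]
    thresholds = np.concatenate([[distinct[-1] + pad], mids_desc, [distinct[0] - pad]])

    # counts of positives/negatives at each distinct score (ascending)
    idx = np.searchsorted(distinct, scores)
    pos_at = np.bincount(idx[labels], minlength=distinct.size)
    neg_at = np.bincount(idx[~labels], minlength=distinct.size)
    # subjects called positive at threshold between distinct[i-1] and distinct[i]
    # are those with score >= distinct[i]: suffix sums, reversed to descending
    tp_counts = np.concatenate([[0], np.cumsum(pos_at[::-1])])
    fp_counts = np.concatenate([[0], np.cumsum(neg_at[::-1])])
    tpr = tp_counts / n_pos
    fpr = fp_counts / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    roc = ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        tp_counts=tp_counts,
        fp_counts=fp_counts,
        n_pos=n_pos,
        n_neg=n_neg,
        auc=auc,
    )
    best = youden_optimal(roc)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        tp_counts=tp_counts,
        fp_counts=fp_counts,
        n_pos=n_pos,
        n_neg=n_neg,
        auc=auc,
        optimal_cutoff=best.cutoff,
        youden_j=best.youden_j,
        metrics_at_cutoff=best.metrics,
        degenerate=best.degenerate,
    )


def youden_optimal(roc: ROCResult) -> YoudenCutoff:
    """Threshold maximizing Youden's J = TPR - FPR.

    Ties are broken by highest sensitivity, then lowest cutoff; when no
    threshold discriminates (max J = 0) the below-minimum sentinel is
    returned with the degenerate flag set.
    """
    j = roc.tpr - roc.fpr
    jmax = float(j.max())
    cand = np.flatnonzero(j >= jmax - 1e-12)
    # highest sensitivity, then lowest cutoff; thresholds descend, so the
    # last qualifying candidate wins both tie-breaks
    cand = cand[roc.tpr[cand] >= roc.tpr[cand].max() - 1e-12]
    k = int(cand[-1])
    tp = int(roc.tp_counts[k])
    fp = int(roc.fp_counts[k])
    metrics = confusion_metrics(tp=tp, fn=roc.n_pos - tp, tn=roc.n_neg - fp, fp=fp)
    return YoudenCutoff(
        cutoff=float(roc.thresholds[k]),
        youden_j=jmax,
        metrics=metrics,
        degenerate=bool(jmax <= 1e-12),
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class ComparisonResult:
    """One comparison-table row: per-group summaries, the test used, its result."""

    variable: str
    summary_a: str
    summary_b: str
    test: str  # t_test | mann_whitney | chi_squared
    statistic: float
    p_value: float
    normality_p: tuple[float, float] | None = None
    n_a: int = 0
    n_b: int = 0


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation via scipy), 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not (_SHAPIRO_MIN <= x.size <= _SHAPIRO_MAX):
        raise UnsupportedSizeError(
            f"Shapiro-Wilk supports {_SHAPIRO_MIN} <= n <= {_SHAPIRO_MAX}, got n={x.size}"
        )
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _gate_sample(x: np.ndarray) -> np.ndarray:
    """Deterministic subsample for the normality gate when n exceeds 5000."""
    if x.size <= _SHAPIRO_MAX:
        return x
    rng = np.random.default_rng(0)
    return rng.choice(x, size=_SHAPIRO_MAX, replace=False)


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.2g}"


def compare_groups(a, b, variable: str = "value") -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk normality gate at alpha = 0.05.

    Both groups normal -> two-sided unpaired t-test; otherwise two-sided
    Mann-Whitney U with the tie-corrected normal approximation.  Each group
    needs n >= 3 (the Shapiro-Wilk minimum).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise UnsupportedSizeError(
            f"each group needs n >= 3 for the normality gate, got {a.size} and {b.size}"
        )
    _, pa = normality_check(_gate_sample(a))
    _, pb = normality_check(_gate_sample(b))
    if pa > _ALPHA_NORMALITY and pb > _ALPHA_NORMALITY:
        stat, p = sps.ttest_ind(a, b)
        test = "t_test"
    else:
        stat, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        test = "mann_whitney"
    return ComparisonResult(
        variable=variable,
        summary_a=_mean_sd(a),
        summary_b=_mean_sd(b),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        normality_p=(pa, pb),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def chi_squared_proportions(table, variable: str = "proportion") -> ComparisonResult:
    """Pearson chi-squared on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DegenerateTableError(f"expected a non-negative 2x2 table, got {t!r}")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("2x2 table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)

    def _pct(row):
        return f"{int(row[0])} ({round_half_up(100 * row[0] / row.sum())}%)"

    return ComparisonResult(
        variable=variable,
        summary_a=_pct(t[0]),
        summary_b=_pct(t[1]),
        test="chi_squared",
        statistic=float(chi2),
        p_value=float(p),
        n_a=int(t[0].sum()),
        n_b=int(t[1].sum()),
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    When ``separation_detected`` is True the coefficients diverge and the
    reported p-values are unreliable (a :class:`SeparationWarning` is issued).
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation_detected: bool
    n_iterations: int
    log_likelihood: float

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


_MAX_ITER = 100
_TOL = 1e-8
_SEPARATION_STD_COEF = 15.0


def logistic_fit(outcome, covariates, names: tuple[str, ...] | None = None) -> LogisticFit:
    """Logistic regression of a binary outcome on covariates, with intercept.

    Fit by iteratively reweighted least squares, at most 100 iterations,
    converged when max |delta beta| < 1e-8.  Separation is flagged (and a
    :class:`SeparationWarning` issued) when any standardized coefficient
    magnitude exceeds 15 or the log-likelihood stabilizes while coefficients
    keep growing; non-convergence without separation raises
    :class:`ConvergenceError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.size:
        raise CollinearityError("outcome and covariates have incompatible shapes")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise CollinearityError("outcome must be binary 0/1")
    if y.size < 10:
        raise UnsupportedSizeError(f"logistic fit needs n >= 10, got n={y.size}")
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        raise CollinearityError(f"covariate column {j} is constant")
    if names is None:
        names = ("intercept",) + tuple(f"x{j}" for j in range(X.shape[1]))
    else:
        names = tuple(names)
        if len(names) != X.shape[1] + 1:
            raise CollinearityError("names must cover intercept plus each covariate")

    from scipy.special import expit

    Xd = np.column_stack([np.ones(y.size), X])
    beta = np.zeros(Xd.shape[1])
    ll_prev = -np.inf
    converged = False
    ll_stalled = False
    diverged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtW = Xd.T * w
        try:
            delta = np.linalg.solve(XtW @ Xd, Xd.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular information matrix: {exc}") from exc
        beta = beta + delta
        eta = Xd @ beta
        ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
        if np.max(np.abs(delta)) < _TOL:
            converged = True
            ll_prev = ll
            break
        if np.any(np.abs(beta[1:]) * sds > _SEPARATION_STD_COEF):
            diverged = True  # standardized coefficient already past the bound
            ll_prev = ll
            break
        if abs(ll - ll_prev) < 1e-10 and np.max(np.abs(delta)) > 1e-3:
            ll_stalled = True  # likelihood flat but coefficients still drifting
            ll_prev = ll
            break
        ll_prev = ll

    std_coef = np.abs(beta[1:]) * sds
    separation = bool(np.any(std_coef > _SEPARATION_STD_COEF) or ll_stalled or diverged)
    if not converged and not separation:
        raise ConvergenceError(
            f"IRLS did not converge in {_MAX_ITER} iterations and no separation detected"
        )
    if separation:
        warnings.warn(
            "separation detected: coefficients diverge and Wald p-values are unreliable",
            SeparationWarning,
            stacklevel=2,
        )

    eta = Xd @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((Xd.T * w) @ Xd)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return LogisticFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        wald_z=z,
        p_values=p,
        converged=converged,
        separation_detected=separation,
        n_iterations=n_iter,
        log_likelihood=ll_prev,
    )
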