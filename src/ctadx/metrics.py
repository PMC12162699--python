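"""Diagnostic-accuracy metrics, Wilson intervals and paired between-rule tests.

Point estimates come straight from a confusion matrix.  The AUC of a binary
classifier is defined as the area of its two-point ROC curve,
``(sensitivity + specificity) / 2``; this matches the published AUCs when
recomputed from the published count tables.

Paired comparisons (same patients classified by two rules):

* sensitivity / specificity — exact McNemar binomial test on the discordant
  pairs within the reference-positive (resp. -negative) stratum;
* PPV / NPV — generalized score statistic for paired predictive values
  (each patient contributes its test-positive / test-negative records, with
  a robust cluster variance);
* AUC — normal test on ``(dSe + dSp)/2`` with the paired-difference
  variance of each stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .rules import ConfusionMatrix

__all__ = [
    "MetricEstimate",
    "DiagnosticReport",
    "PairedTestResult",
    "metrics_from_cm",
    "wilson_interval",
    "compare_sensitivity",
    "compare_specificity",
    "compare_predictive_values",
    "compare_auc_binary",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation rounding for percents/AUC)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type estimate with a two-sided confidence interval.

    ``defined`` is False when the denominator was zero; then ``value`` and
    the CI are None.
    """

    value: Optional[float]
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci": None if not self.defined else [self.ci_lower, self.ci_upper],
            "defined": self.defined,
        }


@dataclass(frozen=True)
class DiagnosticReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate
    youden_j: Optional[float]
    auc: MetricEstimate
    n: int
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "ppv": self.ppv.to_dict(),
            "npv": self.npv.to_dict(),
            "accuracy": self.accuracy.to_dict(),
            "youden_j": self.youden_j,
            "auc": self.auc.to_dict(),
            "n": self.n,
            "ci_level": self.ci_level,
        }

    def rounded(self) -> dict:
        """Presentation rounding: integer percents, 2-dp AUC."""

        def pct(est: MetricEstimate):
            if not est.defined:
                return None
            return {
                "value": int(round_half_away(100.0 * est.value)),
                "ci": [
                    int(round_half_away(100.0 * est.ci_lower)),
                    int(round_half_away(100.0 * est.ci_upper)),
                ],
            }

        out = {
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv),
            "npv": pct(self.npv),
            "accuracy": pct(self.accuracy),
        }
        if self.auc.defined:
            out["auc"] = {
                "value": round_half_away(self.auc.value, 2),
                "ci": [
                    round_half_away(self.auc.ci_lower, 2),
                    round_half_away(self.auc.ci_upper, 2),
                ],
            }
        else:
            out["auc"] = None
        return out


def wilson_interval(successes: int, trials: int, level: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Bounds lie in [0, 1] and always bracket the point estimate.
    """
    if trials <= 0:
        raise ValueError(f"trials must be > 0, got {trials}")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes must be in [0, trials], got {successes}/{trials}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / trials
    n = trials
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # mathematically the Wilson bounds always bracket p; guard against
    # floating-point rounding at the boundaries
    lo = min(max(0.0, centre - half), p)
    hi = max(min(1.0, centre + half), p)
    return (lo, hi)


def _estimate(successes: int, trials: int, level: float) -> MetricEstimate:
    if trials == 0:
        return MetricEstimate(value=None, defined=False)
    lo, hi = wilson_interval(successes, trials, level)
    return MetricEstimate(value=successes / trials, ci_lower=lo, ci_upper=hi)


def metrics_from_cm(cm: ConfusionMatrix, ci_level: float = 0.95) -> DiagnosticReport:
    """Full diagnostic report from a confusion matrix.

    Metrics with a zero denominator are flagged undefined rather than
    raising; Youden's J and the AUC are undefined whenever sensitivity or
    specificity is.
    """
    if cm.n <= 0:
        raise ValueError("confusion matrix has no observations")
    se = _estimate(cm.tp, cm.tp + cm.fn, ci_level)
    sp = _estimate(cm.tn, cm.tn + cm.fp, ci_level)
    ppv = _estimate(cm.tp, cm.tp + cm.fp, ci_level)
    npv = _estimate(cm.tn, cm.tn + cm.fn, ci_level)
    acc = _estimate(cm.tp + cm.tn, cm.n, ci_level)
    if se.defined and sp.defined:
        youden = se.value + sp.value - 1.0
        # two-point ROC area; CI by combining the independent binomial
        # variances of Se and Sp (normal approximation)
        auc_point = (se.value + sp.value) / 2.0
        var_se = se.value * (1.0 - se.value) / (cm.tp + cm.fn)
        var_sp = sp.value * (1.0 - sp.value) / (cm.tn + cm.fp)
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        half = z * math.sqrt((var_se + var_sp) / 4.0)
        auc = MetricEstimate(
            value=auc_point,
            ci_lower=max(0.0, auc_point - half),
            ci_upper=min(1.0, auc_point + half),
        )
    else:
        youden = None
        auc = MetricEstimate(value=None, defined=False)
    return DiagnosticReport(
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        youden_j=youden,
        auc=auc,
        n=cm.n,
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a paired between-rule test."""

    p_value: float
    statistic: Optional[float] = None
    n_discordant: Optional[int] = None
    degenerate: bool = False  # no information (e.g. zero discordant pairs)

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "statistic": self.statistic,
            "n_discordant": self.n_discordant,
            "degenerate": self.degenerate,
        }


def _check_paired(a, b, labels):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == labels.shape) or a.ndim != 1:
        raise ValueError("a, b and labels must be 1-D arrays of equal length")
    return a, b, labels


def _mcnemar_exact(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    """Exact two-sided binomial McNemar test on paired binary calls."""
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    nd = b + c
    if nd == 0:
        return PairedTestResult(p_value=1.0, statistic=0.0, n_discordant=0, degenerate=True)
    p = 2.0 * stats.binom.cdf(min(b, c), nd, 0.5)
    return PairedTestResult(
        p_value=min(1.0, float(p)), statistic=float(b - c), n_discordant=nd
    )


def compare_sensitivity(a, b, labels) -> PairedTestResult:
    """McNemar exact test of equal sensitivity, restricted to reference-positives."""
    a, b, labels = _check_paired(a, b, labels)
    if not labels.any():
        raise ValueError("no reference-positive patients")
    return _mcnemar_exact(a[labels], b[labels])


def compare_specificity(a, b, labels) -> PairedTestResult:
    """McNemar exact test of equal specificity, restricted to reference-negatives."""
    a, b, labels = _check_paired(a, b, labels)
    if labels.all():
        raise ValueError("no reference-negative patients")
    neg = ~labels
    # a negative call is the "success" for specificity
    return _mcnemar_exact(~a[neg], ~b[neg])


def _generalized_score(x1: np.ndarray, x2: np.ndarray, outcome: np.ndarray) -> PairedTestResult:
    """Generalized score test of equal E[outcome | record selected].

    ``x1``/``x2`` select each patient's record under rule 1 / rule 2 (e.g.
    test-positive indicators for the PPV comparison); ``outcome`` is the
    shared per-patient response.  The pooled estimate under H0 weights by
    record counts; the variance is the robust sum of squared per-patient
    score contributions.
    """
    total_sel = int(np.sum(x1) + np.sum(x2))
    if total_sel == 0:
        return PairedTestResult(p_value=1.0, statistic=None, n_discordant=0, degenerate=True)
    pooled = float(np.sum(outcome * (x1 + x2))) / total_sel
    resid = outcome.astype(float) - pooled
    contrib = (x1.astype(float) - x2.astype(float)) * resid
    u = float(np.sum(contrib))
    v = float(np.sum(contrib * contrib))
    if v == 0.0:
        return PairedTestResult(p_value=1.0, statistic=0.0, n_discordant=0, degenerate=True)
    chi2 = u * u / v
    p = float(stats.chi2.sf(chi2, df=1))
    return PairedTestResult(p_value=p, statistic=chi2, n_discordant=int(np.sum(x1 != x2)))


def compare_predictive_values(a, b, labels) -> Tuple[PairedTestResult, PairedTestResult]:
    """Paired comparison of PPV and NPV between two rules.

    Returns ``(ppv_result, npv_result)``.  A comparison with no positive
    (resp. negative) calls under either rule is returned degenerate with
    p = 1.
    """
    a, b, labels = _check_paired(a, b, labels)
    ppv = _generalized_score(a, b, labels)
    npv = _generalized_score(~a, ~b, ~labels)
    return ppv, npv


def _paired_diff_var(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Mean and variance of a paired difference of proportions."""
    n = x.size
    d = x.astype(float) - y.astype(float)
    s = float(np.sum(d))
    ss = float(np.sum(d * d))
    mean = s / n
    var = (ss - s * s / n) / (n * n)
    return mean, var


def compare_auc_binary(a, b, labels) -> PairedTestResult:
    """Paired test of equal binary-classifier AUC (two-point ROC areas).

    dAUC = (dSe + dSp) / 2 with stratum-wise paired variances; two-sided
    normal p-value.
    """
    a, b, labels = _check_paired(a, b, labels)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    pos = labels
    neg = ~labels
    d_se, v_se = _paired_diff_var(a[pos], b[pos])
    # negative calls are the specificity successes
    d_sp, v_sp = _paired_diff_var(~a[neg], ~b[neg])
    delta = (d_se + d_sp) / 2.0
    var = (v_se + v_sp) / 4.0
    nd = int(np.sum(a[pos] != b[pos]) + np.sum(a[neg] != b[neg]))
    if var <= 0.0:
        return PairedTestResult(
            p_value=1.0 if delta == 0.0 else 0.0,
            statistic=delta,
            n_discordant=nd,
            degenerate=True,
        )
    z = delta / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return PairedTestResult(p_value=min(1.0, p), statistic=delta, n_discordant=nd)
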