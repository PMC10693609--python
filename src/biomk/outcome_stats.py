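"""Validation of biomarker areas against postsurgical seizure outcome.

A patient whose biomarker area is *not* fully inside the resected
tissue is predicted to have recurrent seizures.  With seizure freedom
defined as ILAE class 1 and recurrence as ILAE 2-6, each patient falls
into one cell of a confusion matrix:

    area not resected & recurrent  -> TP   (incomplete resection, correctly flagged)
    area not resected & seizure-free -> FP
    area resected & recurrent      -> FN
    area resected & seizure-free   -> TN

Patients whose area could not be defined (no events of that biomarker)
are excluded from that biomarker's matrix.  The five prediction metrics
carry exact Clopper-Pearson 95% confidence intervals, and accuracies of
two biomarkers are compared with a two-proportion z-test (a paired
McNemar variant is available as well).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synthetic_cohort import CohortRow

__all__ = [
    "ConfusionMatrix",
    "Metric",
    "MetricSet",
    "classify_patient",
    "confusion_matrix",
    "binom_ci_exact",
    "metrics",
    "compare_accuracy",
    "compare_accuracy_paired",
]

Classification = Literal["TP", "FP", "TN", "FN", "EXCLUDED"]

#: CohortRow attribute holding the resection flag for each biomarker.
_BIOMARKER_FLAGS = {
    "hfo": "hfo_area_resected",
    "spike": "spike_area_resected",
    "spike_hfo": "spike_hfo_area_resected",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_excluded) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of evaluable patients."""
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metric:
    """A proportion with its exact 95% CI and the defining counts."""

    value: float
    ci_lo: float
    ci_hi: float
    numerator: int
    denominator: int

    def as_percent(self) -> tuple[int, int, int]:
        """Rounded (half-up) integer percents: (value, ci_lo, ci_hi)."""
        return tuple(
            int(math.floor(100.0 * v + 0.5)) for v in (self.value, self.ci_lo, self.ci_hi)
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: Metric | None
    specificity: Metric | None
    ppv: Metric | None
    npv: Metric | None
    accuracy: Metric | None


def classify_patient(area_resected: str, ilae: int) -> Classification:
    """One patient's confusion-matrix cell from resection flag and ILAE class."""
    if not 1 <= int(ilae) <= 6:
        raise ValueError(f"ILAE class must be 1..6, got {ilae}")
    if area_resected not in ("yes", "no", "undefined"):
        raise ValueError(f"area_resected must be yes/no/undefined, got {area_resected!r}")
    if area_resected == "undefined":
        return "EXCLUDED"
    seizure_free = int(ilae) == 1
    if area_resected == "no":
        return "FP" if seizure_free else "TP"
    return "TN" if seizure_free else "FN"


def confusion_matrix(cohort: Sequence[CohortRow], biomarker: str) -> ConfusionMatrix:
    """Aggregate :func:`classify_patient` over a cohort for one biomarker."""
    if not cohort:
        raise ValueError("empty cohort")
    if biomarker not in _BIOMARKER_FLAGS:
        raise ValueError(f"biomarker must be one of {sorted(_BIOMARKER_FLAGS)}")
    attr = _BIOMARKER_FLAGS[biomarker]
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0, "EXCLUDED": 0}
    for row in cohort:
        counts[classify_patient(getattr(row, attr), row.ilae)] += 1
    return ConfusionMatrix(
        tp=counts["TP"],
        fp=counts["FP"],
        tn=counts["TN"],
        fn=counts["FN"],
        n_excluded=counts["EXCLUDED"],
    )


def binom_ci_exact(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval by beta inversion."""
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
    # statsmodels returns NaN at the boundaries where the interval is closed
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return lo, hi


def _metric(x: int, n: int, alpha: float) -> Metric | None:
    if n == 0:
        return None  # undefined denominator: flagged, never reported as 0
    lo, hi = binom_ci_exact(x, n, alpha)
    return Metric(value=x / n, ci_lo=lo, ci_hi=hi, numerator=x, denominator=n)


def metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact 95% CIs.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/N.
    """
    return MetricSet(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn, alpha),
        specificity=_metric(cm.tn, cm.tn + cm.fp, alpha),
        ppv=_metric(cm.tp, cm.tp + cm.fp, alpha),
        npv=_metric(cm.tn, cm.tn + cm.fn, alpha),
        accuracy=_metric(cm.tp + cm.tn, cm.n, alpha),
    )


def compare_accuracy(cm_a: ConfusionMatrix, cm_b: ConfusionMatrix) -> tuple[float, float]:
    """Unpaired two-proportion pooled z-test on the accuracies of two biomarkers.

    Returns (z, two-sided p).  Zero pooled variance (both accuracies 0
    or both 1) gives z = 0, p = 1.
    """
    if cm_a.n == 0 or cm_b.n == 0:
        raise ValueError("both confusion matrices must contain evaluable patients")
    x_a, n_a = cm_a.tp + cm_a.tn, cm_a.n
    x_b, n_b = cm_b.tp + cm_b.tn, cm_b.n
    p_pool = (x_a + x_b) / (n_a + n_b)
    var = p_pool * (1.0 - p_pool) * (1.0 / n_a + 1.0 / n_b)
    if var == 0.0:
        return 0.0, 1.0
    z = (x_a / n_a - x_b / n_b) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_accuracy_paired(
    cohort: Sequence[CohortRow], biomarker_a: str, biomarker_b: str
) -> tuple[float, float]:
    """Paired (McNemar, exact) comparison of per-patient prediction correctness.

    Only patients evaluable under both biomarkers contribute.  Returns
    (discordant-pair statistic, exact two-sided p).
    """
    from statsmodels.stats.contingency_tables import mcnemar

    table = [[0, 0], [0, 0]]
    for row in cohort:
        cls_a = classify_patient(getattr(row, _BIOMARKER_FLAGS[biomarker_a]), row.ilae)
        cls_b = classify_patient(getattr(row, _BIOMARKER_FLAGS[biomarker_b]), row.ilae)
        if "EXCLUDED" in (cls_a, cls_b):
            continue
        ok_a = cls_a in ("TP", "TN")
        ok_b = cls_b in ("TP", "TN")
        table[0 if ok_a else 1][0 if ok_b else 1] += 1
    res = mcnemar(table, exact=True)
    return float(res.statistic), float(res.pvalue)
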