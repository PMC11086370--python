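"""ROC/AUC diagnostics and the AUC confidence-interval design calculation.

The AUC is computed as the Mann-Whitney pair statistic
``(concordant pairs + ties/2) / (n_pos * n_neg)``, which equals the
trapezoidal area under the empirical ROC curve.  Confidence intervals come
either from the DeLong covariance estimator (default for empirical AUCs) or
from the Hanley-McNeil closed form

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg),
    Q1 = A/(2-A),  Q2 = 2A^2/(1+A),

whose closed form also drives the prospective sample-size calculation: the
expected two-sided CI width for a postulated AUC and group sizes.

The "optimum cut-off" maximises Youden's J = sensitivity + specificity - 1;
predictions at a cutoff use the rule score >= cutoff.  PPV and NPV are taken
from the observed confusion table, i.e. at the study prevalence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError
from .pipeline import CVResult, rank_sum_pvalue

__all__ = [
    "ROCCurve",
    "DiagnosticsReport",
    "auc",
    "roc_curve",
    "auc_ci",
    "hanley_mcneil_se",
    "ci_width_for_design",
    "auc_pvalue",
    "optimal_cutoff",
    "confusion_metrics",
    "build_report",
    "diagnostics_from_scores",
]


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise InputError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present")
    return pos, neg


# ---------------------------------------------------------------------- AUC


def auc(scores, labels) -> float:
    """Pair-statistic AUC: (concordant + ties/2) / (n_pos * n_neg)."""
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


@dataclass
class ROCCurve:
    """Empirical ROC: (fpr, tpr, cutoff) triples from cutoff=+inf downwards.

    Starts at (0, 0), ends at (1, 1); both rates non-decreasing; trapezoidal
    area equals the pair-statistic AUC exactly.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores, labels) -> ROCCurve:
    """One ROC point per distinct cutoff (no intermediate points dropped)."""
    _split(scores, labels)  # validates
    fpr, tpr, thresholds = _sk_roc_curve(
        np.asarray(labels, dtype=int),
        np.asarray(scores, dtype=float),
        drop_intermediate=False,
    )
    return ROCCurve(fpr=fpr, tpr=tpr, cutoffs=thresholds)


# ----------------------------------------------------- confidence intervals


def hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC of value ``a`` with ``n_pos``
    positive (case) and ``n_neg`` negative (control) samples.

    The case group carries the Q1 term; the group order matters for
    unbalanced designs.
    """
    if n_pos < 2 or n_neg < 2:
        raise InputError("both groups need at least 2 members")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via midrank placements."""
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # V10[i]: placement of positive i among negatives; V01[j]: converse
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong") -> tuple[float, float]:
    """Two-sided CI for the empirical AUC, truncated to [0, 1].

    ``delong`` (default) uses the nonparametric covariance estimator;
    ``hanley_mcneil`` the closed-form variance at the observed AUC.
    """
    pos, neg = _split(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise InputError("both classes need at least 2 members")
    a = auc(scores, labels)
    if method == "delong":
        se = math.sqrt(_delong_variance(pos, neg))
    elif method == "hanley_mcneil":
        se = hanley_mcneil_se(a, pos.size, neg.size)
    else:
        raise InputError(f"unknown CI method {method!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def ci_width_for_design(
    auc_value: float, n_pos: int, n_neg: int, level: float = 0.95
) -> float:
    """Expected two-sided CI width for a postulated AUC and group sizes:
    ``2 * z * HanleyMcNeilSE``.  Used prospectively, so the AUC must lie in
    the design range [0.5, 1)."""
    if not (0.5 <= auc_value < 1.0):
        raise InputError("design AUC must lie in [0.5, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return 2.0 * z * hanley_mcneil_se(auc_value, n_pos, n_neg)


def auc_pvalue(scores, labels) -> float:
    """Two-sided Mann-Whitney test of the score distributions between the
    classes (equivalently H0: AUC = 0.5)."""
    pos, neg = _split(scores, labels)
    return rank_sum_pvalue(pos, neg)


# ------------------------------------------------------- cutoff and metrics


def optimal_cutoff(curve: ROCCurve) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Ties broken by higher specificity, then lower cutoff.  Returns
    ``(cutoff, sensitivity, specificity)``.
    """
    j = curve.tpr - curve.fpr
    # near-ties within 1e-9 count as ties (J computed from count ratios can
    # differ in the last ulp); then prefer higher specificity, lower cutoff
    cand = np.flatnonzero(j >= j.max() - 1e-9)
    best = cand[np.lexsort((curve.cutoffs[cand], curve.fpr[cand]))[0]]
    return (
        float(curve.cutoffs[best]),
        float(curve.tpr[best]),
        float(1.0 - curve.fpr[best]),
    )


def confusion_metrics(
    scores, labels, cutoff: float
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, PPV, NPV) at prediction rule score >= cutoff.

    Ratios with a zero denominator are returned as NaN, never as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return (
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
        ratio(tp, tp + fp),
        ratio(tn, tn + fn),
    )


# -------------------------------------------------------------------- report


@dataclass
class DiagnosticsReport:
    """One diagnostic comparison: AUC with 95% CI, rank-sum p-value, and the
    confusion metrics at the Youden-optimal cutoff."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_pos: int
    n_neg: int
    ci_method: str = "delong"
    classifier: str = field(default="")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def diagnostics_from_scores(
    scores, labels, ci_method: str = "delong", classifier: str = ""
) -> DiagnosticsReport:
    """Compose AUC, CI, p-value, optimal cutoff and confusion metrics."""
    pos, neg = _split(scores, labels)
    a = auc(scores, labels)
    lo, hi = auc_ci(scores, labels, method=ci_method)
    curve = roc_curve(scores, labels)
    cutoff, _, _ = optimal_cutoff(curve)
    sens, spec, ppv, npv = confusion_metrics(scores, labels, cutoff)
    return DiagnosticsReport(
        auc=a,
        ci_low=lo,
        ci_high=hi,
        p_value=auc_pvalue(scores, labels),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        n_pos=pos.size,
        n_neg=neg.size,
        ci_method=ci_method,
        classifier=classifier,
    )


def build_report(
    cvresult: CVResult, labels, ci_method: str = "delong"
) -> DiagnosticsReport:
    """Table-row diagnostics from the pooled out-of-fold probabilities."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != cvresult.oof_probability.size:
        raise InputError("labels length does not match the CV result")
    return diagnostics_from_scores(
        cvresult.oof_probability,
        labels,
        ci_method=ci_method,
        classifier=cvresult.classifier,
    )
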