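"""Diagnostic-performance statistics for classifier-vs-reader comparison.

Covers the statistics a diagnostic-accuracy study reports: accuracy,
sensitivity and specificity with Wilson score 95% confidence
intervals; ROC AUC with DeLong variance, and the paired DeLong test
for comparing two correlated AUCs measured on the same subjects;
McNemar's test on discordant classifications; Cohen's kappa with the
conventional qualitative agreement bands; and binarization of 5-level
ordinal reader confidence scores (0 definitely absent ... 4 definitely
present; 0-2 negative, 3-4 positive).

AUC follows the Mann-Whitney definition: the probability that a
randomly chosen diseased subject scores above a randomly chosen
control, ties counted one half — identical to the trapezoidal area
under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AgreementResult",
    "binarize_scores",
    "confusion_metrics",
    "wilson_ci",
    "roc_auc",
    "compare_auc",
    "mcnemar_test",
    "cohen_kappa",
    "kappa_band",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Point estimates with 95% CIs; proportions in [0, 1]."""

    counts: ConfusionCounts
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.counts.n

    def as_percent_row(self) -> dict[str, str]:
        """Formatted like a diagnostic-accuracy table row."""

        def fmt(p, ci):
            return f"{100 * p:.1f} [{100 * ci[0]:.1f}-{100 * ci[1]:.1f}]"

        row = {
            "CA (%)": fmt(self.accuracy, self.accuracy_ci),
            "SE (%)": fmt(self.sensitivity, self.sensitivity_ci),
            "SP (%)": fmt(self.specificity, self.specificity_ci),
        }
        if self.auc is not None:
            row["AUC"] = f"{self.auc:.3f} [{self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f}]"
        return row


@dataclass
class AgreementResult:
    kappa: float
    band: str
    degenerate: bool = False  # both raters constant and equal


# ---------------------------------------------------------------------------
# reader scores


def binarize_scores(scores) -> np.ndarray:
    """Map 5-level confidence scores to binary calls: 0-2 -> 0, 3-4 -> 1."""
    s = np.asarray(scores)
    if s.size and (s.min() < 0 or s.max() > 4):
        raise ValueError("reader scores must lie in {0, 1, 2, 3, 4}")
    return (s >= 3).astype(int)


# ---------------------------------------------------------------------------
# proportions


def wilson_ci(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def confusion_metrics(pred, truth) -> MetricsReport:
    """Accuracy, sensitivity, specificity with Wilson 95% CIs."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty input")
    TP = int(np.sum((pred == 1) & (truth == 1)))
    TN = int(np.sum((pred == 0) & (truth == 0)))
    FP = int(np.sum((pred == 1) & (truth == 0)))
    FN = int(np.sum((pred == 0) & (truth == 1)))
    counts = ConfusionCounts(TP, FP, TN, FN)
    n = counts.n
    n_pos = TP + FN
    n_neg = TN + FP
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both classes for SE/SP")
    acc = (TP + TN) / n
    se = TP / n_pos
    sp = TN / n_neg
    return MetricsReport(
        counts=counts,
        accuracy=acc,
        accuracy_ci=wilson_ci(TP + TN, n),
        sensitivity=se,
        sensitivity_ci=wilson_ci(TP, n_pos),
        specificity=sp,
        specificity_ci=wilson_ci(TN, n_neg),
    )


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """Per-subject placement values and AUC (midrank formulation)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m = pos.size
    n = neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for ROC analysis")
    tx = rankdata(pos)  # midranks within positives
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m
    return auc, v01, v10


def roc_auc(scores, truth, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC (ties one half) with a DeLong-variance Wald CI clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    auc, v01, v10 = _delong_components(scores, truth)
    m, n = v01.size, v10.size
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def compare_auc(scores_a, scores_b, truth) -> float:
    """Two-sided DeLong test for paired (same-subject) AUC difference."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != truth.shape:
        raise ValueError("score vectors and truth must cover the same subjects")
    auc_a, va01, va10 = _delong_components(scores_a, truth)
    auc_b, vb01, vb10 = _delong_components(scores_b, truth)
    m, n = va01.size, va10.size
    var = 0.0
    if m > 1:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m
    if n > 1:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    zstat = diff / np.sqrt(var)
    return float(2 * norm.sf(abs(zstat)))


# ---------------------------------------------------------------------------
# paired classifier comparison and agreement


def mcnemar_test(pred_a, pred_b, truth, exact_threshold: int = 25) -> float:
    """McNemar's test on discordant correctness of two classifiers.

    Exact two-sided binomial p when the discordant total is below
    ``exact_threshold``, else chi-square with continuity correction.
    """
    pred_a = np.asarray(pred_a, dtype=int)
    pred_b = np.asarray(pred_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("predictions and truth must cover the same subjects")
    a_correct = pred_a == truth
    b_correct = pred_b == truth
    b10 = int(np.sum(a_correct & ~b_correct))
    b01 = int(np.sum(~a_correct & b_correct))
    if b10 + b01 == 0:
        return 1.0
    both = int(np.sum(a_correct & b_correct))
    neither = int(np.sum(~a_correct & ~b_correct))
    table = [[both, b10], [b01, neither]]
    exact = (b10 + b01) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(1.0, res.pvalue))


_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement label at the conventional 0.2-step cut points."""
    if kappa <= 0:
        return "poor"
    for hi, name in _KAPPA_BANDS[1:]:
        if kappa <= hi + 1e-12:
            return name
    return "almost perfect"


def cohen_kappa(labels_a, labels_b) -> AgreementResult:
    """Chance-corrected agreement between two binary raters."""
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be nonempty and equal length")
    n = a.size
    po = float(np.mean(a == b))
    pe = 0.0
    for cls in (0, 1):
        pe += float(np.mean(a == cls)) * float(np.mean(b == cls))
    if pe >= 1.0 - 1e-15:
        # both raters constant and identical: perfect but chance-saturated
        return AgreementResult(kappa=1.0, band="almost perfect", degenerate=True)
    kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(kappa=float(kappa), band=kappa_band(kappa))
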