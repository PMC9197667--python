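"""Two-sample significance testing and ROC/AUC sensitivity index.

The group comparison underlying parameter optimization: for one region's
entropy values across the two groups, a two-sided Welch t-test gives the
significance, and the area under the ROC curve gives a threshold-free
sensitivity index.  The positive class is group 1 (excellent), and higher
entropy counts as evidence for the positive class; below-chance AUC values
are reported as-is, never folded around 0.5, so the direction can be audited.

The AUC is computed as the tie-corrected Mann-Whitney statistic
U / (n0 * n1) = P(score_1 > score_0) + 0.5 * P(tie), which equals the
trapezoidal area under the explicit ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ROCResult",
    "welch_t_test",
    "roc_auc",
    "auc_quality_band",
    "AUC_BANDS",
]


@dataclass
class TestResult:
    """Two-sample t-test outcome; ``computable`` is False when the data were
    insufficient (fewer than 2 per group, or no variance in either group)."""

    t_statistic: float
    p_value: float
    n0: int
    n1: int
    mean0: float
    mean1: float
    computable: bool = True


@dataclass
class ROCResult:
    """AUC plus the explicit ROC curve as (FPR, TPR) points from (0,0) to (1,1)."""

    auc: float
    curve: np.ndarray


def welch_t_test(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t-test (Welch by default) of group 0 vs group 1.

    The t statistic is signed as mean(a) - mean(b).  Insufficient data yield
    a flagged not-computable result rather than an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n0, n1 = a.size, b.size
    mean0 = float(a.mean()) if n0 else float("nan")
    mean1 = float(b.mean()) if n1 else float("nan")
    if n0 < 2 or n1 < 2 or (a.var(ddof=1) == 0 and b.var(ddof=1) == 0):
        return TestResult(
            t_statistic=float("nan"),
            p_value=float("nan"),
            n0=n0,
            n1=n1,
            mean0=mean0,
            mean1=mean1,
            computable=False,
        )
    with warnings.catch_warnings():
        # near-identical entropy values (extreme r cells) trigger scipy's
        # precision-loss advisory; the resulting p ~ 1 is the correct answer
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        t_statistic=float(t), p_value=float(p), n0=n0, n1=n1, mean0=mean0, mean1=mean1
    )


def _auc_value(scores0: np.ndarray, scores1: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC with group 1 as the positive class."""
    n0, n1 = scores0.size, scores1.size
    ranks = sps.rankdata(np.concatenate([scores0, scores1]))
    u1 = ranks[n0:].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


def roc_curve_points(scores0: np.ndarray, scores1: np.ndarray) -> np.ndarray:
    """ROC curve as (FPR, TPR) rows over thresholds "score >= v", v descending.

    Tied scores are grouped into a single threshold, producing the diagonal
    segments whose trapezoidal area matches the tie-corrected AUC.
    """
    thresholds = np.unique(np.concatenate([scores0, scores1]))[::-1]
    pts = [(0.0, 0.0)]
    for v in thresholds:
        fpr = float((scores0 >= v).mean())
        tpr = float((scores1 >= v).mean())
        pts.append((fpr, tpr))
    return np.asarray(pts)


def roc_auc(scores0: np.ndarray, scores1: np.ndarray) -> ROCResult:
    """ROC curve and AUC for group-0 vs group-1 scores.

    AUC = P(random group-1 score > random group-0 score) + 0.5 * P(tie);
    values below 0.5 are reported as-is (no folding).
    """
    scores0 = np.asarray(scores0, dtype=float)
    scores1 = np.asarray(scores1, dtype=float)
    scores0 = scores0[np.isfinite(scores0)]
    scores1 = scores1[np.isfinite(scores1)]
    if scores0.size == 0 or scores1.size == 0:
        raise ValueError("roc_auc requires non-empty score vectors for both groups")
    return ROCResult(
        auc=_auc_value(scores0, scores1), curve=roc_curve_points(scores0, scores1)
    )


#: Quality bands for AUC values: half-open [low, high) except the top band.
AUC_BANDS = (
    (0.50, 0.60, "poor"),
    (0.60, 0.70, "bad"),
    (0.70, 0.80, "medium"),
    (0.80, 0.90, "good"),
    (0.90, 1.00, "excellent"),
)


def auc_quality_band(auc: float) -> str:
    """Ordinal quality label for an AUC value.

    Bands: 0.50-0.59 poor, 0.60-0.69 bad, 0.70-0.79 medium, 0.80-0.89 good,
    0.90-1 excellent; values below 0.50 map to "below-chance".
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc < 0.50:
        return "below-chance"
    for low, high, label in AUC_BANDS:
        if low <= auc < high or (label == "excellent" and auc <= high):
            return label
    raise AssertionError("unreachable")
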