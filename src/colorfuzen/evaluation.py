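"""Two-group comparison statistics: Mann-Whitney U, Cohen's d, ROC metrics.

Given per-image feature values for two groups (e.g., melanoma vs
benign nevi entropies), this module provides the nonparametric
difference test, the standardized effect size, and ROC-derived
classification metrics at the Youden-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = ["GroupComparison", "ROCResult",
           "mann_whitney_u", "cohens_d", "roc_metrics", "compare_groups"]


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U and Cohen's d for two samples."""

    n_a: int
    n_b: int
    u_statistic: float  # U for group A over group B (pairs a > b, ties 1/2)
    p_value: float
    cohens_d: float


@dataclass(frozen=True)
class ROCResult:
    """ROC summary with the operating point maximizing Youden's J.

    ``direction`` is "greater" when higher scores indicate the positive
    class (possibly auto-selected so that AUC >= 0.5).  The threshold
    is on the original score scale: a case is called positive when
    score >= threshold ("greater") or score <= threshold ("lesser").
    """

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    threshold: float
    direction: str
    fpr: np.ndarray
    tpr: np.ndarray


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small untied samples
    (n <= 20 per group) and the tie-corrected normal approximation
    otherwise.  Returns (U, p) with U counting pairs a > b (ties 1/2).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size <= 20 and b.size <= 20) \
        else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD uses n-1 weighting.  Raises on zero pooled SD.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def compare_groups(group_a, group_b) -> GroupComparison:
    """U test and Cohen's d in one record."""
    u, p = mann_whitney_u(group_a, group_b)
    return GroupComparison(len(group_a), len(group_b), u, p,
                           cohens_d(group_a, group_b))


def _auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by the Mann-Whitney identity: fraction of (pos, neg) pairs
    with pos > neg, ties counted one half."""
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (pos.size * neg.size))


def roc_metrics(scores_pos, scores_neg, direction: str = "auto") -> ROCResult:
    """ROC curve, AUC and Youden-point metrics for two score samples.

    ``direction``: "greater" (higher score = positive), "lesser", or
    "auto" (flip so that AUC >= 0.5; the chosen polarity is reported).
    Youden ties are broken toward higher specificity.
    """
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("each class needs at least one score")
    if direction == "auto":
        direction = "greater" if _auc_pair_counting(pos, neg) >= 0.5 \
            else "lesser"
    if direction not in ("greater", "lesser"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "greater" else -1.0

    from sklearn.metrics import roc_curve

    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = sign * np.concatenate([pos, neg])
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = _auc_pair_counting(sign * pos, sign * neg)

    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    idx = best[np.argmin(fpr[best])]  # ties -> higher specificity
    sens = float(tpr[idx])
    spec = float(1.0 - fpr[idx])
    thr = float(sign * thresholds[idx])

    tp = sens * pos.size
    fn = pos.size - tp
    fp = (1.0 - spec) * neg.size
    tn = neg.size - fp
    accuracy = (tp + tn) / (pos.size + neg.size)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return ROCResult(auc, sens, spec, float(accuracy), float(precision),
                     thr, direction, fpr, tpr)
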