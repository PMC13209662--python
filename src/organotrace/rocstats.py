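"""ROC/AUC machinery for the injury scores.

The curve is built by sweeping a threshold over the distinct score
values (higher score ⇒ more likely injured); tied scores enter the
curve jointly.  The trapezoidal area under this curve equals the
Mann-Whitney statistic (wins + half-ties over all positive-negative
pairs).  Confidence intervals use the DeLong variance estimate with a
normal approximation (a stratified bootstrap is available for
cross-checking); the operating point maximizes the Youden index
J = sensitivity + specificity − 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .frames import DomainError


class DegenerateLabelsError(ValueError):
    """Scores from a single class cannot define a ROC curve."""


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending; leading +inf sentinel
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int
    positive_label: object = True

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.fpr = np.asarray(self.fpr, dtype=np.float64)
        self.tpr = np.asarray(self.tpr, dtype=np.float64)


@dataclass
class ROCSummary:
    auc: float
    ci_low: float
    ci_high: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int
    degenerate: bool = False
    method: dict = field(default_factory=lambda: {
        "ci": "delong-normal",
        "operating_point": "youden",
        "integration": "trapezoid",
    })


def _positive_mask(labels, positive_label) -> np.ndarray:
    labels = np.asarray(labels)
    if positive_label is None:
        return labels.astype(bool)
    return labels == positive_label


def roc_curve(scores, labels, positive_label=None) -> ROCCurve:
    """ROC curve points, one per distinct threshold.

    ``positive_label`` selects the positive class (injured); when None,
    labels are interpreted as booleans.  Requires at least one positive
    and one negative and finite scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0 or not np.all(np.isfinite(scores)):
        raise DomainError("scores must be non-empty and finite")
    pos = _positive_mask(labels, positive_label)
    if scores.shape != pos.shape:
        raise DomainError("scores and labels must have matching lengths")
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"need both classes, got {n_pos} positives and {n_neg} negatives"
        )

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    # indices where a new (lower) distinct score starts → joint handling of ties
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), sorted_scores.size - 1]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = np.cumsum(~sorted_pos)[distinct]

    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return ROCCurve(thresholds, fpr, tpr, n_pos, n_neg,
                    positive_label if positive_label is not None else True)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve (= Mann-Whitney statistic)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    z = x[order]
    n = z.size
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_auc_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[float, float]:
    m, n = pos_scores.size, neg_scores.size
    all_scores = np.concatenate([pos_scores, neg_scores])
    tz = _midrank(all_scores)
    tx = _midrank(pos_scores)
    ty = _midrank(neg_scores)
    auc_hat = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return float(auc_hat), s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95, positive_label=None) -> tuple[float, float]:
    """DeLong normal-approximation interval for the AUC, truncated to [0, 1].

    Degenerate variance (e.g. perfect separation) collapses the interval
    onto the point estimate; :func:`summarize` flags that case.
    """
    if not 0.0 < level < 1.0:
        raise DomainError("confidence level must lie in (0, 1)")
    scores = np.asarray(scores, dtype=np.float64)
    pos = _positive_mask(labels, positive_label)
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise DegenerateLabelsError("need both classes for a confidence interval")
    auc_hat, variance = _delong_auc_variance(scores[pos], scores[~pos])
    if not np.isfinite(variance) or variance <= 0:
        return (min(max(auc_hat, 0.0), 1.0),) * 2
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    return (float(np.clip(auc_hat - half, 0.0, 1.0)),
            float(np.clip(auc_hat + half, 0.0, 1.0)))


def bootstrap_auc_ci(scores, labels, level: float = 0.95, n_boot: int = 2000,
                     seed: int = 0, positive_label=None) -> tuple[float, float]:
    """Stratified percentile bootstrap interval (cross-check for DeLong)."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = _positive_mask(labels, positive_label)
    pos_scores, neg_scores = scores[pos], scores[~pos]
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise DegenerateLabelsError("need both classes for a confidence interval")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos_scores, pos_scores.size, replace=True)
        ns = rng.choice(neg_scores, neg_scores.size, replace=True)
        reps[b] = _delong_auc_variance(ps, ns)[0]
    lo, hi = np.quantile(reps, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


def youden_point(curve: ROCCurve) -> tuple[float, float, float]:
    """Operating point maximizing J = TPR − FPR.

    Ties are broken by higher sensitivity, then by lower threshold; with
    completely tied scores this lands on the all-positive corner
    (threshold at the tied value, sensitivity 1, specificity 0).
    """
    j = curve.tpr - curve.fpr
    best = 0
    for i in range(1, j.size):
        if j[i] > j[best] + 1e-12:
            best = i
        elif abs(j[i] - j[best]) <= 1e-12:
            if (curve.tpr[i] > curve.tpr[best]
                    or (curve.tpr[i] == curve.tpr[best]
                        and curve.thresholds[i] < curve.thresholds[best])):
                best = i
    return (float(curve.thresholds[best]), float(curve.tpr[best]),
            float(1.0 - curve.fpr[best]))


def summarize(scores, labels, level: float = 0.95, positive_label=None) -> ROCSummary:
    """Full ROC readout: AUC, DeLong CI, and the Youden operating point."""
    curve = roc_curve(scores, labels, positive_label)
    auc_hat = auc(curve)
    scores_arr = np.asarray(scores, dtype=np.float64)
    degenerate = bool(np.ptp(scores_arr) == 0)
    lo, hi = auc_ci(scores, labels, level, positive_label)
    if lo == hi:
        degenerate = True
    threshold, sensitivity, specificity = youden_point(curve)
    return ROCSummary(
        auc=auc_hat,
        ci_low=lo,
        ci_high=hi,
        youden_threshold=threshold,
        sensitivity=sensitivity,
        specificity=specificity,
        n_positive=curve.n_positive,
        n_negative=curve.n_negative,
        degenerate=degenerate,
    )
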