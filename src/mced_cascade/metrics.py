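"""ROC/AUC estimation, DeLong AUC comparison, and operating-point metrics.

The empirical AUC here is the Mann-Whitney statistic (ties credited 0.5),
identical to the probability interpretation: for a random (case, control)
pair, the probability the case scores higher, counting ties as one half.
The DeLong test compares two correlated AUCs measured on the same subjects
using placement-value covariance estimates.  Sensitivity/specificity
confidence intervals are exact Clopper-Pearson binomial intervals, and the
threshold-at-specificity lookup uses linearly interpolated (type-7)
percentiles so it is consistent with the CRS calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ROCSummary",
    "DeLongResult",
    "empirical_auc",
    "roc_summary",
    "delong_test",
    "sens_spec_at",
    "threshold_at_specificity",
]


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a


def empirical_auc(scores_pos, scores_neg) -> float:
    """Mann-Whitney AUC of positive-class vs negative-class scores.

    Equals the mean over all (pos, neg) pairs of 1 if pos > neg, 0.5 if
    tied, 0 otherwise; computed via midranks in O(n log n).
    """
    pos = _as_1d(scores_pos)
    neg = _as_1d(scores_neg)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empirical_auc requires non-empty score lists for both classes")
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)  # midranks handle ties as 0.5 credit
    r_pos = ranks[: pos.size].sum()
    auc = (r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    return float(auc)


@dataclass
class ROCSummary:
    """Empirical ROC curve with its Mann-Whitney AUC."""

    auc: float
    n_pos: int
    n_neg: int
    thresholds: np.ndarray = field(repr=False)
    sensitivities: np.ndarray = field(repr=False)
    specificities: np.ndarray = field(repr=False)


def roc_summary(scores, labels) -> ROCSummary:
    """Full empirical ROC over every observed threshold.

    ``labels`` is boolean-like (True = positive class).  Thresholds are the
    distinct scores in increasing order with the "call everything positive"
    point prepended; a subject is called positive when score >= threshold,
    matching the POC/CRS decision convention.
    """
    s = _as_1d(scores)
    y = np.asarray(labels, dtype=bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    pos, neg = s[y], s[~y]
    uniq = np.unique(s)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return ROCSummary(
        auc=empirical_auc(pos, neg), n_pos=int(pos.size), n_neg=int(neg.size),
        thresholds=thresholds, sensitivities=sens, specificities=spec,
    )


# ---------------------------------------------------------------------------
# DeLong comparison of paired AUCs
# ---------------------------------------------------------------------------

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus placement values V10 (per case) and V01 (per control)."""
    m, n = pos.size, neg.size
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n
    v01 = 1.0 - (ranks[m:] - rank_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass
class DeLongResult:
    """Outcome of a DeLong paired-AUC comparison."""

    auc_a: float
    auc_b: float
    z: float | None
    p: float | None
    se: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for the difference of two AUCs on the same subjects.

    Two-sided p against the standard normal.  If the placement values carry
    no variance while the AUCs differ, the comparison is degenerate and the
    p-value is reported absent; identical score vectors give z = 0, p = 1.
    """
    a = _as_1d(scores_a)
    b = _as_1d(scores_b)
    y = np.asarray(labels, dtype=bool).ravel()
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must align subject-by-subject")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _placements(a[y], a[~y])
    auc_b, v10_b, v01_b = _placements(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())

    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2, ddof=1
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0.0:
            return DeLongResult(auc_a, auc_b, z=0.0, p=1.0, se=0.0)
        return DeLongResult(auc_a, auc_b, z=None, p=None, se=0.0, degenerate=True)
    se = float(np.sqrt(var))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, z=float(z), p=p, se=se)


# ---------------------------------------------------------------------------
# operating points
# ---------------------------------------------------------------------------

def sens_spec_at(scores, labels, cutoff: float, alpha: float = 0.05):
    """Sensitivity and specificity at a cutoff, with Clopper-Pearson CIs.

    A subject is screen-positive when score >= cutoff (the same inclusive
    boundary as the POC 0.5 and CRS 2.0 decision rules).

    Returns
    -------
    dict with keys ``sensitivity``, ``specificity``, ``sensitivity_ci``,
    ``specificity_ci``, ``tp``, ``fn``, ``tn``, ``fp``.
    """
    s = _as_1d(scores)
    y = np.asarray(labels, dtype=bool).ravel()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    calls = s >= cutoff
    tp = int((calls & y).sum())
    fn = int((~calls & y).sum())
    fp = int((calls & ~y).sum())
    tn = int((~calls & ~y).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=alpha, method="beta")
    spec_ci = proportion_confint(tn, tn + fp, alpha=alpha, method="beta")
    return {
        "sensitivity": sens, "specificity": spec,
        "sensitivity_ci": (float(sens_ci[0]), float(sens_ci[1])),
        "specificity_ci": (float(spec_ci[0]), float(spec_ci[1])),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def threshold_at_specificity(scores_neg, target_spec: float) -> float:
    """Score threshold whose negative-class lower tail meets a specificity.

    Uses the linearly interpolated (type-7) percentile of the negative-class
    scores at ``target_spec``, the same percentile definition as the CRS
    calibration, so a cutoff at the returned threshold leaves at most the
    requested upper-tail fraction of negatives at or above it (up to the
    1/n resolution of an empirical percentile).
    """
    neg = _as_1d(scores_neg)
    if not 0.0 <= target_spec <= 1.0:
        raise ValueError("target_spec must lie in [0, 1]")
    min_n = int(np.ceil(1.0 / (1.0 - target_spec))) if target_spec < 1.0 else 1
    if neg.size < min_n:
        raise ValueError(
            f"need at least {min_n} negative scores to resolve specificity "
            f"{target_spec}, got {neg.size}")
    return float(np.quantile(neg, target_spec))  # numpy default = type-7
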