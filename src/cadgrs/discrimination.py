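"""ROC analysis: Mann-Whitney AUC and the DeLong paired AUC test.

The AUC is computed through the Mann-Whitney identity — the probability
that a random case outscores a random control, with ties counting one
half — which equals the trapezoidal area under the empirical ROC curve.
The DeLong test compares two correlated AUCs measured on the same
subjects via the covariance of their placement values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values: V10[i] = P-hat(case i outscores a random
    control), V01[j] = P-hat(a random case outscores control j)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    ranks = rankdata(allv)  # midranks
    rpos = rankdata(pos)
    rneg = rankdata(neg)
    v10 = (ranks[:m] - rpos) / n
    v01 = 1.0 - (ranks[m:] - rneg) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC by the Mann-Whitney pair-counting identity (ties count 1/2)."""
    pos, neg = _split(scores, labels)
    _, _, auc = _placements(pos, neg)
    return auc


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve: one row per distinct threshold, columns
    threshold / sensitivity / one_minus_specificity (descending
    thresholds; includes the (0,0) and (1,1) endpoints)."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    thresholds = np.unique(scores)[::-1]
    rows = [{"threshold": np.inf, "sensitivity": 0.0,
             "one_minus_specificity": 0.0}]
    for t in thresholds:
        rows.append({
            "threshold": float(t),
            "sensitivity": float((pos >= t).mean()),
            "one_minus_specificity": float((neg >= t).mean()),
        })
    return pd.DataFrame(rows)


def auc_trapezoid(scores, labels) -> float:
    """Trapezoidal area under the empirical ROC (cross-check identity
    with :func:`auc_mann_whitney`)."""
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts.sensitivity, pts.one_minus_specificity))


@dataclass(frozen=True)
class RocComparison:
    """Paired comparison of two AUCs on the same subjects (DeLong)."""

    auc_base: float
    auc_new: float
    covariance: np.ndarray  # 2x2 covariance of (auc_base, auc_new)
    z: float
    p_value: float
    degenerate: bool = False

    @property
    def auc_difference(self) -> float:
        return self.auc_new - self.auc_base

    @property
    def se_difference(self) -> float:
        c = self.covariance
        return float(np.sqrt(max(c[0, 0] + c[1, 1] - 2 * c[0, 1], 0.0)))


def delong_variance(scores, labels) -> float:
    """DeLong sampling variance of a single AUC."""
    pos, neg = _split(scores, labels)
    v10, v01, _ = _placements(pos, neg)
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


def delong_paired_test(scores_base, scores_new, labels) -> RocComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same subjects.  If the
    two models order subjects identically the variance of the difference
    is zero; the result is flagged degenerate with z = 0, p = 1.
    """
    scores_base = np.asarray(scores_base, dtype=float)
    scores_new = np.asarray(scores_new, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_base) == len(scores_new) == len(labels)):
        raise ValueError("paired scores and labels must have equal length")
    mask = labels == 1
    pos_b, neg_b = scores_base[mask], scores_base[~mask]
    pos_n, neg_n = scores_new[mask], scores_new[~mask]
    if len(pos_b) == 0 or len(neg_b) == 0:
        raise ValueError("both classes must be present")
    m, n = len(pos_b), len(neg_b)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, (pos, neg) in enumerate(((pos_b, neg_b), (pos_n, neg_n))):
        v10[i], v01[i], aucs[i] = _placements(pos, neg)
    s10 = np.cov(v10)  # 2x2
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        return RocComparison(float(aucs[0]), float(aucs[1]), cov, 0.0, 1.0,
                             degenerate=True)
    z = float((aucs[1] - aucs[0]) / np.sqrt(var_diff))
    p = float(2.0 * norm.sf(abs(z)))
    return RocComparison(float(aucs[0]), float(aucs[1]), cov, z, p)
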