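"""ROC curves, the c-statistic and percentile-bootstrap AUC confidence intervals.

The c-statistic is computed in its Mann–Whitney form — the probability that a
random case outscores a random control, with ties counted 1/2 — using a
rank-based O(n log n) algorithm.  The ROC sweep uses the same tie convention,
so the trapezoidal area under the curve equals the c-statistic to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["RocResult", "c_statistic", "roc_points", "bootstrap_auc_ci"]


@dataclass
class RocResult:
    """An ROC curve: (FPR, TPR) points from (0,0) to (1,1) plus its area."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr)
    auc: float
    ci: tuple[float, float] | None = None

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="fpr,tpr", comments="")


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels have different lengths")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC")
    return s, y, n_pos, n_neg


def c_statistic(scores, labels) -> float:
    """Concordance probability P(score_case > score_control) + ½P(tie).

    Rank implementation: with midranks R_i, the Mann–Whitney U statistic for
    the cases is U = sum of case ranks − n1(n1+1)/2, and c = U/(n1·n0).
    """
    s, y, n_pos, n_neg = _check_scores_labels(scores, labels)
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels) -> RocResult:
    """ROC curve swept over unique score thresholds, descending.

    Tied scores move diagonally in one step, which makes the trapezoidal
    area identical to the Mann–Whitney c-statistic.
    """
    s, y, n_pos, n_neg = _check_scores_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # group boundaries: last index of each tie block
    distinct = np.nonzero(np.diff(s_sorted))[0]
    ends = np.append(distinct, s_sorted.size - 1)
    tp = np.cumsum(y_sorted)[ends]
    fp = np.cumsum(1 - y_sorted)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=pts, auc=auc)


def bootstrap_auc_ci(
    scores,
    labels,
    replicates: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC by case-resampling (score, label) pairs.

    Resamples with a single class are redrawn (up to 100 attempts each);
    identical seed gives an identical interval.
    """
    s, y, _, _ = _check_scores_labels(scores, labels)
    if replicates < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = s.size
    aucs = np.empty(replicates)
    for b in range(replicates):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == 0 and yb.max() == 1:
                aucs[b] = c_statistic(s[idx], yb)
                break
        else:
            raise RuntimeError(
                "could not draw a two-class bootstrap resample in 100 attempts"
            )
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
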