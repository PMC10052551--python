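"""Precision-recall evaluation with 11-point interpolated average precision.

The PR curve has one point per distinct score threshold (tied scores are
grouped), plus the conventional (recall 0, precision 1) point for the empty
prediction set. Smoothing replaces each precision by the maximum precision
at any recall to its right; AP is the mean of the smoothed precision at
recall {0.0, 0.1, ..., 1.0}, with recall values beyond the maximum achieved
recall contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PRCurve:
    thresholds: np.ndarray  # descending
    recall: np.ndarray
    precision: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValueError("recall must be non-decreasing along the curve")
        total = self.tp + self.fn
        if len(total) and not np.all(total == total[0]):
            raise ValueError("TP + FN must be constant along the curve")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def pr_curve(
    scores: pd.Series, labels: pd.Series, eval_set: list[str] | None = None
) -> PRCurve:
    """Build the PR curve of driver scores against binary labels.

    ``labels`` holds 1 for positives and 0 for negatives (a string label
    series with "positive"/"negative" is also accepted).
    """
    if eval_set is not None:
        scores = scores.reindex(eval_set)
        labels = labels.reindex(eval_set)
    if labels.dtype == object:
        labels = (labels == "positive").astype(int)
    y = labels.to_numpy().astype(int)
    s = scores.to_numpy(dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR curve requires >= 1 positive in the eval set")
    if n_pos == len(y):
        raise ValueError("PR curve requires >= 1 negative in the eval set")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group tied scores: last index of each distinct threshold
    distinct = np.where(np.diff(s) != 0)[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    predicted = cut + 1
    fp = predicted - tp
    fn = n_pos - tp
    precision = tp / predicted
    recall = tp / n_pos
    # prepend the empty prediction set: recall 0, precision 1
    return PRCurve(
        thresholds=np.concatenate([[np.inf], s[cut]]),
        recall=np.concatenate([[0.0], recall]),
        precision=np.concatenate([[1.0], precision]),
        tp=np.concatenate([[0], tp]),
        fp=np.concatenate([[0], fp]),
        fn=np.concatenate([[n_pos], fn]),
    )


def smooth(curve: PRCurve) -> PRCurve:
    """Right-max smoothing: P_smooth(r) = max over r' >= r of P(r')."""
    p = np.maximum.accumulate(curve.precision[::-1])[::-1]
    return PRCurve(
        thresholds=curve.thresholds,
        recall=curve.recall,
        precision=p,
        tp=curve.tp,
        fp=curve.fp,
        fn=curve.fn,
    )


def interpolated_ap(curve: PRCurve) -> float:
    """11-point interpolated AP on a (smoothed) PR curve.

    AP = (1/11) * sum over r in {0.0, 0.1, ..., 1.0} of P_smooth(r), where
    P_smooth(r) is the maximum precision among curve points with recall >= r
    and 0 where no point reaches recall r.
    """
    grid = np.linspace(0.0, 1.0, 11)
    total = 0.0
    for r in grid:
        mask = curve.recall >= r - 1e-12
        total += float(curve.precision[mask].max()) if mask.any() else 0.0
    return total / 11.0


def average_precision(scores: pd.Series, labels: pd.Series, eval_set=None) -> float:
    """Convenience wrapper: smoothed 11-point AP from raw scores."""
    return interpolated_ap(smooth(pr_curve(scores, labels, eval_set)))
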