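"""Evaluation metrics: max-F1 over thresholds, AUROC, AUPRC.

Conventions:

* ``f1_score`` uses the counts form ``2 TP / (FN + 2 TP + FP)`` and returns 0
  when the denominator is 0.
* ``max_f1`` min-max rescales the scores to [0, 1] and takes the maximum F1
  over every threshold that can change the confusion table (midpoints between
  consecutive distinct rescaled scores, plus the endpoints 0 and 1), which
  dominates any finite grid on [0, 1].  Classification is ``score >= t``.
* ``auroc`` is the Mann-Whitney statistic: the fraction of positive-negative
  pairs ranked concordantly, ties counting one half.
* ``auprc`` is average precision with tied scores handled as one group.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["f1_score", "max_f1", "auroc", "auprc"]


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 from confusion counts: ``2 TP / (FN + 2 TP + FP)``; 0 if empty."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("confusion counts must be nonnegative")
    denom = fn + 2 * tp + fp
    return 2 * tp / denom if denom > 0 else 0.0


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def _rescale01(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def max_f1(scores, labels) -> dict:
    """Maximum F1 over thresholds on the min-max-rescaled scores.

    Returns ``{"f1": best F1, "threshold": a rescaled threshold attaining it}``.
    """
    scores, labels = _check_scores_labels(scores, labels)
    r = _rescale01(scores)
    order = np.argsort(-r, kind="stable")
    r_sorted = r[order]
    pos_sorted = (labels[order] == 1).astype(int)
    n_pos = int(pos_sorted.sum())

    # boundaries of tie groups in the descending sort
    distinct = np.flatnonzero(np.diff(r_sorted) != 0)
    group_ends = np.concatenate([distinct, [r.size - 1]])  # inclusive indices

    tp = np.cumsum(pos_sorted)[group_ends]
    npred = group_ends + 1
    fp = npred - tp
    fn = n_pos - tp
    denom = fn + 2 * tp + fp
    f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)

    # threshold attaining prefix k: midpoint to the next lower distinct value;
    # the all-positive prefix is attained at the endpoint 0.
    vals = r_sorted[group_ends]
    thresholds = 0.5 * (vals + np.concatenate([vals[1:], [0.0]]))
    thresholds[-1] = 0.0

    best = int(np.argmax(f1))
    return {"f1": float(f1[best]), "threshold": float(thresholds[best])}


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties as one-half
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision; tied scores are treated as one group (each positive
    in the group contributes the precision at the end of the group)."""
    scores, labels = _check_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = (labels[order] == 1).astype(int)
    n_pos = int(pos_sorted.sum())

    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    group_ends = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(pos_sorted)[group_ends]
    npred = group_ends + 1
    precision = tp / npred
    tp_in_group = np.diff(np.concatenate([[0], tp]))
    return float((tp_in_group * precision).sum() / n_pos)
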