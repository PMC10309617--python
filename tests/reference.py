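"""Independent brute-force references used by the metric tests.

Everything here is written for clarity over speed and shares no code with
privsvm.metrics: confusion counts come from explicit loops/subset scans, AUROC
from the pairwise definition, average precision from a naive threshold walk.
"""

from __future__ import annotations

import numpy as np


def f1_from_pr(tp: int, fp: int, fn: int) -> float:
    """F1 as the harmonic mean of precision and recall (0 when undefined)."""
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def max_f1_brute(scores, labels) -> float:
    """Max F1 over every threshold-consistent subset of the rescaled scores.

    A subset S of samples is predictable as "positive" by some threshold
    t in [0, 1] (rule: rescaled score >= t) iff min(S) > max(complement), or S
    is everything.  Enumerates all 2^n subsets; n must be small.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = scores.size
    lo, hi = scores.min(), scores.max()
    r = np.full(n, 0.5) if hi == lo else (scores - lo) / (hi - lo)
    best = 0.0  # the empty prediction has F1 = 0
    for bits in range(1, 2 ** n):
        S = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if not S.all():
            if r[S].min() <= r[~S].max():
                continue  # no threshold separates S from its complement
        tp = int(((labels == 1) & S).sum())
        fp = int(((labels == -1) & S).sum())
        fn = int(((labels == 1) & ~S).sum())
        best = max(best, f1_from_pr(tp, fp, fn))
    return best


def auroc_brute(scores, labels) -> float:
    """Pairwise definition: P(pos ranked above neg), ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def auprc_brute(scores, labels) -> float:
    """Average precision from a naive walk over distinct thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = int(((labels == 1) & predicted).sum())
        fp = int(((labels == -1) & predicted).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
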