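"""Shared numeric oracles used by more than one test module."""

import numpy as np


def auprc_fine_oracle(labels, scores, points_per_segment=50_000):
    """Numeric auPRC oracle: dense nonlinear interpolation between PR points.

    Walks the achievable (TP, FP) points in threshold order and inserts a
    dense grid of interpolated true-positive points per segment, with false
    positives interpolated at the segment's local skew, then integrates
    precision over recall with the trapezoid rule.  At this grid density the
    discretisation error is well below 1e-6.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    ends = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tps = np.r_[0.0, np.cumsum(l)[ends]]
    fps = np.r_[0.0, np.cumsum(~l)[ends]]
    n_pos = labels.sum()
    area = 0.0
    for (tp_a, fp_a), (tp_b, fp_b) in zip(zip(tps, fps), zip(tps[1:], fps[1:])):
        if tp_b == tp_a:
            continue
        skew = (fp_b - fp_a) / (tp_b - tp_a)
        x = np.linspace(0.0, tp_b - tp_a, points_per_segment)
        tp = tp_a + x
        fp = fp_a + skew * x
        denom = tp + fp
        precision = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
        if denom[0] == 0:  # start of the whole curve: constant precision
            precision[0] = precision[1]
        area += np.trapezoid(precision, tp / n_pos)
    return area
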