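"""Ranking metrics and cross-term comparisons.

Pathogenic variants are a small minority of any realistic candidate list, so
precision–recall analysis is preferred over ROC.  Two metrics are provided:

* :func:`auprc` — area under the precision–recall curve with Davis–Goadrich
  interpolation.  Precision does not interpolate linearly between achievable
  PR points; between consecutive points ``(TP_a, FP_a)`` and ``(TP_b, FP_b)``
  the curve at ``TP_a + x`` true positives is

  ``p(x) = (TP_a + x) / (TP_a + x + FP_a + x * (FP_b - FP_a) / (TP_b - TP_a))``

  This module integrates each hyperbolic segment in closed form rather than
  discretising it, so the area is exact for the interpolated curve.  Tied
  scores collapse into a single threshold step.

* :func:`ppk` — precision at rank k: the proportion of true pathogenic
  variants among the k highest-scored predictions (PP50/PP100/PP200).  A tie
  block straddling rank k contributes its expected pathogenic fraction.

Methods are compared across phenotype terms with a two-sided paired Student
t-test on the per-term metric differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TermPerformance",
    "ComparisonSummary",
    "pr_points",
    "auprc",
    "ppk",
    "evaluate_ranking",
    "paired_ttest",
    "compare_terms",
]


@dataclass
class TermPerformance:
    """Ranking metrics for one method on one phenotype term."""

    term_id: str
    method: str
    auprc: float
    ppk: dict[int, float]
    n_scored: int = 0
    n_unscored: int = 0


@dataclass
class ComparisonSummary:
    """Paired comparison of a metric across phenotype terms."""

    metric: Optional[str]
    n_terms: int
    n_improved: int
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: int
    p_value: float


def _as_ranking(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite (drop unscored variants first)")
    return labels, scores


def pr_points(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at each distinct score threshold, descending.

    Tied variants form a single threshold step, so consecutive points may
    advance TP and FP jointly.
    """
    labels, scores = _as_ranking(labels, scores)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    # last index of each tied block
    block_end = np.flatnonzero(np.diff(s) != 0)
    block_end = np.concatenate([block_end, [len(s) - 1]])
    tp = np.cumsum(l)[block_end]
    fp = np.cumsum(~l)[block_end]
    return tp.astype(float), fp.astype(float)


def _segment_area(tp_a: float, fp_a: float, tp_b: float, fp_b: float) -> float:
    """Exact integral of interpolated precision over TP in [tp_a, tp_b]."""
    d = tp_b - tp_a
    if d <= 0:
        return 0.0
    slope = (fp_b - fp_a) / d
    m = 1.0 + slope
    c = tp_a + fp_a
    if c == 0.0:
        # first segment from the origin: constant precision tp_b/(tp_b+fp_b)
        return d / m
    # integral of (tp_a + x) / (c + m x) dx from 0 to d
    return d / m + (tp_a - c / m) / m * np.log((c + m * d) / c)


def auprc(labels, scores) -> float:
    """Area under the precision–recall curve (Davis–Goadrich interpolation).

    Raises
    ------
    ValueError
        If only one class is present.
    """
    labels, scores = _as_ranking(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("auprc requires both pathogenic and benign variants")
    tp, fp = pr_points(labels, scores)
    tp = np.concatenate([[0.0], tp])
    fp = np.concatenate([[0.0], fp])
    area = 0.0
    for i in range(len(tp) - 1):
        area += _segment_area(tp[i], fp[i], tp[i + 1], fp[i + 1])
    return area / n_pos


def ppk(labels, scores, k: int) -> float:
    """Proportion of pathogenic variants among the top-k predictions.

    The denominator is always ``k``, even when fewer than k variants exist.
    A tie block crossing rank k contributes the expected pathogenic count over
    random orderings of the block (deterministic and input-order independent).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels, scores = _as_ranking(labels, scores)
    if len(labels) == 0:
        return 0.0
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    if len(s) <= k:
        return float(l.sum()) / k
    cutoff = s[k - 1]
    above = s > cutoff
    count = float(l[above].sum())
    tied = s == cutoff
    slots = k - int(above.sum())
    if slots > 0:
        block = l[tied]
        count += slots * float(block.sum()) / len(block)
    return count / k


def evaluate_ranking(
    term_id: str,
    method: str,
    labels,
    scores,
    ks: Sequence[int] = (50, 100, 200),
) -> TermPerformance:
    """Compute auPRC and PPk for one ranking, excluding unscored variants.

    Variants with NaN scores are dropped from the ranking (never imputed);
    the number excluded is recorded on the result.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    scored = ~np.isnan(scores)
    perf = TermPerformance(
        term_id=term_id,
        method=method,
        auprc=auprc(labels[scored], scores[scored]),
        ppk={k: ppk(labels[scored], scores[scored], k) for k in ks},
        n_scored=int(scored.sum()),
        n_unscored=int((~scored).sum()),
    )
    return perf


def paired_ttest(a, b) -> ComparisonSummary:
    """Two-sided paired Student t-test on ``d = a - b``.

    Returns the mean difference, 95% CI from the t quantile, the t statistic
    with ``n - 1`` degrees of freedom, and the two-sided p-value.

    Raises
    ------
    ValueError
        If fewer than two pairs, or the differences have zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: t statistic undefined")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    q = stats.t.ppf(0.975, df)
    return ComparisonSummary(
        metric=None,
        n_terms=n,
        n_improved=int((d > 0).sum()),
        mean_difference=float(mean),
        ci_low=float(mean - q * se),
        ci_high=float(mean + q * se),
        t_statistic=float(t_stat),
        df=df,
        p_value=float(p),
    )


def _metric_value(perf: TermPerformance, metric: str) -> float:
    if metric == "auprc":
        return perf.auprc
    if metric.startswith("pp"):
        k = int(metric[2:])
        return perf.ppk[k]
    raise ValueError(f"unknown metric {metric!r}")


def compare_terms(
    perf_varpp: Sequence[TermPerformance],
    perf_baseline: Sequence[TermPerformance],
    metric: str = "auprc",
) -> ComparisonSummary:
    """Paired comparison of a metric across matched phenotype terms.

    ``n_improved`` counts terms where the first method's metric is strictly
    greater; the attached t-test is on the per-term differences.
    """
    terms_a = [p.term_id for p in perf_varpp]
    terms_b = [p.term_id for p in perf_baseline]
    if terms_a != terms_b:
        raise ValueError("term sets do not match between methods")
    a = np.array([_metric_value(p, metric) for p in perf_varpp])
    b = np.array([_metric_value(p, metric) for p in perf_baseline])
    summary = paired_ttest(a, b)
    summary.metric = metric
    summary.n_improved = int((a > b).sum())
    return summary
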