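"""Gene-expression feature construction.

Expression matrices are represented as :class:`pandas.DataFrame` objects with
gene symbols as the index and sample or tissue labels as columns.  Three
composable steps turn a raw count matrix into per-tissue predictor variables:

1. :func:`cpm` — library-size scaling to counts per million,
2. :func:`filter_unexpressed` — drop genes below a CPM floor in too few samples,
3. :func:`average_by_group` — collapse sample columns to tissue-group means.

A fourth, optional transform produces tissue-*specificity* features instead of
expression magnitude: each gene's expression vector is L2-normalised
(:func:`specificity_scores`) and the per-tissue scores are converted to
percentile ranks over genes (:func:`specificity_percentiles`).  Low percentiles
(near ``1/G``) mark genes specifically expressed in that tissue; percentiles
near one mark genes that are ubiquitous or silent.

The steps are deliberately separable so matrices normalised elsewhere (e.g.
smooth-quantile normalised tissue data) can enter the pipeline at any stage.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "validate_expression",
    "cpm",
    "filter_unexpressed",
    "average_by_group",
    "specificity_scores",
    "specificity_percentiles",
    "restrict_genes",
]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix (genes x samples/tissues).

    Checks: numeric, non-negative, finite values; unique gene symbols and
    unique column labels.  Returns the matrix unchanged.
    """
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dups[:5]}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column labels: {dups[:5]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return matrix


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each column of a count matrix to counts per million.

    ``cpm[g, s] = counts[g, s] * 1e6 / sum(counts[:, s])``

    Raises
    ------
    ValueError
        If any column sums to zero (the offending column is named).
    """
    validate_expression(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column sum for: {list(zero.index)}")
    return counts * 1e6 / totals


def filter_unexpressed(
    matrix: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 6
) -> pd.DataFrame:
    """Drop genes not expressed (``CPM >= min_cpm``) in at least ``min_samples`` columns.

    The default floor of 1 CPM in 6 samples corresponds to requiring
    expression in at least the smallest tissue group.  Gene order is
    preserved; the operation is idempotent.

    Raises
    ------
    ValueError
        If ``min_samples`` exceeds the column count, or no gene survives.
    """
    validate_expression(matrix)
    if min_samples > matrix.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of columns ({matrix.shape[1]})"
        )
    keep = (matrix >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no genes survive the expression filter")
    return matrix.loc[keep]


def average_by_group(matrix: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Average sample columns within tissue groups.

    ``groups`` maps every column label to a group label.  The output has one
    column per group, ordered by first appearance among the input columns,
    holding the arithmetic mean over member samples.

    Raises
    ------
    KeyError
        If any column of ``matrix`` is not mapped.
    """
    validate_expression(matrix)
    unmapped = [c for c in matrix.columns if c not in groups]
    if unmapped:
        raise KeyError(f"columns without a tissue group: {unmapped[:5]}")
    order: list[str] = []
    for col in matrix.columns:
        g = groups[col]
        if g not in order:
            order.append(g)
    out = pd.DataFrame(index=matrix.index, columns=order, dtype=float)
    for g in order:
        members = [c for c in matrix.columns if groups[c] == g]
        out[g] = matrix[members].mean(axis=1)
    return out


def specificity_scores(avg: pd.DataFrame) -> pd.DataFrame:
    """L2-normalise each gene's expression vector across tissues.

    ``score[g, t] = x[g, t] / ||x[g, :]||_2``.  Rows with any expression have
    unit Euclidean norm afterwards; all-zero rows stay all-zero.
    """
    validate_expression(avg)
    values = avg.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(norms > 0, values / np.where(norms > 0, norms, 1.0), 0.0)
    return pd.DataFrame(scores, index=avg.index, columns=avg.columns)


def specificity_percentiles(scores: pd.DataFrame) -> pd.DataFrame:
    """Convert per-tissue specificity scores to percentile ranks over genes.

    Within each tissue column, genes are ranked in descending score order
    (rank 1 = most specific), ties receive the averaged rank, and ranks are
    divided by the number of genes G.  The most tissue-specific gene thus gets
    percentile 1/G (near zero) and silent or ubiquitous genes end near one.
    """
    validate_expression(scores)
    values = scores.to_numpy(dtype=float)
    n_genes = values.shape[0]
    ranks = np.apply_along_axis(lambda col: rankdata(-col, method="average"), 0, values)
    return pd.DataFrame(ranks / n_genes, index=scores.index, columns=scores.columns)


def restrict_genes(matrix: pd.DataFrame, whitelist: Iterable[str]) -> pd.DataFrame:
    """Keep only whitelisted genes (e.g. protein-coding), preserving order."""
    allowed = set(whitelist)
    keep = matrix.index.isin(allowed)
    return matrix.loc[keep]
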