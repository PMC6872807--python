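"""Simulated disease-exome benchmark.

A single known pathogenic variant (the *spike-in*) is inserted into a healthy
individual's set of rare variants.  A phenotype-specific forest is trained on
pathogenic variants in the term's genes plus the benign background, after
removing every gene present in the test exome (including the spike's gene), so
the model scores only genes it has never seen.  The spike's rank under the
model is compared with its rank under the raw prioritisation score alone.

Conventions the benchmark makes explicit:

* ranks are descending-score with *maximum* (worst) rank for ties —
  conservative for the spike;
* variants that cannot be scored by a method (missing predictors) are
  excluded from that method's ranking, so the two rankings may differ in
  length; both lengths are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import forest
from .cohorts import (
    TermGeneSet,
    build_term_dataset,
    maf_columns,
    score_column,
    variant_ids,
    TermRejection,
)
from .forest import ForestConfig
from .synthetic import ExomeSample

__all__ = [
    "SpikeInResult",
    "SpikeInSkip",
    "SpikeInSummary",
    "filter_rare",
    "ranks_descending",
    "run_spikein",
    "summarize_spikein",
]


def filter_rare(
    variants: pd.DataFrame,
    cohorts: Optional[Sequence[str]] = None,
    maf_threshold: float = 0.01,
) -> pd.DataFrame:
    """Keep variants rare in every cohort where a frequency is reported.

    A variant is removed only if some present MAF exceeds ``maf_threshold``;
    the boundary value itself is kept (removal is strict ``>``), and variants
    with no reported frequency at all are kept.
    """
    cols = maf_columns(variants, cohorts)
    if not cols:
        return variants
    too_common = (variants[cols] > maf_threshold).any(axis=1)
    return variants.loc[~too_common]


def ranks_descending(scores: np.ndarray) -> np.ndarray:
    """1-based descending-score ranks with maximum (worst) rank for ties."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores must be complete; exclude unscored variants first")
    return rankdata(-scores, method="max").astype(int)


@dataclass
class SpikeInResult:
    """Rank of one spike-in under the model and under the raw score."""

    sample_id: str
    spike_id: str
    rank_varpp: Optional[int]
    rank_baseline: Optional[int]
    n_ranked_varpp: int
    n_ranked_baseline: int
    train_genes: frozenset[str]


@dataclass
class SpikeInSkip:
    """Emitted when a sample's term cannot support training."""

    sample_id: str
    reason: str


def _rank_of(ids: pd.Index, scores: pd.Series, target: str) -> tuple[Optional[int], int]:
    scored = scores.notna().to_numpy()
    ids_s = ids[scored]
    ranks = ranks_descending(scores.to_numpy()[scored]) if scored.any() else np.array([], int)
    n_ranked = int(scored.sum())
    hits = np.flatnonzero(ids_s == target)
    if len(hits) == 0:
        return None, n_ranked
    return int(ranks[hits[0]]), n_ranked


def run_spikein(
    sample: ExomeSample,
    term_genes: TermGeneSet,
    pathogenic_pool: pd.DataFrame,
    benign_pool: pd.DataFrame,
    features: pd.DataFrame,
    score_name: str,
    config: ForestConfig,
    rng: Optional[np.random.Generator] = None,
    min_genes: int = 25,
) -> Union[SpikeInResult, SpikeInSkip]:
    """Train on held-out genes and rank the exome's variants.

    Skips the sample if the term has fewer than ``min_genes`` genes, or if
    after excluding every exome gene the surviving pathogenic variants span
    fewer than ``min_genes`` genes.  The trained model never sees any gene of
    the test exome (asserted); a violation raises rather than silently leaking.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(term_genes.genes) < min_genes:
        return SpikeInSkip(
            sample.sample_id,
            f"term {term_genes.term_id} has {len(term_genes.genes)} genes "
            f"(minimum {min_genes})",
        )

    test = sample.all_variants()
    test_ids = variant_ids(test)
    spike_id = variant_ids(sample.spike.to_frame().T)[0]
    exome_genes = set(test["gene"])

    train_path = pathogenic_pool.loc[~pathogenic_pool["gene"].isin(exome_genes)]
    train_benign = benign_pool.loc[~benign_pool["gene"].isin(exome_genes)]
    dataset = build_term_dataset(
        term_genes, train_path, train_benign, features, score_name, min_genes=min_genes
    )
    if isinstance(dataset, TermRejection):
        return SpikeInSkip(
            sample.sample_id, f"after exome-gene exclusion: {dataset.reason}"
        )
    train_genes = frozenset(dataset.genes)
    if train_genes & exome_genes:
        raise RuntimeError(
            f"gene leakage into training set: {sorted(train_genes & exome_genes)[:5]}"
        )

    model = forest.fit(dataset, config, rng)

    score_col = score_column(test, score_name)
    in_features = test["gene"].isin(features.index).to_numpy()
    X = pd.DataFrame(
        {score_name: test[score_col].to_numpy()}, index=range(len(test))
    )
    feat = pd.DataFrame(
        np.nan, index=X.index, columns=features.columns, dtype=float
    )
    feat.loc[in_features] = features.loc[test["gene"].to_numpy()[in_features]].to_numpy()
    X = pd.concat([X, feat], axis=1)
    X.index = test_ids

    varpp_scores = forest.predict(model, X)["probability"]
    baseline_scores = pd.Series(test[score_col].to_numpy(), index=test_ids)

    rank_varpp, n_varpp = _rank_of(test_ids, varpp_scores, spike_id)
    rank_base, n_base = _rank_of(test_ids, baseline_scores, spike_id)
    return SpikeInResult(
        sample_id=sample.sample_id,
        spike_id=spike_id,
        rank_varpp=rank_varpp,
        rank_baseline=rank_base,
        n_ranked_varpp=n_varpp,
        n_ranked_baseline=n_base,
        train_genes=train_genes,
    )


@dataclass
class SpikeInSummary:
    """Aggregate spike-in statistics over samples."""

    n: int
    n_skipped: int
    n_both_ranked: int
    n_better_or_equal: int
    frac_better_or_equal: float
    n_top_varpp: int
    n_top_baseline: int
    frac_top_varpp: float
    frac_top_baseline: float
    n_restricted: int
    n_restricted_better_or_equal: int
    frac_restricted_better_or_equal: float
    top_k: int


def summarize_spikein(
    results: Sequence[Union[SpikeInResult, SpikeInSkip]], top_k: int = 50
) -> SpikeInSummary:
    """Count spikes ranked better-or-equal by the model and top-k appearances.

    The restricted comparison considers only spikes ranked within ``top_k`` by
    at least one method — the clinically relevant short list.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    kept = [r for r in results if isinstance(r, SpikeInResult)]
    skipped = len(results) - len(kept)
    both = [r for r in kept if r.rank_varpp is not None and r.rank_baseline is not None]
    better = [r for r in both if r.rank_varpp <= r.rank_baseline]
    top_v = [r for r in kept if r.rank_varpp is not None and r.rank_varpp <= top_k]
    top_b = [r for r in kept if r.rank_baseline is not None and r.rank_baseline <= top_k]
    restricted = [
        r
        for r in both
        if (r.rank_varpp is not None and r.rank_varpp <= top_k)
        or (r.rank_baseline is not None and r.rank_baseline <= top_k)
    ]
    restricted_better = [r for r in restricted if r.rank_varpp <= r.rank_baseline]

    def _frac(num: int, den: int) -> float:
        return num / den if den else 0.0

    return SpikeInSummary(
        n=len(kept),
        n_skipped=skipped,
        n_both_ranked=len(both),
        n_better_or_equal=len(better),
        frac_better_or_equal=_frac(len(better), len(both)),
        n_top_varpp=len(top_v),
        n_top_baseline=len(top_b),
        frac_top_varpp=_frac(len(top_v), len(kept)),
        frac_top_baseline=_frac(len(top_b), len(kept)),
        n_restricted=len(restricted),
        n_restricted_better_or_equal=len(restricted_better),
        frac_restricted_better_or_equal=_frac(len(restricted_better), len(restricted)),
        top_k=top_k,
    )
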