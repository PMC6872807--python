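"""Training-cohort construction: pathogenic/benign variant filters and per-term datasets.

Variant tables are pandas DataFrames with one row per variant and columns::

    chrom  pos  ref  alt  gene  clinvar  maf_<cohort>...  score_<name>...

``clinvar`` takes the values ``pathogenic``, ``absent`` or ``other``.  Allele
frequencies and rank scores live in ``maf_``/``score_`` prefixed columns and
may be missing (NaN).

The two label filters are deliberately asymmetric:

* pathogenic candidates must be ClinVar-pathogenic and *rare everywhere* —
  a variant is removed if any present MAF is >= the threshold, and a missing
  MAF is treated as 0 (absence of evidence of commonness keeps the variant);
* benign candidates must be absent from ClinVar and *common somewhere* — at
  least one cohort must report MAF >= the threshold, so missing frequencies
  never qualify a variant — and must not fall in any gene that carries a
  retained pathogenic variant (gene-level exclusion, applied globally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence, Union

import numpy as np
import pandas as pd

MAF_PREFIX = "maf_"
SCORE_PREFIX = "score_"

#: Cohort names used by default in generated data (population frequency panels).
DEFAULT_COHORTS = ("1000g", "twinsuk", "alspac", "esp", "exac")

__all__ = [
    "MAF_PREFIX",
    "SCORE_PREFIX",
    "DEFAULT_COHORTS",
    "TermGeneSet",
    "TermDataset",
    "TermRejection",
    "variant_ids",
    "maf_columns",
    "score_column",
    "select_pathogenic",
    "select_benign",
    "build_term_dataset",
]


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` identifier per variant row."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(int).astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str),
        name="variant_id",
    )


def maf_columns(
    variants: pd.DataFrame, cohorts: Optional[Sequence[str]] = None
) -> list[str]:
    """MAF column names, restricted to ``cohorts`` when given."""
    if cohorts is not None:
        cols = [MAF_PREFIX + c for c in cohorts]
        missing = [c for c in cols if c not in variants.columns]
        if missing:
            raise KeyError(f"missing MAF columns: {missing}")
        return cols
    return [c for c in variants.columns if c.startswith(MAF_PREFIX)]


def score_column(variants: pd.DataFrame, score_name: str) -> str:
    col = SCORE_PREFIX + score_name
    if col not in variants.columns:
        raise KeyError(f"unknown score {score_name!r} (no column {col!r})")
    return col


def select_pathogenic(
    variants: pd.DataFrame,
    maf_threshold: float = 0.01,
    cohorts: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """ClinVar-pathogenic variants that are rare in every cohort.

    Keeps rows with ``clinvar == "pathogenic"`` whose maximum present MAF is
    strictly below ``maf_threshold`` (the boundary value itself is removed);
    missing MAFs count as 0.
    """
    if not 0 < maf_threshold < 1:
        raise ValueError("maf_threshold must be in (0, 1)")
    cols = maf_columns(variants, cohorts)
    is_path = variants["clinvar"] == "pathogenic"
    if cols:
        max_maf = variants[cols].fillna(0.0).max(axis=1)
    else:
        max_maf = pd.Series(0.0, index=variants.index)
    return variants.loc[is_path & (max_maf < maf_threshold)]


def select_benign(
    variants: pd.DataFrame,
    pathogenic_genes: FrozenSet[str] | set[str],
    maf_threshold: float = 0.01,
    cohorts: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Benign variants: absent from ClinVar, common in >=1 cohort, outside pathogenic genes.

    ``pathogenic_genes`` should be the global union of genes over all retained
    pathogenic variants, so the benign background is gene-disjoint from every
    term's pathogenic set.
    """
    cols = maf_columns(variants, cohorts)
    is_absent = variants["clinvar"] == "absent"
    if cols:
        common = (variants[cols] >= maf_threshold).any(axis=1)
    else:
        common = pd.Series(False, index=variants.index)
    outside = ~variants["gene"].isin(pathogenic_genes)
    return variants.loc[is_absent & common & outside]


@dataclass(frozen=True)
class TermGeneSet:
    """A phenotype term (opaque identifier) and its associated seed genes."""

    term_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


@dataclass
class TermDataset:
    """One phenotype term's complete-case training table.

    ``X`` holds one row per variant (index = variant id) with the rank-score
    predictor first and one column per tissue feature; ``y`` is True for
    pathogenic rows; ``genes`` gives each row's gene symbol (the clustering
    unit for the bootstrap).
    """

    term_id: str
    X: pd.DataFrame
    y: np.ndarray
    genes: np.ndarray
    score_name: str
    n_dropped_missing_score: int = 0
    n_dropped_missing_gene: int = 0

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_pathogenic_genes(self) -> int:
        return len(np.unique(self.genes[self.y]))


@dataclass
class TermRejection:
    """Returned when a term has too few pathogenic genes to train on."""

    term_id: str
    n_pathogenic_genes: int
    min_genes: int
    reason: str = field(default="")

    def __post_init__(self) -> None:
        if not self.reason:
            self.reason = (
                f"{self.n_pathogenic_genes} pathogenic genes "
                f"(minimum {self.min_genes})"
            )


def build_term_dataset(
    term: TermGeneSet,
    pathogenic: pd.DataFrame,
    benign: pd.DataFrame,
    features: pd.DataFrame,
    score_name: str,
    min_genes: int = 25,
) -> Union[TermDataset, TermRejection]:
    """Assemble the training table for one phenotype term.

    Pathogenic variants are restricted to the term's genes, joined with the
    benign background, and matched by gene symbol to ``features`` (a gene x
    tissue matrix of expression or specificity values).  Variants lacking the
    requested rank score, or whose gene is absent from the feature matrix, are
    dropped and counted.  If fewer than ``min_genes`` distinct genes retain a
    pathogenic variant the term is rejected.
    """
    score_col = score_column(pathogenic, score_name)
    path = pathogenic.loc[pathogenic["gene"].isin(term.genes)]
    table = pd.concat(
        [path.assign(_label=True), benign.assign(_label=False)], ignore_index=True
    )

    has_score = table[score_col].notna()
    n_missing_score = int((~has_score).sum())
    table = table.loc[has_score]

    in_features = table["gene"].isin(features.index)
    n_missing_gene = int((~in_features).sum())
    table = table.loc[in_features]

    n_path_genes = table.loc[table["_label"], "gene"].nunique()
    if n_path_genes < min_genes:
        return TermRejection(term.term_id, n_path_genes, min_genes)

    ids = variant_ids(table)
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate variant ids in term {term.term_id}: "
            f"{ids[ids.duplicated()][:3].tolist()}"
        )

    feat_rows = features.loc[table["gene"].to_numpy()]
    X = pd.concat(
        [
            pd.Series(table[score_col].to_numpy(), name=score_name),
            feat_rows.reset_index(drop=True),
        ],
        axis=1,
    )
    X.index = ids
    assert not X.isna().any().any(), "term dataset must be complete-case"

    return TermDataset(
        term_id=term.term_id,
        X=X,
        y=table["_label"].to_numpy(dtype=bool),
        genes=table["gene"].to_numpy(dtype=object),
        score_name=score_name,
        n_dropped_missing_score=n_missing_score,
        n_dropped_missing_gene=n_missing_gene,
    )
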