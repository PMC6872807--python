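"""Gene-clustered bootstrap random forest for variant pathogenicity.

Variants sharing a gene also share every expression feature, so the rows of a
training table are clustered, not independent.  An ordinary bootstrap over
variants would let members of one gene fall both in-bag and out-of-bag for the
same tree, biasing out-of-bag (OOB) validation optimistically.  The forest
here replaces the bootstrap with a *two-stage* scheme: for each tree, sample G
genes with replacement from the G distinct training genes, then draw a single
variant uniformly within each sampled gene (independently per draw).  Variants
of never-drawn genes form the OOB set, so no gene — and therefore no variant —
can straddle the in-bag/out-of-bag boundary.  Over many trees, roughly
``1 - (1 - 1/G)^G ~ 63%`` of genes are in-bag per tree.

Tree induction itself is standard CART (Gini splits, ``mtry`` features per
split), delegated to scikit-learn on the custom in-bag rows with the library's
own resampling disabled.  OOB votes give per-variant probabilities; unscaled
permutation importance is computed by shuffling each predictor within every
tree's OOB rows and averaging the drop in accuracy over trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cohorts import TermDataset

_FORMAT_VERSION = 1

__all__ = [
    "ForestConfig",
    "BootstrapSample",
    "VarppModel",
    "ImportanceResult",
    "two_stage_bootstrap",
    "fit",
    "oob_predict",
    "predict",
    "permutation_importance",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    Defaults follow common random-forest practice for classification:
    2000 trees, ``mtry = floor(sqrt(p))`` candidate predictors per split,
    Gini impurity, unlimited depth, minimum leaf size 1.
    """

    n_trees: int = 2000
    mtry: Union[int, str] = "sqrt"
    min_leaf: int = 1
    max_depth: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, n_predictors: int) -> int:
        if self.mtry == "sqrt":
            return max(1, int(np.floor(np.sqrt(n_predictors))))
        if not isinstance(self.mtry, int):
            raise ValueError(f"mtry must be an int or 'sqrt', got {self.mtry!r}")
        if self.mtry > n_predictors:
            raise ValueError(f"mtry={self.mtry} exceeds {n_predictors} predictors")
        return self.mtry


@dataclass
class BootstrapSample:
    """One tree's two-stage bootstrap draw.

    ``inbag`` lists the (gene, variant id) pairs actually drawn — one variant
    per gene draw, genes with multiplicity.  ``oob_variants`` holds every
    variant of every never-drawn gene.
    """

    inbag: list[tuple[str, object]]
    oob_variants: set
    inbag_genes: set[str]
    oob_genes: set[str]


def two_stage_bootstrap(
    gene_to_variants: Mapping[str, Sequence], rng: np.random.Generator
) -> BootstrapSample:
    """Draw one gene-clustered bootstrap sample.

    Samples ``G = len(gene_to_variants)`` genes with replacement; each draw
    contributes a single variant chosen uniformly within that gene.  The OOB
    set is every variant whose gene was never drawn, so in-bag and OOB genes
    are disjoint by construction.
    """
    if not gene_to_variants:
        raise ValueError("gene_to_variants is empty")
    genes = list(gene_to_variants)
    for g in genes:
        if len(gene_to_variants[g]) == 0:
            raise ValueError(f"gene {g!r} has no variants")
    n = len(genes)
    draws = rng.integers(0, n, size=n)
    inbag: list[tuple[str, object]] = []
    for d in draws:
        g = genes[d]
        vs = gene_to_variants[g]
        inbag.append((g, vs[rng.integers(0, len(vs))]))
    inbag_genes = {genes[d] for d in draws}
    oob_genes = set(genes) - inbag_genes
    oob_variants = {v for g in oob_genes for v in gene_to_variants[g]}
    return BootstrapSample(inbag, oob_variants, inbag_genes, oob_genes)


@dataclass
class VarppModel:
    """A fitted gene-clustered forest with per-tree bootstrap records."""

    trees: list[DecisionTreeClassifier]
    inbag_rows: list[np.ndarray]       # training row indices, with multiplicity
    oob_rows: list[np.ndarray]         # training row indices OOB per tree
    inbag_gene_codes: list[np.ndarray]  # drawn gene codes (multiset) per tree
    predictor_names: list[str]
    gene_levels: np.ndarray            # code -> gene symbol
    n_rows: int
    config: ForestConfig
    importances: Optional[pd.Series] = field(default=None, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _bootstrap_rows(
    gene_codes: np.ndarray,
    order: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    n_genes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-stage draw over pre-sorted rows.

    ``order`` sorts rows by gene code; ``starts``/``counts`` delimit each
    gene's block within the sorted order.  Returns (inbag rows, OOB rows,
    drawn gene codes).
    """
    draws = rng.integers(0, n_genes, size=n_genes)
    # one uniform variant per gene draw, independently per draw
    offsets = (rng.random(n_genes) * counts[draws]).astype(np.int64)
    inbag = order[starts[draws] + offsets]
    drawn = np.zeros(n_genes, dtype=bool)
    drawn[draws] = True
    oob = np.flatnonzero(~drawn[gene_codes])
    return inbag, oob, draws


def fit(
    dataset: TermDataset,
    config: ForestConfig,
    rng: Optional[np.random.Generator] = None,
) -> VarppModel:
    """Fit the forest on a complete-case term dataset.

    Every tree gets an independent two-stage bootstrap; the in-bag variant
    rows (with multiplicity) are fed to a CART classifier.  Per-tree bootstrap
    records are retained for OOB prediction and permutation importance.  Fully
    reproducible given the generator state (or ``config.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = np.asarray(dataset.y, dtype=np.int8)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    X = dataset.X.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("training data must be complete-case")

    gene_levels, gene_codes = np.unique(
        np.asarray(dataset.genes, dtype=object), return_inverse=True
    )
    n_genes = len(gene_levels)
    order = np.argsort(gene_codes, kind="stable")
    counts = np.bincount(gene_codes, minlength=n_genes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    mtry = config.resolve_mtry(X.shape[1])
    trees: list[DecisionTreeClassifier] = []
    inbag_rows: list[np.ndarray] = []
    oob_rows: list[np.ndarray] = []
    inbag_codes: list[np.ndarray] = []
    for _ in range(config.n_trees):
        inbag, oob, draws = _bootstrap_rows(
            gene_codes, order, starts, counts, n_genes, rng
        )
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=config.min_leaf,
            max_depth=config.max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[inbag], y[inbag])
        trees.append(tree)
        inbag_rows.append(inbag)
        oob_rows.append(oob)
        inbag_codes.append(draws)

    return VarppModel(
        trees=trees,
        inbag_rows=inbag_rows,
        oob_rows=oob_rows,
        inbag_gene_codes=inbag_codes,
        predictor_names=dataset.predictor_names,
        gene_levels=gene_levels,
        n_rows=X.shape[0],
        config=config,
    )


def _vote(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Per-row pathogenic (1) / benign (0) vote of one tree."""
    return tree.predict(X).astype(np.int64)


def oob_predict(model: VarppModel, dataset: TermDataset) -> pd.DataFrame:
    """Out-of-bag probabilities over the training variants.

    For each variant, the probability is the fraction of trees for which the
    variant was out-of-bag that vote pathogenic.  Variants OOB for zero trees
    are left unscored (NaN probability, 0 votes).
    """
    if dataset.X.shape[0] != model.n_rows:
        raise ValueError("dataset does not match the model's training table")
    X = dataset.X.to_numpy(dtype=np.float64)
    votes = np.zeros(model.n_rows, dtype=np.int64)
    n_votes = np.zeros(model.n_rows, dtype=np.int64)
    for tree, oob in zip(model.trees, model.oob_rows):
        if len(oob) == 0:
            continue
        votes[oob] += _vote(tree, X[oob])
        n_votes[oob] += 1
    prob = np.full(model.n_rows, np.nan)
    scored = n_votes > 0
    prob[scored] = votes[scored] / n_votes[scored]
    return pd.DataFrame(
        {"probability": prob, "n_votes": n_votes}, index=dataset.X.index
    )


def predict(model: VarppModel, new_rows: pd.DataFrame) -> pd.DataFrame:
    """Score new variants with the full forest.

    Columns must match the model's predictors exactly.  Complete-case rows get
    the fraction of all trees voting pathogenic; rows with any missing
    predictor are returned unscored.
    """
    if list(new_rows.columns) != model.predictor_names:
        raise ValueError(
            f"predictor columns {list(new_rows.columns)} do not match "
            f"model predictors {model.predictor_names}"
        )
    X = new_rows.to_numpy(dtype=np.float64)
    complete = ~np.isnan(X).any(axis=1)
    prob = np.full(len(new_rows), np.nan)
    n_votes = np.zeros(len(new_rows), dtype=np.int64)
    if complete.any():
        Xc = X[complete]
        votes = np.zeros(Xc.shape[0], dtype=np.int64)
        for tree in model.trees:
            votes += _vote(tree, Xc)
        prob[complete] = votes / model.n_trees
        n_votes[complete] = model.n_trees
    return pd.DataFrame({"probability": prob, "n_votes": n_votes}, index=new_rows.index)


@dataclass
class ImportanceResult:
    """Unscaled permutation importances with tree bookkeeping."""

    importances: pd.Series
    n_trees_used: int
    n_trees_skipped: int


def permutation_importance(
    model: VarppModel,
    dataset: TermDataset,
    rng: Optional[np.random.Generator] = None,
    n_repeats: int = 1,
) -> ImportanceResult:
    """Unscaled OOB permutation importance per predictor.

    For each tree, each predictor is permuted in turn among that tree's OOB
    rows and the drop in OOB classification accuracy is recorded; the
    importance is the plain mean over trees (no standard-deviation scaling).
    Trees with an empty OOB set contribute nothing and are counted as skipped.
    The result is also stored on ``model.importances``.
    """
    if rng is None:
        rng = np.random.default_rng(model.config.seed)
    if dataset.X.shape[0] != model.n_rows:
        raise ValueError("dataset does not match the model's training table")
    X = dataset.X.to_numpy(dtype=np.float64)
    y = np.asarray(dataset.y, dtype=np.int64)
    p = len(model.predictor_names)
    total = np.zeros(p)
    used = 0
    skipped = 0
    for tree, oob in zip(model.trees, model.oob_rows):
        if len(oob) == 0:
            skipped += 1
            continue
        Xo = X[oob]
        yo = y[oob]
        base_acc = float(np.mean(_vote(tree, Xo) == yo))
        for j in range(p):
            drop = 0.0
            for _ in range(n_repeats):
                perm = rng.permutation(len(oob))
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                perm_acc = float(np.mean(_vote(tree, Xp) == yo))
                drop += base_acc - perm_acc
            total[j] += drop / n_repeats
        used += 1
    if used == 0:
        raise ValueError("no tree has a non-empty OOB set")
    result = ImportanceResult(
        importances=pd.Series(total / used, index=model.predictor_names),
        n_trees_used=used,
        n_trees_skipped=skipped,
    )
    model.importances = result.importances
    return result


def save_model(model: VarppModel, path) -> None:
    """Serialise a fitted model (trees, bootstrap records, config) to one archive."""
    joblib.dump({"format_version": _FORMAT_VERSION, "model": model}, path)


def load_model(path) -> VarppModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return payload["model"]
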