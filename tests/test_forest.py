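"""Two-stage bootstrap forest: clustering guarantee, OOB scoring, importance."""

import numpy as np
import pandas as pd
import pytest

from varpp import forest
from varpp.cohorts import TermDataset
from varpp.forest import ForestConfig, two_stage_bootstrap


def toy_dataset(rng, n_genes=20, variants_per_gene=3, informative=True):
    """Small labelled dataset: half the genes pathogenic, score carries signal."""
    genes = np.repeat([f"g{i}" for i in range(n_genes)], variants_per_gene)
    n = len(genes)
    y = np.repeat(np.arange(n_genes) < n_genes // 2, variants_per_gene)
    score = np.where(y, rng.beta(4, 1.5, n), rng.beta(1.5, 4, n)) if informative \
        else rng.uniform(0, 1, n)
    X = pd.DataFrame(
        {
            "rank": score,
            "T0": np.repeat(rng.normal(size=n_genes), variants_per_gene),
            "T1": np.repeat(rng.normal(size=n_genes), variants_per_gene),
        },
        index=[f"v{i}" for i in range(n)],
    )
    return TermDataset(
        term_id="HP:TOY", X=X, y=y, genes=genes.astype(object), score_name="rank"
    )


class TestTwoStageBootstrap:
    def test_single_gene_has_empty_oob(self, rng):
        sample = two_stage_bootstrap({"g0": ["v0", "v1"]}, rng)
        assert sample.inbag_genes == {"g0"}
        assert sample.oob_variants == set()
        assert len(sample.inbag) == 1

    def test_inbag_and_oob_never_share_a_variant(self, rng):
        gene_to_variants = {f"g{i}": [f"v{i}_{j}" for j in range(3)] for i in range(15)}
        for _ in range(50):
            sample = two_stage_bootstrap(gene_to_variants, rng)
            inbag_variants = {v for _, v in sample.inbag}
            assert not inbag_variants & sample.oob_variants
            assert not sample.inbag_genes & sample.oob_genes

    def test_two_gene_oob_probability_is_quarter(self, rng):
        # P(gene OOB) = (1 - 1/2)^2 = 0.25 by enumeration of the 4 draws
        gene_to_variants = {"a": ["va"], "b": ["vb"]}
        hits = sum(
            "a" in two_stage_bootstrap(gene_to_variants, rng).oob_genes
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.25, abs=0.02)

    def test_empty_map_is_an_error(self, rng):
        with pytest.raises(ValueError):
            two_stage_bootstrap({}, rng)


class TestFit:
    def test_records_one_bootstrap_per_tree(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=5), rng)
        assert model.n_trees == 5
        assert len(model.oob_rows) == 5
        assert len(model.inbag_gene_codes) == 5
        assert model.predictor_names == ["rank", "T0", "T1"]

    def test_same_seed_reproduces_bags_and_scores(self, rng):
        ds = toy_dataset(rng)
        m1 = forest.fit(ds, ForestConfig(n_trees=20), np.random.default_rng(5))
        m2 = forest.fit(ds, ForestConfig(n_trees=20), np.random.default_rng(5))
        for a, b in zip(m1.inbag_gene_codes, m2.inbag_gene_codes):
            np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(
            forest.oob_predict(m1, ds), forest.oob_predict(m2, ds)
        )

    def test_single_label_is_an_error(self, rng):
        ds = toy_dataset(rng)
        ds.y = np.ones_like(ds.y)
        with pytest.raises(ValueError, match="both labels"):
            forest.fit(ds, ForestConfig(n_trees=2), rng)

    def test_inbag_and_oob_genes_disjoint_every_tree(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=50), rng)
        gene_of_row = ds.genes
        for draws, oob in zip(model.inbag_gene_codes, model.oob_rows):
            inbag_genes = set(model.gene_levels[draws])
            oob_genes = set(gene_of_row[oob])
            assert not inbag_genes & oob_genes

    def test_mean_distinct_inbag_fraction_near_632(self, rng):
        ds = toy_dataset(rng, n_genes=50)
        model = forest.fit(ds, ForestConfig(n_trees=300), rng)
        fracs = [len(np.unique(d)) / 50 for d in model.inbag_gene_codes]
        expected = 1 - (1 - 1 / 50) ** 50
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


class TestOobPredict:
    def test_probability_is_oob_vote_fraction(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=40), rng)
        oob = forest.oob_predict(model, ds)
        # recompute one variant's vote fraction directly from the stored trees
        X = ds.X.to_numpy()
        scored = oob.index[oob["probability"].notna()]
        target = ds.X.index.get_loc(scored[0])
        votes, n = 0, 0
        for tree, rows in zip(model.trees, model.oob_rows):
            if target in rows:
                votes += int(tree.predict(X[[target]])[0])
                n += 1
        assert n == oob.iloc[target]["n_votes"]
        assert oob.iloc[target]["probability"] == pytest.approx(votes / n)

    def test_single_tree_leaves_inbag_gene_variants_unscored(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=1), rng)
        oob = forest.oob_predict(model, ds)
        inbag_genes = set(model.gene_levels[model.inbag_gene_codes[0]])
        for vid, gene in zip(ds.X.index, ds.genes):
            if gene in inbag_genes:
                assert np.isnan(oob.loc[vid, "probability"])
            else:
                assert not np.isnan(oob.loc[vid, "probability"])

    def test_probabilities_within_unit_interval(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=60), rng)
        probs = forest.oob_predict(model, ds)["probability"].dropna()
        assert ((probs >= 0) & (probs <= 1)).all()


class TestPredict:
    def test_duplicate_rows_get_identical_scores(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=30), rng)
        row = ds.X.iloc[[0]]
        doubled = pd.concat([row, row.set_axis(["copy"])])
        scores = forest.predict(model, doubled)
        assert scores["probability"].iloc[0] == scores["probability"].iloc[1]

    def test_incomplete_rows_are_unscored(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=10), rng)
        rows = ds.X.iloc[:2].copy()
        rows.iloc[1, 0] = np.nan
        scores = forest.predict(model, rows)
        assert not np.isnan(scores["probability"].iloc[0])
        assert np.isnan(scores["probability"].iloc[1])
        assert scores["n_votes"].tolist() == [10, 0]

    def test_single_tree_votes_are_binary(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=1), rng)
        probs = forest.predict(model, ds.X)["probability"]
        assert set(probs.unique()) <= {0.0, 1.0}

    def test_column_mismatch_is_an_error(self, rng):
        ds = toy_dataset(rng)
        model = forest.fit(ds, ForestConfig(n_trees=2), rng)
        with pytest.raises(ValueError, match="do not match"):
            forest.predict(model, ds.X[["T0", "T1", "rank"]])


class TestPermutationImportance:
    def test_constant_column_has_exactly_zero_importance(self, rng):
        ds = toy_dataset(rng)
        ds.X = ds.X.assign(const=1.0)
        model = forest.fit(ds, ForestConfig(n_trees=30), rng)
        imp = forest.permutation_importance(model, ds, rng).importances
        assert imp["const"] == 0.0

    def test_noise_predictor_importance_near_zero(self, rng):
        ds = toy_dataset(rng, n_genes=40)
        ds.X = ds.X.assign(noise=rng.uniform(size=len(ds.X)))
        model = forest.fit(ds, ForestConfig(n_trees=200), rng)
        imp = forest.permutation_importance(model, ds, rng).importances
        # permutation null: |importance| below a loose absolute bound
        assert abs(imp["noise"]) < 0.03

    def test_informative_score_dominates(self, rng):
        ds = toy_dataset(rng, n_genes=40)
        model = forest.fit(ds, ForestConfig(n_trees=200), rng)
        imp = forest.permutation_importance(model, ds, rng).importances
        assert imp.idxmax() == "rank"

    def test_same_seed_gives_bit_identical_importances(self, rng):
        ds = toy_dataset(rng)
        m1 = forest.fit(ds, ForestConfig(n_trees=25), np.random.default_rng(9))
        m2 = forest.fit(ds, ForestConfig(n_trees=25), np.random.default_rng(9))
        i1 = forest.permutation_importance(m1, ds, np.random.default_rng(4)).importances
        i2 = forest.permutation_importance(m2, ds, np.random.default_rng(4)).importances
        pd.testing.assert_series_equal(i1, i2)


def test_model_roundtrips_through_archive(tmp_path, rng):
    ds = toy_dataset(rng)
    model = forest.fit(ds, ForestConfig(n_trees=8), rng)
    path = tmp_path / "model.joblib"
    forest.save_model(model, path)
    loaded = forest.load_model(path)
    assert loaded.predictor_names == model.predictor_names
    pd.testing.assert_frame_equal(
        forest.predict(loaded, ds.X), forest.predict(model, ds.X)
    )
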