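"""Spike-in exome benchmark: rare filter, held-out training, rank summaries."""

import numpy as np
import pandas as pd
import pytest

from varpp.cohorts import TermGeneSet, select_benign, select_pathogenic
from varpp.forest import ForestConfig
from varpp.spikein import (
    SpikeInResult,
    SpikeInSkip,
    filter_rare,
    ranks_descending,
    run_spikein,
    summarize_spikein,
)
from varpp.synthetic import SyntheticConfig, generate, generate_exome


def rare_table(rows):
    table = pd.DataFrame(rows, columns=["maf_a", "maf_b"])
    table.insert(0, "chrom", "1")
    table.insert(1, "pos", np.arange(1, len(table) + 1))
    table.insert(2, "ref", "A")
    table.insert(3, "alt", "G")
    table.insert(4, "gene", "g")
    table.insert(5, "clinvar", "absent")
    return table


class TestFilterRare:
    def test_boundary_maf_is_kept(self):
        kept = filter_rare(rare_table([(0.01, np.nan)]))
        assert len(kept) == 1

    def test_common_variant_removed(self):
        assert len(filter_rare(rare_table([(0.02, 0.001)]))) == 0

    def test_all_missing_maf_kept(self):
        assert len(filter_rare(rare_table([(np.nan, np.nan)]))) == 1

    def test_matches_bruteforce(self, rng):
        mafs = rng.uniform(0, 0.03, (60, 2))
        mafs[rng.random((60, 2)) < 0.3] = np.nan
        table = rare_table(list(map(tuple, mafs)))
        kept = set(filter_rare(table).index)
        brute = {
            i
            for i in range(60)
            if not any(m > 0.01 for m in mafs[i] if not np.isnan(m))
        }
        assert kept == brute


class TestRanks:
    def test_descending_with_worst_tie_rank(self):
        ranks = ranks_descending(np.array([0.9, 0.5, 0.5, 0.1]))
        assert ranks.tolist() == [1, 3, 3, 4]

    def test_rank_invariant_to_input_order(self, rng):
        scores = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert (ranks_descending(scores)[perm] == ranks_descending(scores[perm])).all()


@pytest.fixture(scope="module")
def spikein_setup(small_config):
    data = generate(small_config, np.random.default_rng(21))
    pathogenic = select_pathogenic(data.variants)
    benign = select_benign(data.variants, frozenset(pathogenic["gene"]))
    return data, pathogenic, benign


class TestRunSpikein:
    def test_training_genes_never_overlap_exome(self, small_config, spikein_setup):
        data, pathogenic, benign = spikein_setup
        sample = generate_exome(small_config, np.random.default_rng(22))
        result = run_spikein(
            sample, data.term, pathogenic, benign, data.expression,
            "rank", ForestConfig(n_trees=30), np.random.default_rng(23),
        )
        assert isinstance(result, SpikeInResult)
        exome_genes = set(sample.variants["gene"]) | {sample.spike["gene"]}
        assert not result.train_genes & exome_genes
        assert 1 <= result.rank_varpp <= result.n_ranked_varpp
        assert 1 <= result.rank_baseline <= result.n_ranked_baseline

    def test_identical_seed_gives_identical_result(self, small_config, spikein_setup):
        data, pathogenic, benign = spikein_setup
        sample = generate_exome(small_config, np.random.default_rng(24))
        out = [
            run_spikein(
                sample, data.term, pathogenic, benign, data.expression,
                "rank", ForestConfig(n_trees=40), np.random.default_rng(25),
            )
            for _ in range(2)
        ]
        assert out[0] == out[1]

    def test_rank_invariant_to_background_order(self, small_config, spikein_setup):
        data, pathogenic, benign = spikein_setup
        sample = generate_exome(small_config, np.random.default_rng(26))
        shuffled = generate_exome(small_config, np.random.default_rng(26))
        shuffled.variants = (
            shuffled.variants.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        a = run_spikein(
            sample, data.term, pathogenic, benign, data.expression,
            "rank", ForestConfig(n_trees=40), np.random.default_rng(27),
        )
        b = run_spikein(
            shuffled, data.term, pathogenic, benign, data.expression,
            "rank", ForestConfig(n_trees=40), np.random.default_rng(27),
        )
        assert a.rank_varpp == b.rank_varpp
        assert a.rank_baseline == b.rank_baseline

    def test_small_term_is_skipped(self, small_config, spikein_setup):
        data, pathogenic, benign = spikein_setup
        sample = generate_exome(small_config, np.random.default_rng(28))
        tiny = TermGeneSet("HP:TINY", frozenset(list(data.term.genes)[:10]))
        result = run_spikein(
            sample, tiny, pathogenic, benign, data.expression,
            "rank", ForestConfig(n_trees=5), np.random.default_rng(29),
        )
        assert isinstance(result, SpikeInSkip)
        assert "10 genes" in result.reason

    def test_spike_with_top_raw_score_gets_baseline_rank_one(
        self, small_config, spikein_setup
    ):
        data, pathogenic, benign = spikein_setup
        sample = generate_exome(small_config, np.random.default_rng(30))
        sample.spike = sample.spike.copy()
        sample.spike["score_rank"] = 1.0
        sample.variants = sample.variants.assign(
            score_rank=sample.variants["score_rank"].clip(upper=0.99)
        )
        result = run_spikein(
            sample, data.term, pathogenic, benign, data.expression,
            "rank", ForestConfig(n_trees=20), np.random.default_rng(31),
        )
        assert result.rank_baseline == 1


def res(sample_id, rv, rb, n=200):
    return SpikeInResult(sample_id, "1:1:A:C", rv, rb, n, n, frozenset())


class TestSummarize:
    def test_all_equal_ranks_give_fraction_one(self):
        results = [res(f"s{i}", 7, 7) for i in range(4)]
        out = summarize_spikein(results)
        assert out.frac_better_or_equal == 1.0

    def test_empty_results_give_zero_counts(self):
        out = summarize_spikein([])
        assert out.n == 0
        assert out.n_better_or_equal == 0
        assert out.frac_top_varpp == 0.0

    def test_counts_match_bruteforce(self, rng):
        results = [
            res(f"s{i}", int(rng.integers(1, 120)), int(rng.integers(1, 120)))
            for i in range(60)
        ]
        out = summarize_spikein(results, top_k=50)
        assert out.n_better_or_equal == sum(
            r.rank_varpp <= r.rank_baseline for r in results
        )
        assert out.n_top_varpp == sum(r.rank_varpp <= 50 for r in results)
        assert out.n_top_baseline == sum(r.rank_baseline <= 50 for r in results)
        restricted = [
            r for r in results if r.rank_varpp <= 50 or r.rank_baseline <= 50
        ]
        assert out.n_restricted == len(restricted)
        assert out.n_restricted_better_or_equal == sum(
            r.rank_varpp <= r.rank_baseline for r in restricted
        )

    def test_skips_counted_separately(self):
        results = [res("a", 1, 2), SpikeInSkip("b", "too few genes")]
        out = summarize_spikein(results)
        assert out.n == 1
        assert out.n_skipped == 1
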