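import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dipkit.genomic_io import GenomicInterval, TagSet
from dipkit.integration import (
    GeneMethylationProfile,
    adjust_overlap_family,
    gene_methylation_profiles,
    kmeans_profiles,
    median_window_density,
    metagene_matrix,
    overlap_test,
    pool_in_silico,
    pooled_region_test,
    row_scaled_heatmap,
    silhouette_scan,
)
from dipkit.segmentation import count_windows
from dipkit.simulate import SimParams, gene_expression_levels, simulate_genome


class TestOverlapTest:
    def test_enumeration_oracle_small_universe(self):
        # table (3,2,1,14): |A|=5, |B|=4, overlap 3, universe 20; the
        # two-sided Fisher p is the minlike sum over the hypergeometric
        universe = [f"g{i}" for i in range(20)]
        a = set(universe[:5])
        b = set(universe[:3]) | {universe[7]}
        res = overlap_test(a, b, universe)
        pmf = [stats.hypergeom.pmf(k, 20, 5, 4) for k in range(5)]
        obs = pmf[3]
        expected = sum(x for x in pmf if x <= obs * (1 + 1e-7))
        assert res.p == pytest.approx(expected, rel=1e-9)
        assert res.n_overlap == 3

    def test_symmetry_in_the_two_sets(self):
        universe = [f"g{i}" for i in range(50)]
        a, b = set(universe[:10]), set(universe[5:20])
        r1 = overlap_test(a, b, universe)
        r2 = overlap_test(b, a, universe)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)

    def test_independence_expectation_gives_odds_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        a = set(universe[:50])
        b = set(universe[25:35]) | set(universe[75:85])  # 10 in, 10 out
        res = overlap_test(a, b, universe)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == 1.0

    def test_family_bh_adjustment(self):
        universe = [f"g{i}" for i in range(30)]
        tests = [
            overlap_test(set(universe[:8]), set(universe[:6]), universe, "u", "u"),
            overlap_test(set(universe[:8]), set(universe[20:26]), universe, "u", "d"),
        ]
        adj = adjust_overlap_family(tests)
        assert adj[0].q >= adj[0].p and adj[1].q >= adj[1].p

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test(set(), set(), [])

    def test_inconsistent_overlap_rejected(self):
        from dipkit.integration import OverlapTest

        with pytest.raises(ValueError):
            OverlapTest("a", "b", 3, 3, 4, 100, 1.0, 0.5)


class TestPooling:
    def _ts(self, positions, lib="a", genome=None):
        genome = genome or {"chr1": 10_000}
        return TagSet(lib, "5mC", "sham", [("chr1", p, "+") for p in positions], genome)

    def test_pooling_single_replicate_is_identity(self):
        ts = self._ts([1, 5, 9])
        pooled = pool_in_silico([ts])
        assert list(pooled.iter_tags()) == list(ts.iter_tags())

    def test_tag_conservation(self):
        rng = np.random.default_rng(0)
        a = self._ts(sorted(rng.integers(0, 10_000, 1000).tolist()), "a")
        b = self._ts(sorted(rng.integers(0, 10_000, 1000).tolist()), "b")
        pooled = pool_in_silico([a, b])
        assert pooled.n_tags == 2000
        assert pooled.library_id == "a+b"

    def test_pooled_window_counts_are_additive(self):
        rng = np.random.default_rng(1)
        reps = [self._ts(sorted(rng.integers(0, 10_000, 500).tolist()), f"r{i}") for i in range(3)]
        pooled = pool_in_silico(reps)
        wc_pool = count_windows(pooled, 1000, 500).all_counts()
        wc_sum = sum(count_windows(r, 1000, 500).all_counts() for r in reps)
        np.testing.assert_array_equal(wc_pool, wc_sum)

    def test_mismatched_genomes_rejected(self):
        a = self._ts([1])
        b = self._ts([1], genome={"chr1": 20_000})
        with pytest.raises(ValueError, match="genome"):
            pool_in_silico([a, b])


class TestPooledRegionTest:
    def _pair(self, pos_a, pos_b, genome_len=100_000):
        genome = {"chr1": genome_len}
        a = TagSet.from_arrays("a", "5mC", "sham", {"chr1": np.sort(np.asarray(pos_a))}, genome)
        b = TagSet.from_arrays("b", "5mC", "irradiated", {"chr1": np.sort(np.asarray(pos_b))}, genome)
        return a, b

    def test_equal_proportions_give_p_one(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 100_000, 1000)
        a, b = self._pair(pos, pos.copy())
        df = pooled_region_test(a, b, [GenomicInterval("chr1", 0, 10_000)])
        assert df.loc[0, "p"] == 1.0
        assert df.loc[0, "direction"] == "none"

    def test_matches_fisher_oracle_table(self):
        # (30, 970) vs (10, 990): compare against scipy on the same table
        rng = np.random.default_rng(3)
        pos_a = np.concatenate([rng.integers(0, 1000, 30), rng.integers(1000, 100_000, 970)])
        pos_b = np.concatenate([rng.integers(0, 1000, 10), rng.integers(1000, 100_000, 990)])
        a, b = self._pair(pos_a, pos_b)
        df = pooled_region_test(a, b, [GenomicInterval("chr1", 0, 1000)])
        _, expected = stats.fisher_exact([[30, 970], [10, 990]])
        assert df.loc[0, "p"] == pytest.approx(expected, rel=1e-9)
        assert df.loc[0, "direction"] == "down"  # fewer tags in irradiated

    def test_zero_tag_library_rejected(self):
        a, b = self._pair([1], [])
        with pytest.raises(ValueError, match="zero tags"):
            pooled_region_test(a, b, [])


class TestKmeansProfiles:
    def _profiles(self, X):
        return [GeneMethylationProfile(f"g{i}", np.asarray(x, dtype=float)) for i, x in enumerate(X)]

    def test_k1_single_cluster_total_variance(self):
        X = np.array([[0.0, 0], [1, 1], [2, 2]])
        out, inertia = kmeans_profiles(self._profiles(X), k=1)
        assert {p.cluster for p in out} == {0}
        Xs = (X - X.mean(0)) / X.std(0)
        assert inertia == pytest.approx(((Xs - Xs.mean(0)) ** 2).sum())

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0, 0.1, size=(20, 3))
        blob2 = rng.normal(5, 0.1, size=(10, 3))
        out, _ = kmeans_profiles(self._profiles(np.vstack([blob1, blob2])), k=2, seed=1)
        labels = np.array([p.cluster for p in out])
        assert (labels[:20] == 0).all() and (labels[20:] == 1).all()  # larger blob first

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        out1, i1 = kmeans_profiles(self._profiles(X), k=3, seed=7)
        out2, i2 = kmeans_profiles(self._profiles(X), k=3, seed=7)
        assert [p.cluster for p in out1] == [p.cluster for p in out2]
        assert i1 == i2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(self._profiles(np.zeros((2, 2))), k=3)

    def test_silhouette_scan_reports_requested_range(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.2, (15, 3)), rng.normal(4, 0.2, (15, 3))])
        scores = silhouette_scan(self._profiles(X), k_range=range(2, 5))
        assert list(scores.index) == [2, 3, 4]
        assert scores.idxmax() == 2

    def test_nonfinite_features_rejected(self):
        df = pd.DataFrame({"f": [1.0, np.inf]}, index=["a", "b"])
        with pytest.raises(ValueError, match="finite"):
            gene_methylation_profiles(["a", "b"], df)


class TestMetagene:
    def test_uniform_tags_give_flat_profile(self, uniform_tags):
        params = SimParams(seed=7)
        _, genes = simulate_genome(params)
        mat, _ = metagene_matrix(uniform_tags, genes)
        profile = mat.to_numpy().mean(axis=0)
        cv = profile.std() / profile.mean()
        assert cv < 0.1
        assert profile.mean() == pytest.approx(1.0, abs=0.1)

    def test_rows_sorted_by_descending_expression(self, uniform_tags):
        params = SimParams(seed=7)
        _, genes = simulate_genome(params)
        expr = gene_expression_levels(params, genes)
        mat, order = metagene_matrix(uniform_tags, genes, expression=expr)
        vals = [expr[g] for g in order]
        assert vals == sorted(vals, reverse=True)

    def test_short_gene_skipped_with_warning(self):
        genome = {"chr1": 100_000}
        rng = np.random.default_rng(8)
        ts = TagSet.from_arrays("t", "5mC", "sham",
                                {"chr1": np.sort(rng.integers(0, 100_000, 5000))}, genome)
        from dipkit.genomic_io import GeneModel

        tiny = GeneModel("tiny", GenomicInterval("chr1", 500, 550, "+"), "+")
        ok = GeneModel("ok", GenomicInterval("chr1", 10_000, 60_000, "+"), "+")
        with pytest.warns(UserWarning, match="skipped 1"):
            mat, order = metagene_matrix(ts, [tiny, ok], flank_bp=1000, n_body_bins=100, n_flank_bins=10)
        assert order == ["ok"]

    def test_median_density_of_uniform_library(self, uniform_tags):
        # 50k tags over 10 Mb per chromosome = 5 tags/kb
        assert median_window_density(uniform_tags) == pytest.approx(0.005, rel=0.1)


class TestRowScaledHeatmap:
    def test_constant_row_scales_to_zero(self, tmp_path):
        fig, scaled = row_scaled_heatmap(np.array([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]]),
                                         path=str(tmp_path / "h.png"))
        np.testing.assert_allclose(scaled[0], 0.0)
        assert (tmp_path / "h.png").exists()

    def test_hand_computed_zscores(self):
        _, scaled = row_scaled_heatmap(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(scaled[0], [-1.225, 0.0, 1.225], atol=1e-3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            row_scaled_heatmap(np.empty((0, 0)))


class TestCrossDatasetHarness:
    def test_concordant_experiments_overlap_significantly(self):
        # two synthetic "experiments" sharing half their true gene sets
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(400)]
        shared = set(rng.choice(universe, 40, replace=False))
        a = shared | set(rng.choice(universe, 20, replace=False))
        b = shared | set(rng.choice(universe, 20, replace=False))
        res = overlap_test(a, b, universe)
        assert res.p < 0.01

    def test_independent_experiments_near_uniform(self):
        rng = np.random.default_rng(10)
        universe = [f"g{i}" for i in range(400)]
        pvals = []
        for k in range(40):
            a = set(rng.choice(universe, 50, replace=False))
            b = set(rng.choice(universe, 50, replace=False))
            pvals.append(overlap_test(a, b, universe).p)
        assert (np.array(pvals) <= 0.05).mean() <= 0.15
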