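import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dipkit.annotation import GeneRegionAnnotation
from dipkit.bidirectional import (
    assign_gene_classes,
    bidirectional_recovery_report,
    density_vs_significance,
    dhr_density_bins,
    find_bidirectional_genes,
    hypergeom_overlap_p,
    permutation_density_test,
)
from dipkit.differential import DifferentialRegion
from dipkit.genomic_io import GeneModel, GenomicInterval


def annot(chrom, start, end, p=0.001, gene_id=None):
    r = DifferentialRegion(GenomicInterval(chrom, start, end), "5hmC", 10.0, 1.0, p, p * 2, "up", 0.05)
    return GeneRegionAnnotation(r, gene_id, 0 if gene_id else None, "intragenic")


def gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), strand)


class TestOverlapHypergeometric:
    def test_enumeration_oracle_20_gene_universe(self):
        # exhaustive oracle: enumerate all C(20, 4) draws of the "down"
        # set and count overlaps >= 3 with a fixed 5-gene "up" set
        universe, n_up, n_down, k_obs = 20, 5, 4, 3
        hits = total = 0
        up = set(range(n_up))
        for draw in itertools.combinations(range(universe), n_down):
            total += 1
            hits += len(up & set(draw)) >= k_obs
        expected = hits / total
        assert hypergeom_overlap_p(n_up, n_down, k_obs, universe) == pytest.approx(expected, rel=1e-12)

    def test_disjoint_sets_give_p_one(self):
        res = find_bidirectional_genes({"a", "b"}, {"c", "d"}, 10)
        assert res.bidirectional_genes == set()
        assert res.overlap_p == 1.0

    def test_universe_smaller_than_set_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap_p(5, 4, 3, 4)

    def test_annotations_and_sets_agree(self):
        # set-algebra equivalence: same result from annotation lists or ids
        up_ann = [annot("chr1", 0, 100, gene_id="g1"), annot("chr1", 200, 300, gene_id="g2"),
                  annot("chr1", 400, 500, gene_id="g2"), annot("chr1", 600, 700)]
        down_ann = [annot("chr1", 800, 900, gene_id="g2"), annot("chr1", 1000, 1100, gene_id="g3")]
        r1 = find_bidirectional_genes(up_ann, down_ann, ["g1", "g2", "g3", "g4"])
        r2 = find_bidirectional_genes({"g1", "g2"}, {"g2", "g3"}, 4)
        assert r1.bidirectional_genes == r2.bidirectional_genes == {"g2"}
        assert r1.overlap_p == r2.overlap_p


class TestDensityBins:
    def test_default_bin_layout_matches_published_settings(self):
        g = gene("g", "chr1", 100_000, 320_000)  # 220 kb
        dhrs = [annot("chr1", 100_000 + off - 500, 100_000 + off + 500)
                for off in (10_000, 60_000, 110_000, 160_000)]
        table = dhr_density_bins([g], dhrs)
        assert table.loc["g"].tolist() == [1, 1, 1, 1]

    def test_minus_strand_mirror_gives_same_row(self):
        g = gene("g", "chr1", 100_000, 320_000, "-")
        # offsets measured from the TSS at 319_999 leftwards
        dhrs = [annot("chr1", 320_000 - off - 500, 320_000 - off + 500)
                for off in (10_000, 60_000, 110_000, 160_000)]
        table = dhr_density_bins([g], dhrs)
        assert table.loc["g"].tolist() == [1, 1, 1, 1]

    def test_short_genes_removed(self):
        short = gene("s", "chr1", 0, 150_000)
        long_ = gene("l", "chr1", 200_000, 500_000)
        table = dhr_density_bins([short, long_], [])
        assert list(table.index) == ["l"]
        assert (table.to_numpy() == 0).all()

    def test_bins_exceeding_min_length_rejected(self):
        with pytest.raises(ValueError, match="past the minimum"):
            dhr_density_bins([], [], min_gene_length_bp=150_000)

    def test_strand_symmetry_under_coordinate_mirror(self):
        L = 1_000_000
        g_fwd = gene("g", "chr1", 100_000, 350_000, "+")
        offs = [(12_000, 13_000), (70_000, 72_000), (180_000, 181_000)]
        dhrs_fwd = [annot("chr1", 100_000 + a, 100_000 + b) for a, b in offs]
        # mirror x -> L - x and flip the strand
        g_rev = gene("g", "chr1", L - 350_000, L - 100_000, "-")
        dhrs_rev = [annot("chr1", L - (100_000 + b), L - (100_000 + a)) for a, b in offs]
        t1 = dhr_density_bins([g_fwd], dhrs_fwd)
        t2 = dhr_density_bins([g_rev], dhrs_rev)
        pd.testing.assert_frame_equal(t1, t2)


class TestPermutationDensityTest:
    def _table(self, rows, labels):
        idx = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx, columns=[f"bin_{i+1}" for i in range(len(rows[0]))]), {
            f"g{i}": l for i, l in enumerate(labels)
        }

    def test_identical_rows_give_p_one(self):
        table, labels = self._table([[1, 2, 3, 4]] * 5, ["bidirectional"] * 3 + ["up_only"] * 2)
        res = permutation_density_test(table, labels, ("bidirectional", "up_only"))
        assert res.global_statistic == 0.0
        assert res.global_p == 1.0

    def test_small_contrast_enumerated_exactly(self):
        table, labels = self._table(
            [[5, 5, 5, 5], [6, 6, 6, 6], [7, 7, 7, 7], [1, 1, 1, 1], [2, 2, 2, 2]],
            ["bidirectional"] * 3 + ["up_only"] * 2,
        )
        res = permutation_density_test(table, labels, ("bidirectional", "up_only"), n_permutations=10)
        assert res.exact and res.n_permutations == math.comb(5, 3)
        # manual enumeration of the global statistic over all 10 splits
        data = table.to_numpy(dtype=float)
        obs = data[:3].mean(axis=0).sum() - data[3:].mean(axis=0).sum()
        hits = 0
        for combo in itertools.combinations(range(5), 3):
            mask = np.zeros(5, dtype=bool)
            mask[list(combo)] = True
            t = data[mask].mean(axis=0).sum() - data[~mask].mean(axis=0).sum()
            hits += abs(t) >= abs(obs) - 1e-12
        assert res.global_p == pytest.approx(hits / math.comb(5, 3))

    def test_null_calibration_under_label_exchange(self):
        # both classes from one distribution: exact-p rejection rate at
        # alpha = 0.05 stays near nominal over 500 simulated datasets
        rng = np.random.default_rng(8)
        rejections = 0
        n_data = 500
        for k in range(n_data):
            rows = rng.normal(size=(20, 4))
            table = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)],
                                 columns=[f"bin_{i+1}" for i in range(4)])
            labels = {f"g{i}": ("bidirectional" if i < 10 else "up_only") for i in range(20)}
            res = permutation_density_test(table, labels, ("bidirectional", "up_only"),
                                           n_permutations=199, seed=k)
            rejections += res.global_p <= 0.05
        assert 0.03 <= rejections / n_data <= 0.07

    def test_empty_class_rejected(self):
        table, labels = self._table([[1, 2]] * 3, ["bidirectional"] * 3)
        with pytest.raises(ValueError, match="non-empty"):
            permutation_density_test(table, labels, ("bidirectional", "up_only"))


class TestDensityVsSignificance:
    def _setup(self, ps, n=5):
        genes = [gene(f"g{i}", "chr1", i * 400_000, i * 400_000 + 300_000) for i in range(n)]
        dhrs = []
        table = pd.DataFrame(0, index=[g.gene_id for g in genes], columns=["bin_1", "bin_2"])
        for i, g in enumerate(genes):
            for k in range(i + 1):
                s = g.interval.start + 1000 + 2000 * k
                dhrs.append(annot("chr1", s, s + 1000, p=ps[i]))
            table.loc[g.gene_id, "bin_1"] = i + 1
        return genes, dhrs, table

    def test_monotone_construction_gives_rho_one(self):
        ps = [0.5, 0.1, 0.01, 0.001, 1e-5]  # smaller p with higher density
        genes, dhrs, table = self._setup(ps)
        res = density_vs_significance(genes, dhrs, table)
        assert res.rho == pytest.approx(1.0)

    def test_constant_density_flagged_degenerate(self):
        genes = [gene(f"g{i}", "chr1", i * 400_000, i * 400_000 + 300_000) for i in range(3)]
        dhrs = [annot("chr1", g.interval.start + 1000, g.interval.start + 2000, p=0.01 * (i + 1))
                for i, g in enumerate(genes)]
        table = pd.DataFrame(1, index=[g.gene_id for g in genes], columns=["bin_1"])
        res = density_vs_significance(genes, dhrs, table)
        assert res.degenerate and res.rho == 0.0

    def test_too_few_genes_rejected(self):
        genes, dhrs, table = self._setup([0.1, 0.2], n=2)
        with pytest.raises(ValueError, match=">= 3"):
            density_vs_significance(genes, dhrs, table)


class TestRecoveryReport:
    def _result(self, up, down):
        return find_bidirectional_genes(up, down, 100)

    def test_perfect_detection(self):
        res = self._result({"a", "b"}, {"a", "b"})
        assert bidirectional_recovery_report(res, ["a", "b"]) == (1.0, 1.0)

    def test_empty_detection_gives_nan_precision(self):
        res = self._result({"a"}, {"b"})
        recall, precision = bidirectional_recovery_report(res, ["a"])
        assert recall == 0.0 and math.isnan(precision)

    def test_class_assignment_partition(self):
        labels = assign_gene_classes(["a", "b", "c", "d"], {"a", "b"}, {"b", "c"})
        assert labels == {"a": "up_only", "b": "bidirectional", "c": "down_only", "d": "control"}
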