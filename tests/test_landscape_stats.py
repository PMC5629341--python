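import math

import numpy as np
import pytest

from ltrcall import landscape_stats as LS
from ltrcall.chromatin import ChromatinPartition
from ltrcall.formats_io import GenomicInterval


class TestDensity:
    def test_zero_insertions(self):
        dens, total = LS.insertion_density({}, {"chr1": 1_000_000, "chr2": 2_000_000})
        assert (dens == 0).all() and total == 0

    def test_simple_density(self):
        dens, total = LS.insertion_density({"chr1": 10}, {"chr1": 2_000_000})
        assert dens["chr1"] == pytest.approx(5.0) and total == pytest.approx(5.0)

    def test_zero_length_chromosome_errors(self):
        with pytest.raises(ValueError):
            LS.insertion_density({"chr1": 1}, {"chr1": 0})


class TestClassification:
    def test_exon_point(self, hand_annotation):
        assert LS.classify_insertion("chr1", 1300, hand_annotation) == "exon"

    def test_promoter_under_500(self, hand_annotation):
        # 300 bp upstream of geneA's + strand TSS at 1000
        assert LS.classify_insertion("chr1", 700, hand_annotation) == "promoter_lt500"

    def test_promoter_500_to_1000_minus_strand(self, hand_annotation):
        # geneB is - strand with TSS side at 8000; 8700 is 700 bp upstream
        assert LS.classify_insertion("chr1", 8700, hand_annotation) == "promoter_500_1000"

    def test_feature_precedence(self, hand_annotation):
        assert LS.classify_insertion("chr1", 1100, hand_annotation) == "utr5"
        assert LS.classify_insertion("chr1", 1800, hand_annotation) == "intron"
        assert LS.classify_insertion("chr1", 2900, hand_annotation) == "utr3"
        assert LS.classify_insertion("chr1", 9200, hand_annotation) == "te"
        assert LS.classify_insertion("chr1", 12_000, hand_annotation) == "intergenic_gt1000"

    def test_outside_assembly_errors(self, hand_annotation):
        with pytest.raises(ValueError):
            LS.classify_insertion("chr1", 99_999, hand_annotation, {"chr1": 20_000})

    def test_classification_is_total(self, hand_annotation):
        """Every point gets exactly one category; counts sum to n points."""
        rng = np.random.default_rng(0)
        points = rng.integers(0, 15_000, size=300)
        cats = [LS.classify_insertion("chr1", int(p), hand_annotation) for p in points]
        table = LS.category_table(cats)
        assert table["count"].sum() == 300


class TestCategoryTable:
    def test_single_category(self):
        table = LS.category_table(["exon"] * 7)
        assert table.loc["exon", "percent"] == 100.0
        assert table["percent"].drop("exon").sum() == 0.0

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            LS.category_table(["nonsense"])


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert LS.fisher_exact_2x2([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)

    def test_small_table_by_enumeration(self):
        # margins r1=3, c1=3, N=6: pmf (1,9,9,1)/20; observed a=2 -> p = 1
        assert LS.fisher_exact_2x2([[2, 1], [1, 2]]).p_value == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert LS.fisher_exact_2x2([[0, 0], [3, 4]]).p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LS.fisher_exact_2x2([[1, -1], [2, 3]])


class TestHypergeom:
    def test_saturated_case(self):
        res = LS.genic_enrichment_hypergeom(6, 6, 1000, 1000)
        assert res.p_value == pytest.approx(1.0)

    def test_small_case_matches_direct_sum(self):
        # 5 of 6 draws genic with half the population genic
        M, K, n = 100, 50, 6
        direct = sum(
            math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)
            for k in range(5, n + 1)
        )
        res = LS.genic_enrichment_hypergeom(5, 6, K, M)
        assert res.p_value == pytest.approx(direct, rel=1e-12)


class TestMatchedLoci:
    @pytest.fixture()
    def partition(self):
        eu = [GenomicInterval("chr1", 0, 500_000), GenomicInterval("chr1", 700_000, 1_000_000),
              GenomicInterval("chr2", 0, 800_000)]
        return ChromatinPartition([GenomicInterval("chr1", 500_000, 700_000)], eu)

    def test_empty_calls(self, partition):
        assert LS.sample_matched_loci([], partition, np.random.default_rng(0)) == []

    def test_per_chromosome_counts_preserved(self, partition):
        rng = np.random.default_rng(1)
        calls = [GenomicInterval("chr1", 10, 15)] * 7 + [GenomicInterval("chr2", 10, 15)] * 3
        loci = LS.sample_matched_loci(calls, partition, rng)
        assert sum(l.chrom == "chr1" for l in loci) == 7
        assert sum(l.chrom == "chr2" for l in loci) == 3
        assert all(len(l) == 5 for l in loci)

    def test_loci_never_cross_class_boundaries(self, partition):
        rng = np.random.default_rng(2)
        calls = [GenomicInterval("chr1", 0, 5000)] * 200
        for l in LS.sample_matched_loci(calls, partition, rng):
            assert any(iv.start <= l.start and l.end <= iv.end
                       for iv in partition.euchromatin)

    def test_marginal_uniformity(self):
        """Positions are uniform within euchromatin (chi-square GOF)."""
        from scipy import stats
        eu = [GenomicInterval("chr1", 0, 1_000_000)]
        part = ChromatinPartition([], eu)
        rng = np.random.default_rng(3)
        calls = [GenomicInterval("chr1", 0, 2)] * 10_000
        loci = LS.sample_matched_loci(calls, part, rng)
        counts, _ = np.histogram([l.start for l in loci], bins=20, range=(0, 1_000_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001


class TestWindowVariance:
    def _windows(self):
        return [GenomicInterval("chr1", i * 100, i * 100 + 100) for i in range(10)]

    def test_equal_counts_zero_variance(self):
        loci = [GenomicInterval("chr1", i * 100 + 50, i * 100 + 51) for i in range(10)]
        assert LS.window_count_variance(loci, self._windows()) == 0.0

    def test_matches_direct_formula(self):
        loci = [GenomicInterval("chr1", 50, 51)] * 4 + [GenomicInterval("chr1", 250, 251)]
        counts = np.zeros(10)
        counts[0], counts[2] = 4, 1
        assert LS.window_count_variance(loci, self._windows()) == pytest.approx(counts.var())

    def test_window_order_invariance(self):
        rng = np.random.default_rng(4)
        loci = [GenomicInterval("chr1", int(p), int(p) + 1)
                for p in rng.integers(0, 1000, size=30)]
        w = self._windows()
        shuffled = [w[i] for i in rng.permutation(len(w))]
        assert LS.window_count_variance(loci, w) == \
            LS.window_count_variance(loci, shuffled)


class TestPermutationTest:
    def test_observed_zero_variance_p_near_one(self):
        eu = [GenomicInterval("chr1", 0, 2_000_000)]
        part = ChromatinPartition([], eu)
        rng = np.random.default_rng(5)
        # evenly spread calls: observed variance at the low end of the null
        calls = [GenomicInterval("chr1", i * 20_000 + 10_000, i * 20_000 + 10_001)
                 for i in range(100)]
        res = LS.permutation_variance_test(calls, part, rng, n_perm=200)
        assert res.p_value > 0.5

    def test_gamma_p_close_to_empirical_tail(self):
        eu = [GenomicInterval("chr1", 0, 3_000_000)]
        part = ChromatinPartition([], eu)
        rng = np.random.default_rng(6)
        calls = [GenomicInterval("chr1", int(p), int(p) + 5)
                 for p in rng.integers(0, 3_000_000 - 5, size=100)]
        res = LS.permutation_variance_test(calls, part, rng, n_perm=2000)
        if res.p_value > 0.01:
            assert abs(res.p_value - res.empirical_p) < 0.05


class TestGammaMoments:
    def test_moment_identities(self):
        rng = np.random.default_rng(7)
        sample = rng.gamma(2.5, 1.7, size=50_000)
        k, theta = LS.fit_gamma_moments(sample)
        assert k == pytest.approx(np.mean(sample) ** 2 / np.var(sample))
        assert theta == pytest.approx(np.var(sample) / np.mean(sample))

    def test_degenerate_sample(self):
        k, theta = LS.fit_gamma_moments(np.full(10, 3.0))
        assert math.isnan(k)


class TestKs:
    def test_identical_samples(self):
        d, p = LS.ks_distance_test([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = LS.ks_distance_test(list(range(30)), list(range(100, 130)))
        assert d == 1.0

    def test_statistic_matches_ecdf_supremum(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1, 20)
        d, _ = LS.ks_distance_test(a, b)
        grid = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert d == pytest.approx(np.max(np.abs(fa - fb)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            LS.ks_distance_test([], [1.0])


class TestLengthCorrectedChisq:
    def test_exact_expectation_gives_zero(self):
        stat, p, df = LS.length_corrected_chisq(
            ["a"] * 5 + ["b"] * 5, [100, 100], ["a", "b"])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_hand_computed_statistic(self):
        # observed (8, 2) vs length-expected (5, 5): 1.8 + 1.8 = 3.6
        stat, _, _ = LS.length_corrected_chisq(
            ["a"] * 8 + ["b"] * 2, [100, 100], ["a", "b"])
        assert stat == pytest.approx(3.6)

    def test_class_order_invariance(self):
        flags = ["a"] * 8 + ["b"] * 2
        s1, p1, _ = LS.length_corrected_chisq(flags, [100, 300], ["a", "b"])
        s2, p2, _ = LS.length_corrected_chisq(flags, [300, 100], ["b", "a"])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)
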