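"""Cochran-Armitage trend test, allelic OR, windows and the locus scan."""
import numpy as np
import pytest

from cleftvar.association import (ScanConfig, allelic_or,
                                  bonferroni_thresholds, oriented_to_minor,
                                  scan, trend_test, window_select)
from cleftvar.simulate import simulate_case_control
from cleftvar.types import GenotypeCounts


def _subject_vectors(counts):
    n0, n1, n2 = counts.case_counts
    m0, m1, m2 = counts.control_counts
    g = np.array([0] * n0 + [1] * n1 + [2] * n2
                 + [0] * m0 + [1] * m1 + [2] * m2)
    y = np.array([1] * counts.n_cases + [0] * counts.n_controls)
    return g, y


def _oracle_chi2(counts):
    """Independent route: trend chi-square equals N times the squared
    Pearson correlation between genotype score and case status."""
    g, y = _subject_vectors(counts)
    if np.std(g) == 0:
        return 0.0
    r = np.corrcoef(g, y)[0, 1]
    return len(g) * r * r


class TestTrendTest:
    def test_identical_distributions_give_null(self):
        chi2, p = trend_test(GenotypeCounts((10, 20, 10), (10, 20, 10)))
        assert chi2 == 0.0 and p == 1.0

    def test_monomorphic_table_gives_p_one(self):
        chi2, p = trend_test(GenotypeCounts((30, 0, 0), (30, 0, 0)))
        assert (chi2, p) == (0.0, 1.0)

    def test_against_correlation_oracle_on_random_tables(self):
        """Exact agreement with an independently coded subject-level
        statistic on 1000 random 2x3 tables."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            pc = rng.uniform(0.05, 0.95)
            qc = rng.uniform(0.05, 0.95)
            case = tuple(int(x) for x in rng.multinomial(
                int(rng.integers(10, 120)),
                [(1 - pc) ** 2, 2 * pc * (1 - pc), pc ** 2]))
            ctrl = tuple(int(x) for x in rng.multinomial(
                int(rng.integers(10, 120)),
                [(1 - qc) ** 2, 2 * qc * (1 - qc), qc ** 2]))
            counts = GenotypeCounts(case, ctrl)
            chi2, _ = trend_test(counts)
            assert chi2 == pytest.approx(_oracle_chi2(counts), abs=1e-9)
            checked += 1

    def test_two_class_case_reduces_to_pearson_2x2(self):
        # third genotype class empty: trend test == Pearson chi-square
        from scipy.stats import chi2_contingency
        counts = GenotypeCounts((12, 18, 0), (22, 8, 0))
        chi2, p = trend_test(counts)
        expected = chi2_contingency(
            [[12, 18], [22, 8]], correction=False)
        assert chi2 == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_weight_affine_invariance(self):
        counts = GenotypeCounts((5, 10, 5), (10, 8, 2))
        assert trend_test(counts, (0, 1, 2)) == \
            pytest.approx(trend_test(counts, (0, 0.5, 1)))
        assert trend_test(counts, (0, 1, 2)) == \
            pytest.approx(trend_test(counts, (3, 5, 7)))

    def test_orientation_invariance(self):
        counts = GenotypeCounts((5, 10, 5), (10, 8, 2))
        assert trend_test(counts) == pytest.approx(
            trend_test(counts.flipped()))

    def test_mid_p_permutation_agreement_small_cohort(self):
        """The chi-square p matches a 1e5-replicate label-permutation
        mid-p null on a 60-subject cohort (standard comparison of a
        continuous approximation to a discrete null)."""
        counts = GenotypeCounts((8, 16, 6), (16, 10, 4))
        chi2, p_asym = trend_test(counts)
        g, y = _subject_vectors(counts)
        rng = np.random.default_rng(7)
        B = 100_000
        perms = np.array([rng.permutation(y) for _ in range(B)])
        w = g.astype(float)
        R = y.sum()
        S = len(y) - R
        T0 = abs(np.sum(w * (y * S - (1 - y) * R)))
        Tb = np.abs(perms @ (w * S) - (1 - perms) @ (w * R))
        p_mid = (np.sum(Tb > T0 + 1e-9)
                 + 0.5 * np.sum(np.abs(Tb - T0) <= 1e-9)) / B
        mc_se = np.sqrt(p_mid * (1 - p_mid) / B)
        assert 0.01 <= p_mid <= 0.5  # the regime under comparison
        assert abs(p_asym - p_mid) < 0.015 + 3 * mc_se

    def test_negative_counts_and_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCounts((-1, 2, 3), (1, 2, 3))
        with pytest.raises(ValueError):
            GenotypeCounts((1, 2, 3), (0, 0, 0))


class TestAllelicOr:
    def test_identical_frequencies_give_unity(self):
        assert allelic_or(GenotypeCounts((25, 50, 25), (25, 50, 25))) == 1.0

    def test_haldane_correction_keeps_degenerate_tables_finite(self):
        counts = GenotypeCounts((0, 0, 10), (10, 0, 0))
        or_corrected = allelic_or(counts, haldane=True)
        assert np.isfinite(or_corrected) and or_corrected > 1
        assert allelic_or(counts, haldane=False) == float("inf")

    def test_known_2x2_value(self):
        # case alleles 30 alt / 70 ref; control 10 alt / 90 ref
        counts = GenotypeCounts((40, 20, 5), (80, 10, 0))
        a, b, c, d = counts.allele_counts()
        assert allelic_or(counts) == pytest.approx((a * d) / (b * c))

    def test_planted_or_recovery_median(self):
        """Simulating the strongest reported locus signal (control MAF
        0.18, allelic OR 1.62, 269 cases / 569 controls): the median
        estimate over 1000 seeded replicates recovers the planted value."""
        rng = np.random.default_rng(2024)
        estimates = [
            allelic_or(simulate_case_control(0.18, 1.62, 269, 569, rng))
            for _ in range(1000)]
        assert 1.45 <= float(np.median(estimates)) <= 1.80


class TestWindowSelect:
    SNVS = [("a", "chr1", 900_000), ("b", "chr1", 1_000_000),
            ("c", "chr1", 1_500_000), ("d", "chr1", 2_100_000),
            ("e", "chr2", 1_500_000)]

    def test_closed_boundaries_and_chromosome_match(self):
        gene = ("chr1", 1_000_000, 2_000_000)
        assert window_select(gene, self.SNVS, 100_000) == \
            ["a", "b", "c", "d"]  # a sits exactly at start - flank
        # shrinking the flank by 1 bp drops both edge SNVs (a and d)
        assert window_select(gene, self.SNVS, 99_999) == ["b", "c"]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="start.*end"):
            window_select(("chr1", 10, 5), self.SNVS, 0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        snvs = [(f"s{i}", "chr3", int(p))
                for i, p in enumerate(rng.integers(1, 10_000, 300))]
        gene = ("chr3", 4_000, 6_000)
        flank = 1_000
        expected = sorted(
            (pos, sid) for sid, _c, pos in snvs
            if 4_000 - flank <= pos <= 6_000 + flank)
        assert window_select(gene, snvs, flank) == [s for _, s in expected]


class TestScan:
    @staticmethod
    def _cohort(seed, n_snvs=12, null=True):
        rng = np.random.default_rng(seed)
        genes = {"GENE_A": ("chr1", 10_000, 60_000),
                 "GENE_B": ("chr2", 10_000, 60_000)}
        snvs, counts = [], {}
        for i in range(n_snvs):
            chrom = "chr1" if i < n_snvs // 2 else "chr2"
            sid = f"rs{i:04d}"
            snvs.append((sid, chrom, 10_000 + 4_000 * (i % (n_snvs // 2))))
            orr = 1.0 if null or i != 0 else 2.0
            counts[sid] = simulate_case_control(
                float(rng.uniform(0.1, 0.4)), orr, 269, 569, rng)
        return genes, snvs, counts

    def test_thresholds_reproduce_published_values(self):
        g_thr, s_thr = bonferroni_thresholds(0.05, 30, 2151)
        assert g_thr == pytest.approx(1.67e-3, rel=5e-3)
        assert s_thr == pytest.approx(2.32e-5, rel=5e-3)

    def test_scan_reports_each_snv_once_per_window(self):
        genes, snvs, counts = self._cohort(1)
        result = scan(genes, snvs, counts)
        assert result.n_genes == 2
        assert result.n_snvs == len(result.results)
        assert set(result.best_per_gene) <= set(genes)

    def test_maf_filter_is_enforced_sample_wide(self):
        genes, snvs, counts = self._cohort(2)
        # plant one SNV below the MAF floor
        counts["rs0000"] = GenotypeCounts((260, 9, 0), (560, 9, 0))
        result = scan(genes, snvs, counts, ScanConfig(maf_min=0.05))
        assert all(r.maf >= 0.05 for r in result.results)
        assert "rs0000" not in {r.snv_id for r in result.results}

    def test_best_per_gene_is_minimal_p(self):
        genes, snvs, counts = self._cohort(3)
        result = scan(genes, snvs, counts)
        for gene, best in result.best_per_gene.items():
            gene_ps = [r.p_trend for r in result.results if r.gene == gene]
            assert best.p_trend == min(gene_ps)

    def test_monomorphic_snv_is_never_significant(self):
        genes = {"G": ("chr1", 1_000, 2_000)}
        snvs = [("s1", "chr1", 1_500)]
        counts = {"s1": GenotypeCounts((269, 0, 0), (569, 0, 0))}
        result = scan(genes, snvs, counts, ScanConfig(maf_min=0.0))
        [r] = result.results
        assert r.p_trend == 1.0
        assert not r.significant_gene_level

    def test_orientation_to_minor_allele(self):
        counts = GenotypeCounts((5, 60, 204), (10, 120, 439))  # alt common
        oriented = oriented_to_minor(counts)
        assert oriented.pooled_alt_fraction() <= 0.5
        assert trend_test(counts) == pytest.approx(trend_test(oriented))
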