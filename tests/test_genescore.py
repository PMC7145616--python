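import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tseakit import (ContractError, GeneAnnotation, GeneScoreConfig,
                     GenotypeRef, LDMatrix, SimConfig, SummaryStats,
                     gene_pvalue_sum, ld_matrix, map_snps_to_genes,
                     score_study, weighted_chi2_sf)
from tseakit.simulate import simulate_study


def _sumstats(snp_rows):
    df = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "pvalue"])
    for col in ("effect_allele", "other_allele", "maf", "effect", "se", "n"):
        df[col] = np.nan
    return SummaryStats("s", df)


class TestSnpToGeneMapping:
    GENE = GeneAnnotation("G1", "G1", "1", 100_000, 101_000)

    @pytest.mark.parametrize("pos,included", [
        (50_000, True),      # exactly start - window
        (49_999, False),     # one bp outside
        (151_000, True),     # exactly end + window
        (151_001, False),
        (100_500, True),     # inside the body
    ])
    def test_window_boundaries_inclusive(self, pos, included):
        ss = _sumstats([("rs1", "1", pos, 0.5)])
        mapping = map_snps_to_genes(ss, [self.GENE], window=50_000)
        assert ("G1" in mapping) is included

    def test_snp_in_two_overlapping_windows(self):
        g2 = GeneAnnotation("G2", "G2", "1", 120_000, 130_000)
        ss = _sumstats([("rs1", "1", 110_000, 0.5)])
        mapping = map_snps_to_genes(ss, [self.GENE, g2], window=50_000)
        assert mapping["G1"] == ["rs1"] and mapping["G2"] == ["rs1"]

    def test_non_autosomal_genes_skipped(self):
        gx = GeneAnnotation("GX", "GX", "X", 100_000, 101_000)
        ss = _sumstats([("rs1", "X", 100_500, 0.5)])
        assert map_snps_to_genes(ss, [gx]) == {}


class TestLDMatrix:
    def _geno(self, dosages):
        dosages = np.asarray(dosages, dtype=float)
        return GenotypeRef(samples=[f"s{i}" for i in range(dosages.shape[1])],
                           dosages=dosages,
                           snp_ids=[f"rs{i}" for i in range(dosages.shape[0])])

    def test_single_snp_unit_matrix(self):
        geno = self._geno([[0, 1, 2, 1]])
        ld = ld_matrix(geno, ["rs0"])
        np.testing.assert_allclose(ld.corr, [[1.0]])

    def test_identical_dosages_perfect_ld(self):
        geno = self._geno([[0, 1, 2, 1], [0, 1, 2, 1]])
        ld = ld_matrix(geno, ["rs0", "rs1"])
        assert ld.corr[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_pairwise_correlation(self):
        rng = np.random.default_rng(1)
        dose = rng.integers(0, 3, size=(5, 40)).astype(float)
        geno = self._geno(dose)
        ld = ld_matrix(geno, [f"rs{i}" for i in range(5)])
        for i in range(5):
            for j in range(5):
                expected = stats.pearsonr(dose[i], dose[j])[0]
                assert ld.corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_snp_dropped_with_warning(self):
        geno = self._geno([[1, 1, 1, 1], [0, 1, 2, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            ld = ld_matrix(geno, ["rs0", "rs1"])
        assert ld.snp_ids == ["rs1"]

    def test_eigenvalues_clipped_nonnegative(self):
        corr = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        lam = LDMatrix(["a", "b", "c"], corr).eigenvalues()
        assert (lam >= 0).all()


class TestGenePvalue:
    def test_single_snp_identity(self):
        ld = LDMatrix(["a"], np.array([[1.0]]))
        assert gene_pvalue_sum([0.01], ld) == pytest.approx(0.01, abs=1e-8)

    def test_independent_snps_chi2_k(self):
        p = [0.1, 0.02, 0.5, 0.3]
        ld = LDMatrix(list("abcd"), np.eye(4))
        t = stats.chi2.isf(p, 1).sum()
        assert gene_pvalue_sum(p, ld) == pytest.approx(stats.chi2.sf(t, 4), abs=1e-8)

    def test_perfect_ld_single_eigenvalue(self):
        k = 3
        p = [0.05, 0.04, 0.06]
        ld = LDMatrix(list("abc"), np.ones((k, k)))
        t = stats.chi2.isf(p, 1).sum()
        assert gene_pvalue_sum(p, ld) == pytest.approx(
            stats.chi2.sf(t / k, 1), abs=1e-8)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.standard_normal((4, 10))
        corr = np.corrcoef(a)
        ld = LDMatrix(list("abcd"), corr)
        p = [0.2, 0.01, 0.4, 0.05]
        gp = gene_pvalue_sum(p, ld)
        t = stats.chi2.isf(p, 1).sum()
        lam = ld.eigenvalues()
        draws = rng.chisquare(1, size=(1_000_000, lam.size)) @ lam
        mc = (draws > t).mean()
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert gp == pytest.approx(mc, abs=3 * se)

    def test_dimension_mismatch(self):
        with pytest.raises(ContractError):
            gene_pvalue_sum([0.1, 0.2], LDMatrix(["a"], np.array([[1.0]])))

    def test_monotone_in_snp_pvalues(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((3, 30))
        ld = LDMatrix(list("abc"), np.corrcoef(a))
        base = [0.3, 0.2, 0.4]
        prev = gene_pvalue_sum(base, ld)
        for p0 in (0.1, 0.01, 1e-4):
            cur = gene_pvalue_sum([p0, 0.2, 0.4], ld)
            assert cur <= prev + 1e-12
            prev = cur

    def test_tail_limits(self):
        assert weighted_chi2_sf(0.0, [1.2, 0.8]) == 1.0
        assert weighted_chi2_sf(1e4, [1.2, 0.8]) < 1e-10

    def test_null_gene_pvalues_uniform(self):
        """Under the global null with simulated LD, gene P-values are uniform
        (KS below the 1% critical value at 2000 genes)."""
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(2000):
            k = int(rng.integers(2, 6))
            dose = rng.integers(0, 3, size=(k, 60)).astype(float)
            dose += rng.normal(0, 0.01, dose.shape)  # break exact ties
            corr = np.corrcoef(dose)
            lam_full = np.clip(np.linalg.eigvalsh(corr), 0, None)
            root = np.linalg.cholesky(corr + 1e-9 * np.eye(k))
            z = root @ rng.standard_normal(k)
            p = 2 * stats.norm.sf(np.abs(z))
            pvals.append(gene_pvalue_sum(p, LDMatrix([str(i) for i in range(k)], corr)))
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 1.63 / np.sqrt(2000)


class TestScoreStudy:
    def test_all_genes_scored_on_synthetic_genome(self):
        cfg = SimConfig(seed=3, n_genes=50, n_tissues=2, n_causal_genes=2,
                        n_snps_per_gene=3, n_ref_samples=200)
        ss, genes, geno, _, _ = simulate_study(cfg)
        table = score_study(ss, genes, geno, GeneScoreConfig(min_genes=50))
        assert table.n_success == 50
        assert table.qualified

    def test_uncovered_gene_fails_and_gates_qualification(self):
        cfg = SimConfig(seed=3, n_genes=50, n_tissues=2, n_causal_genes=2,
                        n_snps_per_gene=3, n_ref_samples=200)
        ss, genes, geno, _, _ = simulate_study(cfg)
        # remove every reference SNP of the first gene
        geno2 = GenotypeRef(samples=geno.samples, dosages=geno.dosages[3:],
                            snp_ids=geno.snp_ids[3:])
        table = score_study(ss, genes, geno2, GeneScoreConfig(min_genes=50))
        assert table.table.loc["G00", "status"] == "failed"
        assert table.n_success == 49
        assert not table.qualified  # 49 < 50: below the study floor
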