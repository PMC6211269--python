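import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from epigain.genotype import MISSING, GenotypeMatrix, Phenotype
from epigain.qc import (
    QCError,
    QCParams,
    heterozygosity_outliers,
    hwe_test,
    impute_mode,
    ld_prune,
    ld_r2,
    maf_filter,
    run_qc,
    sample_missingness,
    single_snp_association,
    snp_missingness_filter,
)


def _gm(geno, **kw):
    geno = np.asarray(geno, dtype=np.int8)
    return GenotypeMatrix(geno, [f"rs{j}" for j in range(geno.shape[1])],
                          [f"s{i}" for i in range(geno.shape[0])], **kw)


class TestPerSampleStats:
    def test_sample_missingness_counts_missing_fraction(self):
        g = _gm([[0, 1, 2, 0], [MISSING, 1, 2, 0], [MISSING] * 4])
        assert sample_missingness(g).tolist() == [0.0, 0.25, 1.0]

    def test_het_outlier_flags_only_the_deviant_sample(self):
        rng = np.random.default_rng(5)
        # 50 samples with ~1/3 heterozygous SNPs, one sample 90% heterozygous
        geno = rng.choice([0, 1, 2], size=(51, 100), p=[1 / 3, 1 / 3, 1 / 3])
        geno[50] = rng.choice([0, 1], size=100, p=[0.1, 0.9])
        g = _gm(geno)
        # independent recomputation of the mean + 3 SD rule
        h = (geno == 1).mean(axis=1)
        expected = np.abs(h - h.mean()) > 3 * h.std(ddof=1)
        assert expected[50] and expected.sum() == 1
        assert heterozygosity_outliers(g, 3.0).tolist() == expected.tolist()

    def test_identical_rows_have_no_outliers(self):
        g = _gm(np.tile([0, 1, 2, 1], (5, 1)))
        assert not heterozygosity_outliers(g).any()


class TestPerSnpFilters:
    def test_maf_filter_keeps_polymorphic_removes_monomorphic(self):
        col_keep = [0, 0, 1, 1, 2]      # allele freq 0.4
        col_mono = [2, 2, 2, 2, 2]      # MAF 0
        g = _gm(np.column_stack([col_keep, col_mono]))
        assert maf_filter(g, QCParams()).tolist() == [0]

    def test_missingness_filter_threshold(self):
        col_ok = [0] * 20
        col_bad = [0] * 18 + [MISSING, MISSING]  # 10% missing > 5%
        g = _gm(np.column_stack([col_ok, col_bad]))
        assert snp_missingness_filter(g, QCParams()).tolist() == [0]

    def test_hwe_exact_proportions_and_total_het_depletion(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)
        # (50,0,50): expected (25,50,25) -> chi2 = 25 + 50 + 25 = 100
        stat, p = oracles.hwe_chi2(50, 0, 50)
        assert stat == pytest.approx(100.0)
        assert hwe_test((50, 0, 50)) == pytest.approx(p) and p < 1e-4
        assert hwe_test((100, 0, 0)) == 1.0  # monomorphic convention

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_hwe_matches_first_principles_on_small_tables(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        _, p = oracles.hwe_chi2(n0, n1, n2)
        assert hwe_test((n0, n1, n2)) == pytest.approx(p, abs=1e-12)


class TestLD:
    def test_r2_bounds_and_zero_covariance(self):
        x = np.array([0, 0, 1, 1], dtype=np.int8)
        y = np.array([0, 1, 0, 1], dtype=np.int8)
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, y) == pytest.approx(0.0)

    def test_r2_matches_brute_force_formula(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 3, 50).astype(np.int8)
        y = np.where(rng.random(50) < 0.7, x, rng.integers(0, 3, 50)).astype(np.int8)
        assert ld_r2(x, y) == pytest.approx(oracles.pearson_r2(x, y), abs=1e-12)

    def test_prune_keeps_first_of_identical_block(self):
        col = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        g = _gm(np.column_stack([col, col, col]))
        assert ld_prune(g, QCParams()).tolist() == [0]

    def test_prune_planted_block_and_no_residual_ld(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(100, 100)).astype(np.int8)
        geno[:, 40:45] = geno[:, [40]]  # 5-SNP perfect-LD block
        g = _gm(geno)
        params = QCParams()
        kept = ld_prune(g, params)
        # brute-force replay of the greedy keep-first rule
        expect = []
        for j in range(100):
            if all(oracles.pearson_r2(geno[:, i], geno[:, j]) <= params.ld_r2_max
                   for i in expect[-params.ld_window:]):
                expect.append(j)
        assert kept.tolist() == expect
        assert kept.size == 96
        for a_pos, a in enumerate(kept):
            for b in kept[max(0, a_pos - params.ld_window):a_pos]:
                assert ld_r2(geno[:, b], geno[:, a]) <= params.ld_r2_max


class TestImpute:
    def test_mode_fill_and_tie_toward_smaller_code(self):
        g = _gm(np.column_stack([
            [0, 1, 1, MISSING, 0],
            [2, 2, MISSING, MISSING, 2],
            [0, 0, 2, 2, MISSING],  # tie 0 vs 2 -> 0
        ]))
        out = impute_mode(g)
        assert out.genotypes[:, 0].tolist() == [0, 1, 1, 0, 0]
        assert out.genotypes[:, 1].tolist() == [2, 2, 2, 2, 2]
        assert out.genotypes[4, 2] == 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_impute_never_changes_observed_genotypes(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        mask = rng.random(geno.shape) < 0.3
        mask[0] = False  # keep every SNP observed at least once
        masked = np.where(mask, MISSING, geno).astype(np.int8)
        out = impute_mode(_gm(masked))
        assert np.array_equal(out.genotypes[~mask], masked[~mask])
        assert not (out.genotypes == MISSING).any()


class TestRunQC:
    @staticmethod
    def _clean_dataset(n=60, p=40, seed=1):
        rng = np.random.default_rng(seed)
        maf = rng.uniform(0.2, 0.5, p)
        geno = (rng.random((n, p)) < maf).astype(np.int8) + \
               (rng.random((n, p)) < maf).astype(np.int8)
        phen = Phenotype(rng.integers(0, 2, n))
        return _gm(geno), phen

    def test_idempotence_on_clean_input(self):
        g, phen = self._clean_dataset()
        g1, p1, rep1 = run_qc(g, phen)
        g2, p2, rep2 = run_qc(g1, p1)
        assert np.array_equal(g1.genotypes, g2.genotypes)
        assert g1.snp_ids == g2.snp_ids
        assert rep2.n_snps_in == rep2.n_snps_out

    def test_report_accounts_for_every_removal(self):
        # many SNPs so one missing call stays under the 1% per-sample limit
        g, phen = self._clean_dataset(p=200, seed=2)
        geno = g.genotypes.copy()
        geno[:, 0] = 2                      # monomorphic -> MAF removal
        geno[:4, 1] = MISSING               # 6.7% missing at this SNP > 5%
        geno[:, 2] = geno[:, 3]             # perfect LD -> later column pruned
        g = _gm(geno)
        _, _, rep = run_qc(g, phen)
        rep.check_consistent()
        assert rep.snps_removed_maf >= 1
        assert rep.snps_removed_missing >= 1
        assert rep.snps_removed_ld >= 1

    def test_single_class_after_sample_filters_raises(self):
        g, phen = self._clean_dataset(n=10)
        geno = g.genotypes.copy()
        labels = phen.labels.copy()
        labels[:] = 0
        labels[3] = 1
        geno[3, :] = MISSING  # the only case is removed by sample missingness
        with pytest.raises(QCError, match="single-class"):
            run_qc(_gm(geno), Phenotype(labels))

    def test_monotone_in_maf_threshold(self):
        g, phen = self._clean_dataset(seed=4)
        strict = set(maf_filter(g, QCParams(maf_min=0.3)).tolist())
        loose = set(maf_filter(g, QCParams(maf_min=0.1)).tolist())
        assert strict <= loose


class TestAssociation:
    def test_identical_distribution_gives_p_near_one(self):
        col = np.array([0, 1, 2] * 10, dtype=np.int8)
        g = _gm(col[:, None])
        phen = Phenotype(np.array([0, 0, 0, 1, 1, 1] * 5))
        assert single_snp_association(g, phen)[0] > 0.5

    def test_perfect_separation_is_significant(self):
        col = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        phen = Phenotype(np.array([1] * 50 + [0] * 50))
        assert single_snp_association(_gm(col[:, None]), phen)[0] < 1e-4

    def test_matches_chi_square_oracle_on_printed_table(self):
        # genotype x status counts [[30,10],[20,20],[10,30]]
        col = np.array([0] * 40 + [1] * 40 + [2] * 40, dtype=np.int8)
        y = np.array([0] * 30 + [1] * 10 + [0] * 20 + [1] * 20 + [0] * 10 + [1] * 30)
        from scipy.stats import chi2 as chi2_dist

        table = np.array([[30, 10], [20, 20], [10, 30]], dtype=float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - exp) ** 2 / exp).sum()
        p_oracle = float(chi2_dist.sf(stat, df=2))
        got = single_snp_association(_gm(col[:, None]), Phenotype(y))[0]
        assert got == pytest.approx(p_oracle, abs=1e-12)

    def test_monomorphic_snp_gets_p_one(self):
        col = np.zeros(20, dtype=np.int8)
        phen = Phenotype(np.array([0, 1] * 10))
        assert single_snp_association(_gm(col[:, None]), phen)[0] == 1.0
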