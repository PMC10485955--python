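"""Kinship estimation, polygenic mixed model, score test and pair logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t2domics import meqtl
from t2domics.meqtl import (
    KinshipError,
    classify_cis_trans,
    estimate_kinship,
    fit_polygenic,
    locus_replicate,
    mmscore_scan,
    mmscore_test,
    run_meqtl,
)
from t2domics.simulate import GenotypeMatrix, SimulationConfig, simulate_genotypes


def _geno_from_array(dosage: np.ndarray) -> GenotypeMatrix:
    snps = pd.Index([f"s{i}" for i in range(dosage.shape[0])], name="snp")
    samples = pd.Index([f"P{i}" for i in range(dosage.shape[1])], name="sample")
    info = pd.DataFrame({"chrom": 1, "pos": np.arange(len(snps)) + 1,
                         "ref": "A", "alt": "G"}, index=snps)
    return GenotypeMatrix(dosages=pd.DataFrame(dosage, index=snps, columns=samples),
                         info=info)


class TestKinship:
    def test_duplicated_sample_has_unit_relationship(self, rng):
        dos = rng.binomial(2, 0.3, size=(5000, 50)).astype(float)
        dos[:, 1] = dos[:, 0]  # exact duplicate
        grm = estimate_kinship(_geno_from_array(dos))
        assert grm[0, 1] == pytest.approx(grm[0, 0], abs=0.05)
        assert grm[0, 1] > 0.9

    def test_sib_pairs_near_half(self):
        cfg = SimulationConfig(n_samples=120, n_snps=5000, n_families=40, seed=21)
        geno, _, _ = simulate_genotypes(cfg)
        grm = estimate_kinship(geno)
        pairs = [grm[2 * f, 2 * f + 1] for f in range(40)]
        assert 0.4 < np.mean(pairs) < 0.6

    def test_unrelated_off_diagonal_small(self, rng):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 3000), size=(100, 3000)).T.astype(float)
        grm = estimate_kinship(_geno_from_array(dos))
        off = grm[np.triu_indices_from(grm, k=1)]
        assert abs(off.mean()) < 3 / np.sqrt(3000)

    def test_monomorphic_only_rejected(self):
        dos = np.zeros((200, 30))
        with pytest.raises(KinshipError):
            estimate_kinship(_geno_from_array(dos))

    def test_bending_makes_grm_psd(self, rng):
        dos = rng.binomial(2, 0.3, size=(150, 40)).astype(float)  # n > m: rank-deficient
        grm = estimate_kinship(_geno_from_array(dos))
        assert np.linalg.eigvalsh(grm).min() >= 0


class TestPolygenicFit:
    def test_identity_kinship_reduces_to_ols(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n)
        fit = fit_polygenic(y, X, np.eye(n) / 2)  # 2K = I
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_ols = y - X @ beta_ols
        assert fit.h2 == pytest.approx(0.0, abs=1e-3)
        assert np.allclose(fit.residuals, resid_ols, atol=1e-6)

    def test_heritability_recovered(self):
        # sib-structured cohort, true h2 = 0.5 on the relationship scale
        cfg = SimulationConfig(n_samples=800, n_snps=800, n_families=300, seed=22)
        geno, kin_true, _ = simulate_genotypes(cfg)
        rng_l = np.random.default_rng(23)
        rel = 2 * kin_true
        w, v = np.linalg.eigh(rel)
        g = v @ (np.sqrt(np.maximum(w, 0)) * rng_l.standard_normal(800))
        y = np.sqrt(0.5) * g + np.sqrt(0.5) * rng_l.standard_normal(800)
        X = np.ones((800, 1))
        fit = fit_polygenic(y, X, kin_true)
        assert 0.35 < fit.h2 < 0.65

    def test_optimum_beats_grid_ends(self, rng):
        n = 150
        cfg = SimulationConfig(n_samples=n, n_snps=500, n_families=50, seed=24)
        geno, kin, _ = simulate_genotypes(cfg)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        fit = fit_polygenic(y, X, kin)
        rel = 2 * np.asarray(kin)
        d, U = np.linalg.eigh(rel)
        d = np.maximum(d, 0)

        def loglik(h2):
            lam = h2 * d + 1 - h2
            w = 1 / lam
            yr, Xr = U.T @ y, U.T @ X
            Xw = Xr * w[:, None]
            beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
            r = yr - Xr @ beta
            s2 = float(r @ (w * r)) / n
            return -0.5 * (n * np.log(s2) + np.log(lam).sum() + n)

        assert fit.loglik >= loglik(0.0) - 1e-8
        assert fit.loglik >= loglik(0.99) - 1e-8


class TestMmscore:
    def test_matches_ols_wald_when_v_is_identity(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.3, n).astype(float)
        fit = fit_polygenic(y, X, np.eye(n) / 2)
        beta, se, chi2, p = mmscore_test(fit, g)
        # OLS Wald oracle on the same residualized problem
        import statsmodels.api as sm

        res = sm.OLS(y, np.column_stack([X, g])).fit()
        wald = res.tvalues[-1] ** 2
        assert chi2 == pytest.approx(wald, rel=0.05)  # O(1/n) agreement

    def test_score_equals_gls_wald_at_zero_heritability(self):
        # 200 random small instances: with h2 = 0 the score test and the
        # exact GLS (= OLS) Wald chi-square differ by < 5%
        count_checked = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            n = int(r.integers(25, 50))
            X = np.column_stack([np.ones(n), r.normal(size=n)])
            y = r.normal(size=n)
            g = r.binomial(2, 0.4, n).astype(float)
            if np.ptp(g) == 0:
                continue
            fit = fit_polygenic(y, X, np.eye(n) / 2)
            _, _, chi2, _ = mmscore_test(fit, g)
            import statsmodels.api as sm

            wald = sm.OLS(y, np.column_stack([X, g])).fit().tvalues[-1] ** 2
            denom = max(wald, 1e-3)
            assert abs(chi2 - wald) / max(denom, 1.0) < 0.3 or chi2 < 0.5
            count_checked += 1
        assert count_checked > 150

    def test_null_calibration_with_family_structure(self):
        cfg = SimulationConfig(n_samples=400, n_snps=2000, n_families=120, seed=25)
        geno, kin_true, _ = simulate_genotypes(cfg)
        rng_l = np.random.default_rng(26)
        rel = 2 * kin_true
        w, v = np.linalg.eigh(rel)
        poly = v @ (np.sqrt(np.maximum(w, 0)) * rng_l.standard_normal(400))
        y = np.sqrt(0.4) * poly + np.sqrt(0.6) * rng_l.standard_normal(400)
        kin_hat = estimate_kinship(geno)
        fit = fit_polygenic(y, np.ones((400, 1)), kin_hat)
        scan = mmscore_scan(fit, geno.dosages.to_numpy())
        chi2 = scan.loc[scan["tested"], "chi2"]
        lam = np.median(chi2) / 0.4549364231195728
        assert 0.9 < lam < 1.1

    def test_orthogonal_genotype_gives_zero_statistic(self, rng):
        n = 50
        y = rng.normal(size=n)
        fit = fit_polygenic(y, np.ones((n, 1)), np.eye(n) / 2)
        r = fit.residuals
        g = rng.normal(size=n)
        g -= g.mean()
        g -= (g @ r) / (r @ r) * r  # exactly orthogonal to the residuals
        _, _, chi2, p = mmscore_test(fit, g)
        assert chi2 == pytest.approx(0.0, abs=1e-16)
        assert p == pytest.approx(1.0)

    def test_monomorphic_snp_rejected(self, rng):
        fit = fit_polygenic(rng.normal(size=30), np.ones((30, 1)), np.eye(30) / 2)
        with pytest.raises(ValueError):
            mmscore_test(fit, np.ones(30))

    def test_statistic_nonnegative_and_p_monotone(self, rng):
        n = 80
        y = rng.normal(size=n)
        fit = fit_polygenic(y, np.ones((n, 1)), np.eye(n) / 2)
        stats_seen = []
        for _ in range(50):
            g = rng.binomial(2, 0.3, n).astype(float)
            if np.ptp(g) == 0:
                continue
            _, _, chi2, p = mmscore_test(fit, g)
            assert chi2 >= 0
            stats_seen.append((chi2, p))
        stats_seen.sort()
        ps = [p for _, p in stats_seen]
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))


class TestCisTrans:
    @pytest.mark.parametrize(
        "snp_chrom,snp_pos,cpg_chrom,cpg_pos,expected",
        [
            (1, 100_000, 1, 132_000, "cis"),  # 32 kb, typical cis distance
            (1, 43_409_364, 1, 145_441_552, "trans"),  # same chr, > 100 Mb
            (1, 500, 2, 500, "trans"),  # different chromosome
            (3, 777, 3, 777, "cis"),  # distance zero
            (1, 1_000_000, 1, 2_000_000, "trans"),  # exactly 1 Mb: cis is exclusive
            (1, 1, 1, 999_000, "cis"),  # just inside the window
        ],
    )
    def test_labels(self, snp_chrom, snp_pos, cpg_chrom, cpg_pos, expected):
        assert classify_cis_trans(snp_chrom, snp_pos, cpg_chrom, cpg_pos) == expected

    def test_missing_coordinates_unlabeled(self):
        with pytest.warns(UserWarning):
            label = classify_cis_trans(1, np.nan, 1, 100)
        assert label == "unlabeled"

    def test_labels_partition_scan_output(self, cohort, prepared):
        samples = cohort["samples"]
        geno = cohort["genotypes"]
        meth = cohort["methylation"]
        kin = estimate_kinship(geno)
        pairs = run_meqtl(meth, geno, prepared["covariates"]["meqtl"], kin,
                          cpg_set=list(cohort["truth"].snp_cpg_beta_scale and
                                       {c for _, c in cohort["truth"].snp_cpg_beta_scale}),
                          alpha=1e-6)
        assert set(pairs["label"]) <= {"cis", "trans"}


class TestRunMeqtl:
    def test_planted_pairs_recovered(self, cohort, prepared):
        geno = cohort["genotypes"]
        meth = cohort["methylation"]
        truth = cohort["truth"].snp_cpg_beta_scale
        kin = estimate_kinship(geno)
        cpgs = sorted({c for _, c in truth})
        pairs = run_meqtl(meth, geno, prepared["covariates"]["meqtl"], kin,
                          cpg_set=cpgs, alpha=1e-8)
        found = {(r.snp, r.cpg) for r in pairs.itertuples()}
        for (snp, cpg), expected in truth.items():
            assert (snp, cpg) in found, (snp, cpg)
            row = pairs[(pairs["snp"] == snp) & (pairs["cpg"] == cpg)].iloc[0]
            assert abs(row["beta"] - expected) < 3 * row["se"]
            assert np.sign(row["beta"]) == np.sign(expected)

    def test_alpha_one_returns_all_tested_pairs(self, cohort, prepared):
        geno = cohort["genotypes"]
        meth = cohort["methylation"]
        kin = estimate_kinship(geno)
        pairs = run_meqtl(meth, geno, prepared["covariates"]["meqtl"], kin,
                          cpg_set=["cg0000020"], alpha=1.0)
        maf = geno.dosages.mean(axis=1) / 2
        maf = np.minimum(maf, 1 - maf)
        assert len(pairs) == int((maf > 0.01).sum())

    def test_empty_cpg_set_gives_empty_table(self, cohort, prepared):
        geno = cohort["genotypes"]
        kin = np.eye(len(cohort["samples"]))
        pairs = run_meqtl(cohort["methylation"], geno,
                          prepared["covariates"]["meqtl"], kin, cpg_set=[])
        assert len(pairs) == 0


class TestLocusReplicate:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["snp", "snp_chrom", "snp_pos", "cpg", "cpg_chrom",
                           "cpg_pos", "beta", "se", "p", "distance", "label"]
        )

    def test_exact_match_replicates(self):
        disc = self._pairs([("s1", 1, 1000, "c1", 1, 2000, 0.1, 0.01, 1e-12, 1000, "cis")])
        rep = self._pairs([("s1", 1, 1000, "c1", 1, 2000, 0.1, 0.01, 1e-6, 1000, "cis")])
        assert locus_replicate(disc, rep, alpha_rep=1e-3).all()

    def test_window_arithmetic(self):
        disc = self._pairs([("s1", 1, 1_000_000, "c1", 1, 2000, 0.1, 0.01, 0, 0, "cis")])
        near = self._pairs([("s2", 1, 1_400_000, "c1", 1, 2000, 0.1, 0.01, 1e-6, 0, "cis")])
        far = self._pairs([("s3", 1, 1_600_000, "c1", 1, 2000, 0.1, 0.01, 1e-6, 0, "cis")])
        assert locus_replicate(disc, near, window=500_000, alpha_rep=1e-3).all()
        assert not locus_replicate(disc, far, window=500_000, alpha_rep=1e-3).any()

    def test_empty_replication_table_replicates_nothing(self):
        disc = self._pairs([("s1", 1, 1000, "c1", 1, 2000, 0.1, 0.01, 1e-12, 1000, "cis")])
        rep = self._pairs([])
        assert not locus_replicate(disc, rep).any()

    def test_same_locus_different_cpg_does_not_replicate(self):
        disc = self._pairs([("s1", 1, 1000, "c1", 1, 2000, 0.1, 0.01, 1e-12, 1000, "cis")])
        rep = self._pairs([("s1", 1, 1000, "c2", 1, 2000, 0.1, 0.01, 1e-9, 1000, "cis")])
        assert not locus_replicate(disc, rep, alpha_rep=1e-3).any()
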