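import numpy as np
import pytest

from kinflate import (
    FamilyDesign,
    PhenotypeModel,
    RelatednessMatrix,
    build_family_relatedness,
    calibrate_effect,
    empirical_lambda,
    fit_simple_regression,
    simulate_phenotypes,
    theoretical_slope_variance,
)
from kinflate.phenotype_association import covariance_factor, ols_batch, summarize_replicates


class TestPhenotypeModel:
    def test_heritability_derivation(self):
        m = PhenotypeModel(sigma2_g=0.9, sigma2_e=0.1)
        assert m.r2_h == pytest.approx(0.9)

    def test_unit_variance_constructor(self):
        m = PhenotypeModel.from_heritability(0.4)
        assert m.sigma2_g == pytest.approx(0.4)
        assert m.sigma2_e == pytest.approx(0.6)
        assert m.total_var == pytest.approx(1.0)

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeModel(sigma2_g=-0.1, sigma2_e=1.0)
        with pytest.raises(ValueError):
            PhenotypeModel(sigma2_g=0.0, sigma2_e=0.0)


class TestSimulatePhenotypes:
    def test_pure_noise_is_iid_standard_normal(self):
        G = RelatednessMatrix(np.eye(200))
        model = PhenotypeModel(b1=5.0, sigma2_g=0.0, sigma2_e=1.0)
        s = np.tile([0.0, 1, 2, 1], 50)
        Y = simulate_phenotypes(G, s, model, 500, seed=0)
        assert Y.shape == (500, 200)
        assert Y.mean() == pytest.approx(5.0, abs=0.02)
        assert Y.var() == pytest.approx(1.0, abs=0.02)

    def test_identity_relatedness_covariance_independent_of_split(self):
        G = RelatednessMatrix(np.eye(50))
        s = np.zeros(50)
        rng_draws = []
        for sg in (0.0, 0.5, 0.9):
            model = PhenotypeModel(sigma2_g=sg, sigma2_e=1.0 - sg)
            Y = simulate_phenotypes(G, s, model, 4000, seed=1)
            C = np.cov(Y.T)
            rng_draws.append(C)
            off = C[~np.eye(50, dtype=bool)]
            assert np.abs(off).max() < 0.2
            assert np.diag(C).mean() == pytest.approx(1.0, abs=0.05)

    def test_parent_child_phenotype_covariance(self, trio_design):
        # cov(y_i, y_j) = R2h * G_ij = 0.9 * 0.5 for a parent-child pair
        G = build_family_relatedness(trio_design)
        model = PhenotypeModel.from_heritability(0.9)
        Y = simulate_phenotypes(G, np.zeros(3), model, 10_000, seed=2)
        cov_fc = np.cov(Y[:, 0], Y[:, 2])[0, 1]
        cov_fm = np.cov(Y[:, 0], Y[:, 1])[0, 1]
        assert cov_fc == pytest.approx(0.45, abs=0.03)
        assert cov_fm == pytest.approx(0.0, abs=0.03)

    def test_eigenvalue_clipping_for_indefinite_matrix(self):
        vals = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, -0.7], [0.7, -0.7, 1.0]])
        G = RelatednessMatrix(vals, source="estimated")
        with pytest.warns(UserWarning, match="positive definite"):
            L = covariance_factor(G)
        # factor reproduces the PSD projection of the matrix
        assert np.linalg.eigvalsh(L @ L.T).min() >= -1e-10


class TestCalibrateEffect:
    def test_zero_explained_variance_gives_zero_effect(self):
        s = np.array([0.0, 1, 2, 1, 0, 2])
        assert calibrate_effect(s, 0.0) == 0.0

    def test_explained_variance_identity(self):
        s = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        b2 = calibrate_effect(s, 0.3, total_var=2.0)
        assert b2**2 * np.var(s, ddof=1) == pytest.approx(0.3 / 0.7 * 2.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            calibrate_effect(np.ones(5), 0.1)

    def test_mean_statistic_approximates_mu(self, sfs2_design):
        # with the calibrated effect, the average T over replicates tracks
        # mu = sqrt((n-1) R2s) (an approximation, checked to ~2%)
        G = build_family_relatedness(sfs2_design)
        rng = np.random.default_rng(3)
        geno = rng.binomial(2, 0.4, size=999).astype(float)
        r2_s = 0.02
        b2 = calibrate_effect(geno, r2_s)
        model = PhenotypeModel.from_heritability(0.9, b2=b2, r2_s=r2_s)
        Y = simulate_phenotypes(G, geno, model, 400, seed=4)
        _, _, t = ols_batch(Y, geno)
        mu = np.sqrt(998 * r2_s)
        assert np.nanmean(t) == pytest.approx(mu, rel=0.02)


class TestFitSimpleRegression:
    def test_exact_linear_relation(self):
        s = np.array([0.0, 1, 2, 1, 0, 2])
        out = fit_simple_regression(2.0 + 3.0 * s, s)
        assert out.beta2_hat == pytest.approx(3.0)
        assert out.s2_beta == pytest.approx(0.0, abs=1e-20)
        assert np.isnan(out.t_stat)  # undefined, flagged as NaN

    def test_matches_independent_ols_implementation(self):
        import statsmodels.api as sm

        s = np.array([0.0, 1, 2, 1, 0, 2])
        y = np.array([0.1, 1.2, 2.1, 0.9, -0.2, 2.2])
        out = fit_simple_regression(y, s)
        ref = sm.OLS(y, sm.add_constant(s)).fit()
        assert out.beta2_hat == pytest.approx(ref.params[1], abs=1e-12)
        assert out.s2_beta == pytest.approx(ref.bse[1] ** 2, abs=1e-12)
        assert out.t_stat == pytest.approx(ref.tvalues[1], abs=1e-10)

    def test_null_statistic_centred_at_zero(self):
        rng = np.random.default_rng(5)
        s = rng.integers(0, 3, 100).astype(float)
        Y = rng.standard_normal((2000, 100))
        _, _, t = ols_batch(Y, s)
        assert np.nanmean(t) == pytest.approx(0.0, abs=3 * np.nanstd(t) / np.sqrt(2000))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_simple_regression(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="monomorphic"):
            fit_simple_regression(np.zeros(5), np.ones(5))


class TestTheoreticalSlopeVariance:
    def test_identity_relatedness_reduces_to_standard_ols_variance(self):
        s = np.array([0.0, 1, 2, 1, 0, 2])
        G = RelatednessMatrix(np.eye(6))
        model = PhenotypeModel(sigma2_g=0.0, sigma2_e=2.0)
        sxx = ((s - s.mean()) ** 2).sum()
        assert theoretical_slope_variance(s, G, model) == pytest.approx(2.0 / sxx)

    @pytest.mark.parametrize("seed", range(3))
    def test_identity_with_lambda_rewrite(self, seed, sfs1_matrix):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 3, 129).astype(float)
        model = PhenotypeModel.from_heritability(0.9)
        v = theoretical_slope_variance(s, sfs1_matrix, model)
        lam = empirical_lambda(s, sfs1_matrix, model.r2_h)
        v_beta = model.sigma2_e / ((s - s.mean()) ** 2).sum()
        assert v == pytest.approx(lam / (1 - model.r2_h) * v_beta, abs=1e-9)

    def test_monte_carlo_slope_variance(self, trio_design):
        # simulated slope variance matches the exact formula within 3 SE
        d = FamilyDesign(40, 1, 1)
        G = build_family_relatedness(d)
        rng = np.random.default_rng(7)
        s = rng.binomial(2, 0.3, d.n).astype(float)
        model = PhenotypeModel.from_heritability(0.9)
        Y = simulate_phenotypes(G, s, model, 4000, seed=9)
        beta, _, _ = ols_batch(Y, s)
        v_mc = np.var(beta, ddof=1)
        v_th = theoretical_slope_variance(s, G, model)
        se = v_th * np.sqrt(2.0 / (4000 - 1))
        assert abs(v_mc - v_th) < 3 * se

    def test_unbiased_slope_under_relatedness(self, sfs1_matrix):
        rng = np.random.default_rng(9)
        s = rng.binomial(2, 0.4, 129).astype(float)
        b2 = 0.35
        model = PhenotypeModel.from_heritability(0.9, b2=b2)
        Y = simulate_phenotypes(sfs1_matrix, s, model, 3000, seed=10)
        beta, _, _ = ols_batch(Y, s)
        se = beta.std(ddof=1) / np.sqrt(beta.size)
        assert abs(beta.mean() - b2) < 3 * se


class TestSummarizeReplicates:
    def test_identity_relatedness_reference_values(self):
        # without relatedness the variance of T is ~1 and nu ~ 1
        n = 300
        G = RelatednessMatrix(np.eye(n))
        rng = np.random.default_rng(11)
        s = rng.binomial(2, 0.3, n).astype(float)
        model = PhenotypeModel.from_heritability(0.0)
        Y = simulate_phenotypes(G, s, model, 3000, seed=12)
        beta, s2b, t = ols_batch(Y, s)
        sxx = float(((s - s.mean()) ** 2).sum())
        summ = summarize_replicates(beta, s2b, t, sxx, model)
        assert summ.t_var == pytest.approx(1.0, abs=0.08)
        assert summ.nu == pytest.approx(1.0, abs=0.05)

    def test_replicate_variance_of_t_matches_per_snp_lambda(self, sfs3_matrix):
        # over-replicate variance of T is the empirical counterpart of the
        # per-SNP inflation factor
        rng = np.random.default_rng(13)
        s = rng.binomial(2, 0.4, 999).astype(float)
        model = PhenotypeModel.from_heritability(0.9)
        Y = simulate_phenotypes(sfs3_matrix, s, model, 1500, seed=14)
        beta, s2b, t = ols_batch(Y, s)
        lam = empirical_lambda(s, sfs3_matrix, 0.9)
        t_var = np.nanvar(t, ddof=1)
        se = lam * np.sqrt(2.0 / (1500 - 1))
        assert abs(t_var - lam) < 3 * se

    def test_requires_two_replicates(self):
        model = PhenotypeModel.from_heritability(0.5)
        with pytest.raises(ValueError):
            summarize_replicates(np.array([1.0]), np.array([1.0]), np.array([1.0]), 1.0, model)
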