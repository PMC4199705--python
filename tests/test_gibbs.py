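import numpy as np
import pytest
from scipy import stats

from invgp import (
    ChainConfig,
    ErrorPrior,
    ModelSpec,
    default_hyperparameters,
    predict_values,
    ridge_coefficients,
    run_chain,
    run_chain_transformed,
    summarize_fit,
)
from invgp.gibbs import (
    sample_coefficients,
    sample_error_variance,
    sample_hyper_scale,
    sample_prior_variances,
    sample_scaled_inv_chi2,
)
from invgp.spectral import decompose, forward_transform


def sc_inv_chi2_dist(df, scale):
    """Oracle distribution: ScInvChi2(df, scale) == InvGamma(df/2, df*scale/2)."""
    return stats.invgamma(df / 2.0, scale=df * scale / 2.0)


class TestCoefficientSampler:
    def test_closed_form_mean_and_variance(self, stub_rng_factory):
        # lam = s = d = sigma2_e = 1 -> mean 1/2, variance 1/2
        one = np.array([1.0])
        mean = sample_coefficients(one, one, one, 1.0, stub_rng_factory(z=0.0))
        np.testing.assert_allclose(mean, [0.5], atol=1e-12)
        shifted = sample_coefficients(one, one, one, 1.0, stub_rng_factory(z=1.0))
        np.testing.assert_allclose((shifted - mean) ** 2, [0.5], atol=1e-12)

    def test_large_prior_variance_recovers_ols(self, stub_rng_factory):
        d, s = np.array([3.0]), np.array([2.0])
        mean = sample_coefficients(d, s, np.array([1e12]), 1.0, stub_rng_factory(z=0.0))
        np.testing.assert_allclose(mean, d / s, rtol=1e-9)

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(101)
        d, s, lam, sig = np.array([2.0]), np.array([1.5]), np.array([0.8]), 0.6
        analytic_mean = lam * s * d / (lam * s**2 + sig)
        analytic_var = sig * lam / (sig + lam * s**2)
        draws = np.array(
            [sample_coefficients(d, s, lam, sig, rng)[0] for _ in range(100_000)]
        )
        se = np.sqrt(analytic_var[0] / draws.size)
        assert abs(draws.mean() - analytic_mean[0]) < 4 * se
        assert abs(draws.var() - analytic_var[0]) < 0.02 * analytic_var[0]

    def test_conditional_mean_is_spectral_ridge(self, stub_rng_factory):
        """E[b_i | .] equals the ridge estimator with gamma_i = sigma2_e/lam_i."""
        rng = np.random.default_rng(102)
        X = rng.normal(size=(12, 30))
        y = rng.normal(size=12)
        basis = decompose(X)
        d = forward_transform(basis, y)
        lam, sig = 0.7, 1.3
        mean = sample_coefficients(
            d, basis.s, np.full(basis.r, lam), sig, stub_rng_factory(z=0.0)
        )
        gamma = np.full(basis.r, sig / lam)
        np.testing.assert_allclose(mean, ridge_coefficients(basis, d, gamma), rtol=1e-10)

    def test_rejects_bad_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_coefficients(np.array([np.inf]), np.ones(1), np.ones(1), 1.0, rng)
        with pytest.raises(ValueError):
            sample_coefficients(np.ones(1), np.ones(1), np.ones(1), 0.0, rng)


class TestErrorVarianceSampler:
    def test_pure_prior_moments(self):
        """With no data terms the conditional is the ScInvChi2(3, 1) prior."""
        rng = np.random.default_rng(103)
        prior = ErrorPrior(df_e=3.0, scale_e=1.0)
        empty = np.array([])
        draws = np.array(
            [sample_error_variance(empty, empty, empty, prior, rng)
             for _ in range(50_000)]
        )
        # analytic mean df*scale/(df-2) = 3; compare medians (mean is heavy-tailed)
        oracle = sc_inv_chi2_dist(3.0, 1.0)
        assert abs(np.median(draws) - oracle.median()) < 0.02 * oracle.median()
        ks = stats.kstest(draws, oracle.cdf).statistic
        assert ks < 0.01

    def test_prior_dominance_limit(self):
        rng = np.random.default_rng(104)
        prior = ErrorPrior(df_e=1e7, scale_e=2.5)
        d = np.array([1.0, 2.0])
        s = np.array([1.0, 1.0])
        b = np.array([1.0, 2.0])  # zero residual
        draws = [sample_error_variance(d, s, b, prior, rng) for _ in range(200)]
        np.testing.assert_allclose(draws, 2.5, rtol=0.01)

    def test_conditional_matches_quadrature_posterior(self):
        """3-point toy problem: sampled conditional vs grid-integrated density."""
        rng = np.random.default_rng(105)
        d = np.array([1.0, -0.5, 2.0])
        s = np.array([2.0, 1.0, 0.5])
        b = np.array([0.4, -0.2, 1.0])
        prior = ErrorPrior(df_e=3.0, scale_e=0.8)
        draws = np.array(
            [sample_error_variance(d, s, b, prior, rng) for _ in range(100_000)]
        )
        # Independent quadrature oracle: unnormalized density on a grid.
        e2 = float(np.sum((d - s * b) ** 2))
        grid = np.linspace(1e-4, 60.0, 300_001)
        log_dens = (
            -0.5 * len(d) * np.log(grid)
            - e2 / (2 * grid)
            - (prior.df_e / 2 + 1) * np.log(grid)
            - prior.df_e * prior.scale_e / (2 * grid)
        )
        dens = np.exp(log_dens - log_dens.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        cdf_at = np.interp(np.sort(draws), grid, cdf)
        emp = np.arange(1, draws.size + 1) / draws.size
        assert np.max(np.abs(cdf_at - emp)) < 0.01


class TestPriorVarianceSampler:
    def test_birr_zero_coefficients_moment_check(self):
        rng = np.random.default_rng(106)
        spec = ModelSpec("BIRR", df_b=5.0)
        b = np.zeros(4)
        draws = np.array(
            [sample_prior_variances(b, spec, np.ones(4), 2.0, rng)[0]
             for _ in range(50_000)]
        )
        # conditional is ScInvChi2(df_b + r, df_b*Sc/(df_b + r))
        df, scale = 5.0 + 4, 5.0 * 2.0 / (5.0 + 4)
        oracle = sc_inv_chi2_dist(df, scale)
        assert abs(draws.mean() - oracle.mean()) < 0.02 * oracle.mean()
        assert stats.kstest(draws, oracle.cdf).statistic < 0.01

    def test_bai_with_one_coefficient_matches_birr(self):
        b = np.array([0.7])
        s = np.array([1.0])
        draws_birr = sample_prior_variances(
            b, ModelSpec("BIRR", df_b=3.0), s, 1.5, np.random.default_rng(7)
        )
        draws_bai = sample_prior_variances(
            b, ModelSpec("BAI", df_b=3.0), s, 1.5, np.random.default_rng(7)
        )
        np.testing.assert_allclose(draws_birr, draws_bai)

    def test_bir2_alpha_zero_update_identical_to_birr(self):
        b = np.array([0.3, -0.8, 1.2])
        s = np.array([5.0, 2.0, 1.0])
        d_birr = sample_prior_variances(
            b, ModelSpec("BIRR", df_b=3.0), s, 0.9, np.random.default_rng(8)
        )
        d_bir2 = sample_prior_variances(
            b, ModelSpec("BIR2", df_phi=3.0, alpha=0.0), s, 0.9,
            np.random.default_rng(8),
        )
        np.testing.assert_allclose(d_birr, d_bir2)

    def test_bai_returns_per_coefficient_variances(self):
        rng = np.random.default_rng(9)
        out = sample_prior_variances(
            np.array([0.1, 5.0]), ModelSpec("BAI", df_b=3.0), np.ones(2), 1.0, rng
        )
        assert out.shape == (2,)
        assert np.all(out > 0)


class TestHyperScaleSampler:
    def test_untruncated_gamma_moments(self):
        rng = np.random.default_rng(110)
        variances = np.array([0.5, 1.0, 2.0])
        df = 3.0
        shape = 0.5 * len(variances) * df + 1.0
        rate = 0.5 * df * np.sum(1.0 / variances)
        # bound far beyond the Gamma mass -> effectively untruncated
        draws = np.array(
            [sample_hyper_scale(variances, df, 1e6, rng) for _ in range(50_000)]
        )
        assert abs(draws.mean() - shape / rate) < 0.02 * shape / rate

    def test_small_bound_flat_kernel_is_uniform(self):
        rng = np.random.default_rng(111)
        # near-zero df -> shape ~ 1 and rate*A ~ 0: kernel flat on (0, A)
        draws = np.array(
            [sample_hyper_scale(np.array([1.0]), 1e-4, 1e-4, rng)
             for _ in range(20_000)]
        )
        ks = stats.kstest(draws, stats.uniform(0, 1e-4).cdf).statistic
        assert ks < 0.02

    def test_truncated_density_matches_quadrature(self):
        rng = np.random.default_rng(112)
        variances = np.array([0.5, 1.0, 2.0, 4.0])
        df, bound = 3.0, 2.0
        shape = 0.5 * len(variances) * df + 1.0
        rate = 0.5 * df * np.sum(1.0 / variances)
        draws = np.array(
            [sample_hyper_scale(variances, df, bound, rng) for _ in range(100_000)]
        )
        assert np.all((draws > 0) & (draws < bound))
        grid = np.linspace(0, bound, 200_001)[1:]
        dens = grid ** (shape - 1) * np.exp(-rate * grid)
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        cdf_at = np.interp(np.sort(draws), grid, cdf)
        emp = np.arange(1, draws.size + 1) / draws.size
        assert np.max(np.abs(cdf_at - emp)) < 0.01

    def test_scaled_inv_chi2_parameterization(self):
        """Sampler convention matches density x^(-df/2-1) exp(-df*Sc/(2x))."""
        rng = np.random.default_rng(113)
        draws = sample_scaled_inv_chi2(6.0, 1.5, rng, size=100_000)
        oracle = sc_inv_chi2_dist(6.0, 1.5)
        assert stats.kstest(draws, oracle.cdf).statistic < 0.01
        assert abs(draws.mean() - 6.0 * 1.5 / 4.0) < 0.03


class TestRunChain:
    def _sim_transformed(self, r, sigma2_b, sigma2_e, seed):
        # Log-spaced spectrum: plenty of signal-dominated components to pin
        # down sigma2_b and plenty of noise-dominated ones for sigma2_e.
        s = 20.0 * (0.01) ** (np.arange(r) / max(r - 1, 1))
        rng = np.random.default_rng(seed)
        b = rng.normal(0.0, np.sqrt(sigma2_b), size=r)
        d = s * b + rng.normal(0.0, np.sqrt(sigma2_e), size=r)
        return d, s, b

    def test_default_config_retains_5000_draws(self):
        assert ChainConfig().n_retained == 5000

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)

    def test_same_seed_is_bit_identical(self):
        d, s, _ = self._sim_transformed(30, 0.1, 1.0, 1)
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=99)
        out1 = run_chain_transformed(d, s, ModelSpec("BAI"), cfg)
        out2 = run_chain_transformed(d, s, ModelSpec("BAI"), cfg)
        assert np.array_equal(out1.b, out2.b)
        assert np.array_equal(out1.sigma2_e, out2.sigma2_e)
        assert np.array_equal(out1.var_b, out2.var_b)

    def test_different_seeds_differ(self):
        d, s, _ = self._sim_transformed(30, 0.1, 1.0, 1)
        out1 = run_chain_transformed(
            d, s, ModelSpec("BIRR"), ChainConfig(400, 100, 2, seed=1)
        )
        out2 = run_chain_transformed(
            d, s, ModelSpec("BIRR"), ChainConfig(400, 100, 2, seed=2)
        )
        assert not np.array_equal(out1.b, out2.b)

    def test_frozen_variances_match_closed_form_mean(self):
        """With variances pinned, E[b_i] is the analytic conditional mean."""
        sigma2_b, sigma2_e = 0.2, 1.0
        d, s, _ = self._sim_transformed(50, sigma2_b, sigma2_e, 3)
        cfg = ChainConfig(n_iter=6000, burn_in=1000, thin=1, seed=5)
        out = run_chain_transformed(
            d, s, ModelSpec("BIRR"), cfg,
            fixed={"sigma2_e": sigma2_e, "var_b": sigma2_b},
        )
        denom = sigma2_b * s**2 + sigma2_e
        mean = sigma2_b * s * d / denom
        sd = np.sqrt(sigma2_e * sigma2_b / denom)
        mc_se = sd / np.sqrt(out.n_draws)
        assert np.all(np.abs(out.b.mean(axis=0) - mean) < 4 * mc_se)

    def test_retained_variances_positive_and_scale_bounded(self):
        d, s, _ = self._sim_transformed(40, 0.1, 1.0, 4)
        for model in ("BIRR", "BAI", "BIR1", "BIR2"):
            out = run_chain_transformed(
                d, s, ModelSpec(model), ChainConfig(600, 100, 1, seed=6)
            )
            assert np.all(out.sigma2_e > 0)
            assert np.all(out.var_b > 0)
            assert np.all(
                (out.scale_hyper > 0) & (out.scale_hyper < out.spec.hyper_bound)
            )

    def test_parameter_recovery_transformed_scale(self):
        """BIRR posterior means recover the generating variances within 15%."""
        errs_e, errs_b = [], []
        for seed in range(10):
            d, s, _ = self._sim_transformed(200, 0.1, 1.0, 100 + seed)
            out = run_chain_transformed(
                d, s, ModelSpec("BIRR"),
                ChainConfig(n_iter=4000, burn_in=1000, thin=2, seed=seed),
            )
            errs_e.append(out.sigma2_e.mean() - 1.0)
            errs_b.append(out.var_b.mean() - 0.1)
        assert abs(np.mean(errs_e)) < 0.15 * 1.0
        assert abs(np.mean(errs_b)) < 0.15 * 0.1

    def test_shrinkage_ordering_bir2_vs_birr(self):
        """On decaying spectra BIR2 (alpha=1) shrinks ||b||^2 at least as hard."""
        rng = np.random.default_rng(30)
        r = 80
        s = 20.0 * np.arange(1, r + 1, dtype=float) ** -1.0
        b_true = rng.normal(0.0, 0.3, size=r)
        d = s * b_true + rng.normal(0.0, 1.0, size=r)
        cfg = ChainConfig(n_iter=4000, burn_in=1000, thin=2, seed=31)
        norm = {}
        for model, alpha in (("BIRR", None), ("BIR2", 1.0)):
            out = run_chain_transformed(d, s, ModelSpec(model, alpha=alpha), cfg)
            norm[model] = np.mean(np.sum(out.b**2, axis=1))
        assert norm["BIR2"] <= norm["BIRR"]


class TestSummaryAndPrediction:
    def test_single_draw_summary_equals_that_draw(self, small_dataset):
        aligned = small_dataset["aligned"]
        cfg = ChainConfig(n_iter=101, burn_in=100, thin=10, seed=1)
        samples = run_chain(aligned, ModelSpec("BIRR"), cfg)
        assert samples.n_draws == 1
        fit = summarize_fit(samples)
        np.testing.assert_array_equal(fit.b_mean, samples.b[0])
        np.testing.assert_allclose(
            fit.beta_hat, samples.basis.V1 @ samples.b[0], rtol=1e-12
        )

    def test_zero_coefficients_give_zero_effects(self, small_dataset):
        aligned = small_dataset["aligned"]
        samples = run_chain(
            aligned, ModelSpec("BIRR"), ChainConfig(300, 100, 2, seed=2)
        )
        samples.b[:] = 0.0
        fit = summarize_fit(samples)
        np.testing.assert_array_equal(fit.beta_hat, 0.0)

    def test_weighting_profile_monotone_on_decaying_spectrum(self):
        """Posterior-mean weights fall along the spectrum for BIRR."""
        rng = np.random.default_rng(40)
        r = 60
        s = 15.0 * np.exp(-0.05 * np.arange(r))
        b_true = rng.normal(0.0, 0.3, size=r)
        d = s * b_true + rng.normal(size=r)
        out = run_chain_transformed(
            d, s, ModelSpec("BIRR"), ChainConfig(2000, 500, 2, seed=41)
        )
        from invgp import SVDBasis

        basis = SVDBasis(U=np.eye(r), s=s, V1=np.eye(r), r=r, trunc_tol=0.0)
        fit = summarize_fit(out, basis=basis, mu=0.0)
        assert np.all((fit.f_mean > 0) & (fit.f_mean < 1))
        assert np.all(np.diff(fit.f_mean) < 0)

    def test_prediction_contract(self, small_dataset):
        aligned = small_dataset["aligned"]
        samples = run_chain(
            aligned, ModelSpec("BIRR"), ChainConfig(300, 100, 2, seed=3)
        )
        fit = summarize_fit(samples)
        zeros = np.zeros((4, aligned.X.n_markers))
        np.testing.assert_allclose(predict_values(fit, zeros), fit.mu)
        with pytest.raises(ValueError, match="marker columns"):
            predict_values(fit, np.zeros((4, 3)))

    def test_interpolation_limit_reproduces_training_data(self):
        """Full-rank X with vanishing error variance interpolates y exactly."""
        rng = np.random.default_rng(50)
        X = rng.normal(size=(10, 10))
        y = rng.normal(size=10)
        basis = decompose(X)
        d = forward_transform(basis, y)
        out = run_chain_transformed(
            d, basis.s, ModelSpec("BIRR"),
            ChainConfig(500, 100, 1, seed=51),
            fixed={"sigma2_e": 1e-12, "var_b": 10.0},
        )
        out.basis = basis
        fit = summarize_fit(out, mu=0.0)
        np.testing.assert_allclose(X @ fit.beta_hat, y, atol=1e-4)

    def test_empty_samples_rejected(self, small_dataset):
        aligned = small_dataset["aligned"]
        samples = run_chain(
            aligned, ModelSpec("BIRR"), ChainConfig(300, 100, 2, seed=4)
        )
        samples.b = samples.b[:0]
        import dataclasses

        samples = dataclasses.replace(samples)
        with pytest.raises(ValueError, match="no retained draws"):
            summarize_fit(samples)
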