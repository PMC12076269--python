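"""Bayesian model: log-posterior, sampling, diagnostics, marginal fits."""

import numpy as np
import pytest
from scipy import stats

from hemuq import (
    CouetteDesign,
    HemolysisModel,
    LogNormalFit,
    NoiseSpec,
    PriorSpec,
    REFERENCE_PARAMS,
    SamplerConfig,
    ShearDataset,
    ShearRecord,
    generate_couette_dataset,
)
from hemuq.model import HemolysisResults, build_posterior_model

TINY = SamplerConfig.quick(n_chains=2, n_draws=300, n_tune=300)


def _fake_results(draws):
    return HemolysisResults(model=None, draws=draws)


class TestLogPosterior:
    def test_matches_direct_density_arithmetic(self):
        """2-record toy dataset: log-posterior equals the hand-summed
        prior + Student-t likelihood terms evaluated with scipy."""
        ds = ShearDataset([ShearRecord(100.0, 0.5, 0.8),
                           ShearRecord(200.0, 1.0, 2.5)])
        model = HemolysisModel(ds)  # all five parameters free
        c, a, b, sig, nu = 2e-5, 0.7, 1.9, 0.15, 12.0
        mu = c * ds.tau**b * ds.t_exp**a
        expected = (
            stats.uniform(0, 1).logpdf(c)
            + stats.norm(0, 1).logpdf(a)
            + stats.norm(0, 1).logpdf(b)
            + stats.halfnorm(scale=1).logpdf(sig)
            + stats.expon(scale=30).logpdf(nu)
            + stats.t(df=nu, loc=mu, scale=sig).logpdf(ds.hi).sum()
        )
        got = model.log_posterior(np.array([c, a, b, sig, nu]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_support_is_minus_inf(self):
        ds = ShearDataset([ShearRecord(100.0, 0.5, 0.8)])
        model = HemolysisModel(ds)
        assert model.log_posterior(np.array([2e-5, 0.7, 1.9, -0.1, 12.0])) == -np.inf
        assert model.log_posterior(np.array([1.5, 0.7, 1.9, 0.1, 12.0])) == -np.inf

    def test_free_parameter_bookkeeping(self, noisy_dataset):
        full = build_posterior_model(noisy_dataset)
        assert full.free_names == ("C", "alpha", "beta", "sigma", "nu")
        fixed_c = build_posterior_model(
            noisy_dataset, PriorSpec().fix_c(1.228e-5)
        )
        assert fixed_c.free_names == ("alpha", "beta", "sigma", "nu")
        both = build_posterior_model(
            noisy_dataset,
            PriorSpec(c_prior=("fixed", 1.228e-5), nu_prior=("fixed", 30.0)),
        )
        assert both.free_names == ("alpha", "beta", "sigma")

    def test_batch_equals_scalar(self, noisy_dataset):
        model = HemolysisModel(noisy_dataset)
        pts = np.array([
            [2e-5, 0.7, 1.9, 0.15, 12.0],
            [1e-5, 0.6, 2.0, 0.05, 30.0],
        ])
        batch = model.log_posterior(pts)
        assert batch[0] == model.log_posterior(pts[0])
        assert batch[1] == model.log_posterior(pts[1])


class TestSampling:
    def test_draw_count_bookkeeping(self, fixedc_results):
        assert fixedc_results.n_chains == 4
        assert fixedc_results.n_draws == 2000
        for arr in fixedc_results.draws.values():
            assert arr.shape == (4, 2000)

    def test_same_seed_identical_draws(self, noisy_dataset):
        model = HemolysisModel(noisy_dataset, PriorSpec().fix_c(1.228e-5))
        r1 = model.fit(TINY)
        r2 = model.fit(TINY)
        for name in r1.draws:
            assert np.array_equal(r1.draws[name], r2.draws[name])

    def test_noise_free_recovery_fixed_c(self, noisefree_dataset):
        """Credibility check: on data lying exactly on the model surface,
        the fixed-C posterior pins the generating exponents."""
        model = HemolysisModel(
            noisefree_dataset, PriorSpec().fix_c(REFERENCE_PARAMS.c_coeff)
        )
        res = model.fit(SamplerConfig.quick(n_chains=2, n_draws=500, seed=4))
        assert np.median(res.pooled("alpha")) == pytest.approx(
            REFERENCE_PARAMS.alpha, rel=0.01
        )
        assert np.median(res.pooled("beta")) == pytest.approx(
            REFERENCE_PARAMS.beta, rel=0.01
        )

    def test_interval_width_grows_with_noise(self):
        """5-95% posterior intervals of alpha and beta widen as the
        generator's noise scale increases."""
        widths = {}
        for sigma in (0.0, 0.05, 0.3):
            kind = "none" if sigma == 0 else "student_t"
            ds = generate_couette_dataset(
                CouetteDesign(noise=NoiseSpec(kind=kind, sigma=sigma), seed=11)
            )
            res = HemolysisModel(ds, PriorSpec().fix_c(1.228e-5)).fit(
                SamplerConfig.quick(n_chains=2, n_draws=500, seed=6)
            )
            s = res.posterior_summary()
            widths[sigma] = (
                s.loc["alpha", "q95"] - s.loc["alpha", "q05"],
                s.loc["beta", "q95"] - s.loc["beta", "q05"],
            )
        assert widths[0.0][0] < widths[0.05][0] < widths[0.3][0]
        assert widths[0.0][1] < widths[0.05][1] < widths[0.3][1]


class TestDiagnostics:
    def test_rhat_near_one_for_same_law_chains(self, rng):
        """Independent chains from one stationary law: R-hat ~ 1."""
        draws = {"x": rng.normal(0, 1, (4, 10_000)),
                 "y": rng.normal(5, 2, (4, 10_000))}
        rhat = _fake_results(draws).gelman_rubin()
        assert rhat["x"] < 1.01 and rhat["y"] < 1.01

    def test_rhat_flags_shifted_chains(self, rng):
        base = rng.normal(0, 1, (2, 5_000))
        shifted = base.copy()
        shifted[1] += 5.0  # 5-sd mean separation
        rhat = _fake_results({"x": shifted}).gelman_rubin()
        assert rhat["x"] > 1.5

    def test_rhat_requires_two_chains(self, rng):
        res = _fake_results({"x": rng.normal(0, 1, (1, 100))})
        with pytest.raises(ValueError):
            res.gelman_rubin()

    def test_summary_quantiles_match_analytic(self, rng):
        draws = {"x": rng.standard_normal((1, 1_000_000))}
        s = _fake_results(draws).posterior_summary()
        assert s.loc["x", "median"] == pytest.approx(0.0, abs=0.01)
        assert s.loc["x", "q05"] == pytest.approx(-1.6449, abs=0.01)
        assert s.loc["x", "q95"] == pytest.approx(1.6449, abs=0.01)

    def test_summary_permutation_invariant(self, rng):
        x = rng.normal(0, 1, (2, 1000))
        perm = x.reshape(-1)
        rng.shuffle(perm)
        a = _fake_results({"x": x}).posterior_summary()
        b = _fake_results({"x": perm.reshape(2, 1000)}).posterior_summary()
        assert np.allclose(a.values, b.values)

    def test_constant_draws_summary(self):
        s = _fake_results({"x": np.full((2, 100), 3.5)}).posterior_summary()
        assert s.loc["x", "median"] == 3.5
        assert s.loc["x", "q05"] == s.loc["x", "q95"] == 3.5


class TestCorrelations:
    def test_diagonal_and_symmetry(self, fixedc_results):
        corr = fixedc_results.correlations()
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.allclose(corr.values, corr.values.T)
        assert np.all(np.abs(corr.values) <= 1.0 + 1e-12)

    def test_independent_draws_uncorrelated(self, rng):
        draws = {"x": rng.normal(0, 1, (1, 100_000)),
                 "y": rng.normal(0, 1, (1, 100_000))}
        corr = _fake_results(draws).correlations()
        assert abs(corr.loc["x", "y"]) < 0.02

    def test_zero_variance_flagged_as_nan(self, rng):
        draws = {"x": rng.normal(0, 1, (1, 100)),
                 "y": np.full((1, 100), 2.0)}
        corr = _fake_results(draws).correlations()
        assert np.isnan(corr.loc["x", "y"])


class TestLogNormalFit:
    def test_mle_recovery(self, rng):
        shape, scale = 0.2, 0.6
        samples = scale * np.exp(shape * rng.standard_normal(100_000))
        fit = LogNormalFit.from_samples(samples)
        assert fit.shape == pytest.approx(shape, rel=0.02)
        assert fit.scale == pytest.approx(scale, rel=0.02)
        assert fit.location == 0.0

    def test_truncation_bounds_are_1_99_quantiles(self, rng):
        samples = np.exp(0.3 * rng.standard_normal(10_000))
        fit = LogNormalFit.from_samples(samples)
        dist = stats.lognorm(fit.shape, loc=0, scale=fit.scale)
        assert fit.trunc_low == pytest.approx(dist.ppf(0.01), rel=1e-12)
        assert fit.trunc_high == pytest.approx(dist.ppf(0.99), rel=1e-12)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            LogNormalFit.from_samples(np.array([0.5, -0.1, 1.0]))

    def test_posterior_marginal_fit_centres_on_median(self, fixedc_results):
        fit = fixedc_results.fit_truncated_lognormal("alpha")
        med = np.median(fixedc_results.pooled("alpha"))
        assert fit.scale == pytest.approx(med, rel=0.02)
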