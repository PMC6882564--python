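"""Sampler correctness against the closed-form posterior, derived
quantities and convergence diagnostics."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from ctdose import (
    McmcConfig,
    McmcError,
    PosteriorDraws,
    UndefinedMomentsError,
    analytic_posterior,
    coverage_dose,
    delta_method_sd,
    exceedance_probability,
    gelman_rubin,
    moment_match,
    sample_posterior,
    split_rhat,
    summarize_posterior,
)


def matched_data(rng, n, mean, sd):
    return moment_match(rng.normal(size=n), mean, sd)


def constant_draws(mu, sigma, n_chains=2, n_draws=100):
    cfg = McmcConfig(n_chains=n_chains, draws_per_chain=n_draws + 1, burn_in=1,
                     mu_bounds=(-1e6, 1e6), sigma_bounds=(1e-9, 1e6))
    return PosteriorDraws(
        mu=np.full((n_chains, n_draws), float(mu)),
        sigma=np.full((n_chains, n_draws), float(sigma)),
        n=100, sample_mean=float(mu), sample_sd=float(sigma), config=cfg,
    )


class TestAnalyticPosterior:
    def test_location_posterior_is_centred_on_sample_mean(self):
        ap = analytic_posterior(100, 1.681, 0.264)
        assert ap.mu_mean() == 1.681
        assert ap.mu_ppf(0.5) == pytest.approx(1.681)

    def test_mu_sd_matches_t_variance_formula(self):
        # SD(mu) = (s/sqrt(n)) * sqrt((n-1)/(n-4))
        ap = analytic_posterior(100, 1.681, 0.264)
        assert ap.mu_sd() == pytest.approx(0.0264 * np.sqrt(99 / 96), rel=1e-3)
        assert ap.mu_sd() == pytest.approx(0.0268, abs=2e-4)

    def test_sigma2_mean_matches_inverse_chi_square_formula(self):
        ap = analytic_posterior(100, 1.681, 0.264)
        assert ap.sigma2_mean() == pytest.approx(99 * 0.264**2 / 96, rel=1e-12)
        assert ap.sigma2_mean() == pytest.approx(0.0719, abs=1e-4)

    def test_sigma_quantiles_invert_chi_square(self):
        ap = analytic_posterior(50, 1.0, 0.3)
        q = np.array([0.1, 0.5, 0.9])
        # CDF(ppf(q)) == q through the chi2 representation
        from scipy.stats import chi2

        x = ap.sigma_ppf(q)
        back = chi2.sf(49 * 0.3**2 / x**2, 48)
        assert back == pytest.approx(q)

    def test_too_small_n_rejected(self):
        with pytest.raises(UndefinedMomentsError):
            analytic_posterior(3, 1.0, 0.3)


class TestSampler:
    def test_seed_contract_identical_draws(self, rng, small_mcmc):
        y = matched_data(rng, 50, 1.7, 0.3)
        d1 = sample_posterior(y, small_mcmc)
        d2 = sample_posterior(y, small_mcmc)
        assert np.array_equal(d1.mu, d2.mu)
        assert np.array_equal(d1.sigma, d2.sigma)

    def test_draw_count_and_prior_box_respected(self, rng, small_mcmc):
        y = matched_data(rng, 60, 1.7, 0.3)
        d = sample_posterior(y, small_mcmc)
        assert d.mu.shape == (4, 2500)
        assert small_mcmc.retained_total == 10_000
        lo, hi = small_mcmc.mu_bounds
        assert ((d.mu >= lo) & (d.mu <= hi)).all()
        assert (d.sigma > 0).all()

    def test_marginals_match_oracle_at_published_moments(self, rng):
        y = matched_data(rng, 100, 1.681, 0.264)
        d = sample_posterior(y, McmcConfig(n_chains=5, draws_per_chain=5000,
                                           burn_in=500, seed=2))
        ap = analytic_posterior(100, 1.681, 0.264)
        assert d.mu.mean() == pytest.approx(ap.mu_mean(), abs=0.003)
        assert d.mu.std(ddof=1) == pytest.approx(ap.mu_sd(), rel=0.05)
        assert d.sigma.mean() == pytest.approx(ap.sigma_mean(), rel=0.02)

    def test_metropolis_sampler_agrees_with_oracle(self, rng):
        y = matched_data(rng, 80, 1.7, 0.3)
        cfg = McmcConfig(n_chains=4, draws_per_chain=20_000, burn_in=2_000,
                         seed=4, sampler="metropolis")
        d = sample_posterior(y, cfg)
        ap = analytic_posterior(80, 1.7, 0.3)
        assert d.mu.mean() == pytest.approx(ap.mu_mean(), abs=0.01)
        assert d.sigma.mean() == pytest.approx(ap.sigma_mean(), rel=0.05)

    def test_wide_vs_wider_prior_bounds_are_immaterial(self, rng):
        y = matched_data(rng, 100, 1.7, 0.3)
        base = McmcConfig(n_chains=4, draws_per_chain=10_000, burn_in=1000, seed=6)
        wider = dataclasses.replace(base, mu_bounds=(-100.0, 100.0), sigma_bounds=(1e-9, 100.0))
        d1, d2 = sample_posterior(y, base), sample_posterior(y, wider)
        for a, b in [(d1.mu.mean(), d2.mu.mean()), (d1.sigma.mean(), d2.sigma.mean())]:
            assert abs(a - b) / abs(a) < 1e-3

    def test_zero_variance_data_rejected(self, small_mcmc):
        with pytest.raises(McmcError):
            sample_posterior([2.0] * 10, small_mcmc)

    def test_prior_excluding_sample_mean_rejected(self, rng):
        y = matched_data(rng, 20, 8.0, 0.5)
        cfg = McmcConfig(mu_bounds=(0.0, 5.0))
        with pytest.raises(McmcError, match="exclude"):
            sample_posterior(y, cfg)

    def test_inconsistent_burn_in_rejected(self):
        with pytest.raises(McmcError):
            McmcConfig(draws_per_chain=100, burn_in=100)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "mu,sigma,expected",
        [(1.681, 0.264, 0.887), (1.818, 0.482, 0.647)],
    )
    def test_plugin_probability_matches_published(self, mu, sigma, expected):
        p = exceedance_probability(constant_draws(mu, sigma), 2.0)
        assert p.mean == pytest.approx(expected, abs=5e-4)
        assert p.sd == pytest.approx(0.0, abs=1e-12)

    def test_probability_is_half_when_mean_equals_limit(self):
        for sigma in (0.1, 0.5, 2.0):
            p = exceedance_probability(constant_draws(2.0, sigma), 2.0)
            assert p.mean == pytest.approx(0.5)

    def test_probability_monotone_in_dose_limit(self, rng, small_mcmc):
        d = sample_posterior(matched_data(rng, 50, 1.7, 0.3), small_mcmc)
        probs = [exceedance_probability(d, L).mean for L in (1.5, 2.0, 2.5)]
        assert probs[0] < probs[1] < probs[2]

    def test_coverage_dose_plugin_matches_published(self):
        q = coverage_dose(constant_draws(1.681, 0.264), 0.95)
        assert q.mean == pytest.approx(1.681 + 1.6449 * 0.264, abs=2e-4)
        assert q.mean == pytest.approx(2.113, abs=3e-3)

    def test_coverage_half_returns_posterior_mean_and_tiny_sigma_collapses(self):
        d = constant_draws(1.7, 0.3)
        assert coverage_dose(d, 0.5).mean == pytest.approx(1.7)
        assert coverage_dose(constant_draws(1.7, 1e-12), 0.95).mean == pytest.approx(1.7)

    def test_coverage_dose_monotone_in_coverage(self, rng, small_mcmc):
        d = sample_posterior(matched_data(rng, 50, 1.7, 0.3), small_mcmc)
        qs = [coverage_dose(d, c).mean for c in (0.5, 0.9, 0.95, 0.99)]
        assert np.all(np.diff(qs) > 0)

    def test_exceedance_of_coverage_dose_is_the_coverage(self, rng, small_mcmc):
        """Per draw, plugging q_k back in gives attainment == coverage."""
        d = sample_posterior(matched_data(rng, 50, 1.7, 0.3), small_mcmc)
        q = coverage_dose(d, 0.95)
        back = norm.cdf((q.values - d.flat("mu")) / d.flat("sigma"))
        assert back == pytest.approx(0.95, abs=1e-12)


class TestDeltaMethod:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(1.681, 0.264, 0.025), (1.818, 0.482, 0.038)],
    )
    def test_matches_published_probability_sds(self, mean, sd, expected):
        assert delta_method_sd(100, mean, sd, 2.0) == pytest.approx(expected, abs=6e-4)

    def test_vanishes_with_posterior_concentration(self):
        small = delta_method_sd(10_000_000, 1.681, 0.264, 2.0)
        assert small < 1e-3
        assert small < delta_method_sd(100, 1.681, 0.264, 2.0)


class TestDiagnostics:
    def test_identical_chains_have_unit_rhat(self):
        x = np.tile(np.sin(np.arange(1000.0)), (4, 1))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_have_large_rhat(self, rng):
        a = rng.normal(0.0, 1.0, size=(1, 500))
        b = rng.normal(10.0, 1.0, size=(1, 500))
        assert split_rhat(np.vstack([a, b])) > 1.5

    def test_default_run_is_well_mixed(self, rng, small_mcmc):
        d = sample_posterior(matched_data(rng, 100, 1.681, 0.264), small_mcmc)
        r = gelman_rubin(d)
        assert r["mu"] < 1.01 and r["sigma"] < 1.01

    def test_agrees_with_arviz_split_rhat(self, rng, small_mcmc):
        import arviz as az

        d = sample_posterior(matched_data(rng, 50, 1.7, 0.3), small_mcmc)
        ours = split_rhat(d.mu)
        theirs = float(az.rhat(np.asarray(d.mu), method="split"))
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_single_chain_rejected(self, rng):
        cfg = McmcConfig(n_chains=1, draws_per_chain=500, burn_in=100, seed=1)
        d = sample_posterior(matched_data(rng, 30, 1.7, 0.3), cfg)
        with pytest.raises(McmcError):
            gelman_rubin(d)


class TestSummary:
    def test_summary_is_internally_consistent(self, rng, small_mcmc):
        d = sample_posterior(matched_data(rng, 100, 1.681, 0.264), small_mcmc)
        s = summarize_posterior(d, dose_limit=2.0, coverage=0.95)
        assert 0.0 <= s.p.mean <= 1.0
        assert s.p.ci_low <= s.p.mean <= s.p.ci_high
        assert s.q.ci_low <= s.q.mean <= s.q.ci_high
        assert s.rhat["mu"] >= 1.0 - 1e-3
        assert s.ess["mu"] > 1000
        round_trip = s.to_dict()
        assert round_trip["p"]["mean"] == s.p.mean
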