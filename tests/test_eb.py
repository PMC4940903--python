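"""Poisson-Gamma empirical Bayes: posterior math, estimators, shrinkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from owratio.eb import (
    GammaPrior,
    PoissonGammaModel,
    eb_table,
    fit_gamma_prior,
    marginal_loglik_gradient,
    posterior_summary,
)

ADJUSTED_PAIRS = [(16, 26.6), (74, 66.6), (81, 79.8), (12, 9.3)]
CRUDE_PAIRS = [(21, 37.0), (100, 89.7), (107, 102.6), (14, 12.6)]


class TestPosteriorSummary:
    def test_posterior_mean_identity_matches_numerical_integration(self):
        prior = GammaPrior(alpha=11.8, beta=11.8)
        O, E = 16, 26.6
        est = posterior_summary(O, E, prior)
        # integrate theta * posterior density numerically
        shape, rate = O + prior.alpha, E + prior.beta
        pdf = lambda t: stats.gamma.pdf(t, shape, scale=1 / rate)
        mean, _ = integrate.quad(lambda t: t * pdf(t), 0, 10)
        assert est.eb_mean == pytest.approx(mean, abs=1e-8)

    def test_prob_below_one_matches_sampling_oracle(self):
        rng = np.random.default_rng(123)
        prior = GammaPrior(alpha=11.8, beta=11.8)
        for O, E in ADJUSTED_PAIRS:
            est = posterior_summary(O, E, prior)
            draws = rng.gamma(O + prior.alpha, 1 / (E + prior.beta), size=100_000)
            assert est.prob_below_1 == pytest.approx(np.mean(draws < 1), abs=0.005)

    def test_credible_interval_contains_posterior_mean(self):
        prior = GammaPrior(alpha=3.0, beta=2.5)
        est = posterior_summary(7, 5.0, prior)
        assert est.credible95[0] < est.eb_mean < est.credible95[1]

    def test_total_shrinkage_limit(self):
        """A near-degenerate prior at mean 1 pins the posterior mean at 1."""
        prior = GammaPrior(alpha=1e8, beta=1e8)
        est = posterior_summary(3, 30.0, prior)
        assert est.eb_mean == pytest.approx(1.0, abs=1e-4)

    def test_invalid_inputs_rejected(self):
        prior = GammaPrior(alpha=1.0, beta=1.0)
        with pytest.raises(ValueError):
            posterior_summary(3, 0.0, prior)
        with pytest.raises(ValueError):
            GammaPrior(alpha=-1.0, beta=1.0)


class TestShrinkage:
    @settings(max_examples=60, deadline=None)
    @given(
        o1=st.integers(0, 60), o2=st.integers(0, 60),
        e1=st.floats(1.0, 80.0), e2=st.floats(1.0, 80.0),
        o3=st.integers(0, 60), e3=st.floats(1.0, 80.0),
    )
    def test_eb_mean_lies_between_raw_ratio_and_prior_mean(self, o1, o2, e1, e2, o3, e3):
        pairs = [(o1, e1), (o2, e2), (o3, e3)]
        try:
            prior = fit_gamma_prior(pairs, method="moments")
        except Exception:
            return  # degenerate ensembles are allowed to fail fitting
        for o, e in pairs:
            est = posterior_summary(o, e, prior)
            lo, hi = sorted((o / e, prior.mean))
            assert lo - 1e-9 <= est.eb_mean <= hi + 1e-9

    def test_large_expected_count_recovers_raw_ratio(self):
        prior = GammaPrior(alpha=10.0, beta=10.0)
        raw = 0.6
        gaps = [
            abs(posterior_summary(raw * E, E, prior).eb_mean - raw)
            for E in (10, 1_000, 100_000)
        ]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-3

    def test_small_expected_count_recovers_prior_mean(self):
        prior = GammaPrior(alpha=10.0, beta=10.0)
        est = posterior_summary(0, 1e-6, prior)
        assert est.eb_mean == pytest.approx(prior.mean, rel=1e-4)

    def test_exchangeability_identical_pairs_identical_outputs(self):
        table = eb_table([(10, 12.0), (10, 12.0), (30, 20.0)], labels=list("abc"))
        assert table[0].eb_mean == table[1].eb_mean
        assert table[0].credible95 == table[1].credible95


class TestEstimators:
    def test_moments_fit_reproduces_published_adjusted_column(self):
        res = PoissonGammaModel(
            [p[0] for p in ADJUSTED_PAIRS], [p[1] for p in ADJUSTED_PAIRS]
        ).fit(method="moments")
        assert np.allclose(res.eb_means, [0.73, 1.09, 1.01, 1.13], atol=0.03)

    def test_moments_fit_reproduces_published_crude_column(self):
        res = PoissonGammaModel(
            [p[0] for p in CRUDE_PAIRS], [p[1] for p in CRUDE_PAIRS]
        ).fit(method="moments")
        assert np.allclose(res.eb_means, [0.67, 1.09, 1.03, 1.03], atol=0.03)

    def test_homogeneous_large_counts_give_tight_prior_near_one(self):
        pairs = [(1000, 1000.0)] * 6
        prior = fit_gamma_prior(pairs, method="clayton-kaldor")
        assert prior.mean == pytest.approx(1.0, abs=0.01)
        assert prior.variance < 0.01

    def test_mle_recovers_generating_hyperparameters(self):
        """Recovery of the generating prior from ensembles of 200 areas:
        the estimator is unbiased to within 15 % when averaged over
        replicates (a single 200-area ensemble carries ~12 % sampling noise
        on the hyperparameters)."""
        rng = np.random.default_rng(7)
        a0, b0 = 8.0, 8.0
        alphas, betas = [], []
        for _ in range(8):
            theta = rng.gamma(a0, 1 / b0, size=200)
            E = rng.uniform(20, 120, size=200)
            O = rng.poisson(theta * E)
            prior = fit_gamma_prior(list(zip(O, E)), method="mle")
            alphas.append(prior.alpha)
            betas.append(prior.beta)
        assert np.mean(alphas) == pytest.approx(a0, rel=0.15)
        assert np.mean(betas) == pytest.approx(b0, rel=0.15)

    def test_mle_gradient_vanishes_at_interior_optimum(self):
        rng = np.random.default_rng(7)
        theta = rng.gamma(8.0, 1 / 8.0, size=200)
        E = rng.uniform(20, 120, size=200)
        O = rng.poisson(theta * E)
        pairs = list(zip(O, E))
        prior = fit_gamma_prior(pairs, method="mle")
        assert np.linalg.norm(marginal_loglik_gradient(prior, pairs)) < 1e-6

    def test_fewer_than_two_areas_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_prior([(5, 5.0)])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            fit_gamma_prior(ADJUSTED_PAIRS, method="bogus")


class TestModelObject:
    def test_from_standardization_round_trip(self, study_classified):
        from owratio.standardize import IndirectStandardization

        std = IndirectStandardization(
            study_classified, ["sex"], rate_cohort=study_classified
        ).fit()
        res = PoissonGammaModel.from_standardization(std).fit()
        assert [e.label for e in res.estimates] == ["lt10", "10to19.9", "20to29.9", "ge30"]
        # smoothing pulls the affluent stratum's ratio towards one
        assert std.ratios[0].ratio < res.estimates[0].eb_mean < 1.0

    def test_summary_table_shape(self):
        res = PoissonGammaModel(
            [p[0] for p in CRUDE_PAIRS], [p[1] for p in CRUDE_PAIRS],
            labels=["a", "b", "c", "d"],
        ).fit()
        tab = res.summary()
        assert list(tab["area"]) == ["a", "b", "c", "d"]
        assert {"raw_ratio", "eb_ratio", "ci_low", "ci_high", "p_below_1"} <= set(tab.columns)
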