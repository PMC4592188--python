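"""Posterior analysis: random effects, dependency mixture, generation,
correlations and marginal summaries."""

import numpy as np
import pytest

from bayespbpk.posterior import (
    PosteriorSample,
    correlation_analysis,
    extract_random_effects,
    fit_dependency_mixture,
    generate_individual,
    generate_population,
    intraindividual_correlation,
    marginal_summaries,
)
from bayespbpk.synthetic import make_synthetic_posterior

PAIR = ("specTS", "volume_kidney")


def _sample_from_b(model, b, M=None, S=None):
    """Build a PosteriorSample whose draws encode the given effects."""
    Z, N, K = b.shape
    M = model.priors.M_mu if M is None else M
    S = model.priors.S_mu if S is None else S
    mu, sd = model.scaled_moments(M, S)
    states = np.empty((Z, model.layout.dimension))
    for z in range(Z):
        states[z] = model.layout.pack(mu + sd * b[z], model.priors.g_start,
                                      0.01, M, S)
    return PosteriorSample(model=model, states=states)


class TestRandomEffects:
    def test_scaled_mean_gives_zero_effects(self, model):
        b = np.zeros((3, model.layout.n_individuals, model.layout.K))
        sample = _sample_from_b(model, b)
        np.testing.assert_allclose(extract_random_effects(sample), 0.0,
                                   atol=1e-12)

    def test_known_effects_recovered_exactly(self, model, rng):
        b = rng.standard_normal((4, model.layout.n_individuals,
                                 model.layout.K))
        sample = _sample_from_b(model, b)
        np.testing.assert_allclose(extract_random_effects(sample), b,
                                   atol=1e-9)

    def test_matches_direct_formula_on_random_draws(self, model, rng):
        Z = 3
        lay = model.layout
        states = np.stack([model.initial_state()] * Z)
        states += 0.01 * rng.standard_normal(states.shape) * np.abs(states)
        states[:, lay.S_slice] = np.abs(states[:, lay.S_slice]) + 0.01
        sample = PosteriorSample(model=model, states=states)
        b = extract_random_effects(sample)
        for z in range(Z):
            theta, _g, _s2, M, S = lay.unpack(states[z])
            mu = model.scale_a * M + model.shift_c
            sd = model.scale_d * S
            np.testing.assert_allclose(b[z], (theta - mu) / sd, rtol=1e-10)


class TestDependencyMixture:
    def test_identical_individuals_give_zero_covariance(self, model):
        row = np.full((model.layout.n_individuals, model.layout.K), 0.3)
        b = np.stack([row, row])
        _bbar, sigma = fit_dependency_mixture(b)
        np.testing.assert_allclose(sigma, 0.0, atol=1e-15)

    def test_three_row_hand_covariance(self, model):
        rows = np.array([[1.0, 2.0], [3.0, 2.0], [2.0, 5.0]])
        b = rows[None, :, :]  # Z=1, N=3, K=2
        bbar, sigma = fit_dependency_mixture(b)
        np.testing.assert_allclose(bbar[0], [2.0, 3.0])
        # hand-computed sample covariance (ddof=1)
        np.testing.assert_allclose(
            sigma[0], [[1.0, 0.0], [0.0, 3.0]], atol=1e-12)

    def test_mixture_mean_is_grand_mean(self, rng, model):
        b = rng.standard_normal((5, 4, 3))
        bbar, _ = fit_dependency_mixture(b)
        np.testing.assert_allclose(bbar.mean(axis=0),
                                   b.mean(axis=(0, 1)), rtol=1e-12)

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            fit_dependency_mixture(np.zeros((2, 1, 3)))


class TestGeneration:
    def test_zero_covariance_gives_deterministic_theta(self, model, rng):
        row = np.full((model.layout.n_individuals, model.layout.K), 0.2)
        sample = _sample_from_b(model, row[None, :, :])
        cov = model.observations[0].covariates
        x1, g1, _ = generate_individual(sample, cov, rng)
        x2, g2, _ = generate_individual(sample, cov, rng)
        np.testing.assert_allclose(x1, x2, atol=1e-12)
        a, c, d = model.covariate_scaling(cov)
        expected = a * sample.M[0] + c + d * sample.S[0] * 0.2
        np.testing.assert_allclose(x1, expected, atol=1e-10)

    def test_generated_moments_match_component(self, model, rng):
        # one component with independent effects: generated draws must
        # reproduce its mean and covariance within Monte-Carlo error
        names = model.priors.names
        k1, k2 = names.index(PAIR[0]), names.index(PAIR[1])
        R = {PAIR: 0.8}
        sample = make_synthetic_posterior(model, R, Z=1,
                                          rng=np.random.default_rng(0))
        n = 8000
        X, _G, _z = generate_population(
            sample, model.observations[0].covariates, n, rng)
        b = extract_random_effects(sample)
        bbar, sigma = fit_dependency_mixture(b)
        a, c, d = model.covariate_scaling(model.observations[0].covariates)
        mu = a * sample.M[0] + c + d * sample.S[0] * bbar[0]
        sd = d * sample.S[0] * np.sqrt(np.diag(sigma[0]))
        for k in (k1, k2):
            se = sd[k] / np.sqrt(n)
            assert X[:, k].mean() == pytest.approx(mu[k], abs=4 * se)
        r = np.corrcoef(X[:, k1], X[:, k2])[0, 1]
        assert r == pytest.approx(np.corrcoef(
            b[0, :, k1], b[0, :, k2])[0, 1], abs=0.05)

    def test_rank_deficient_covariance_still_generates(self, model, rng):
        # N=12 individuals, K=38: each component covariance has rank <= 11
        b = rng.standard_normal((3, model.layout.n_individuals,
                                 model.layout.K)) * 0.3
        sample = _sample_from_b(model, b)
        _bbar, sigma = fit_dependency_mixture(extract_random_effects(sample))
        assert np.linalg.matrix_rank(sigma[0], tol=1e-8) <= 11
        X, _G, _z = generate_population(
            sample, model.observations[0].covariates, 50, rng)
        assert np.all(np.isfinite(X))
        assert np.all(X >= model.priors.x_lower - 1e-12)
        assert np.all(X <= model.priors.x_upper + 1e-12)


class TestCorrelationAnalysis:
    def test_parameter_with_itself_is_unit_correlation(self, model, rng):
        b = rng.standard_normal((5, model.layout.n_individuals,
                                 model.layout.K)) * 0.3
        sample = _sample_from_b(model, b)
        res = correlation_analysis(sample, pairs=[("specCL", "specCL")])
        np.testing.assert_allclose(res[("specCL", "specCL")].values, 1.0,
                                   atol=1e-12)

    def test_independent_effects_not_significant(self, model):
        rng = np.random.default_rng(11)
        b = rng.standard_normal((200, model.layout.n_individuals,
                                 model.layout.K)) * 0.5
        sample = _sample_from_b(model, b)
        res = correlation_analysis(sample, pairs=[PAIR])[PAIR]
        se = 1.0 / np.sqrt(model.layout.n_individuals - 3)
        assert abs(np.arctanh(res.mean)) < 3 * se
        assert res.interval[0] < 0 < res.interval[1]

    def test_injected_negative_correlation_recovered(self, model):
        rng = np.random.default_rng(5)
        sample = make_synthetic_posterior(model, {PAIR: -0.7}, Z=200, rng=rng)
        res = correlation_analysis(sample, pairs=[PAIR])[PAIR]
        # sampling interval of a correlation estimate at n = 12
        se = 1.0 / np.sqrt(model.layout.n_individuals - 3)
        assert np.arctanh(res.mean) == pytest.approx(np.arctanh(-0.7),
                                                     abs=3 * se)
        assert res.significant
        assert res.p_value < 0.05

    def test_intraindividual_correlation_across_draws(self, model):
        rng = np.random.default_rng(9)
        sample = make_synthetic_posterior(model, {PAIR: 0.9}, Z=400, rng=rng)
        r = intraindividual_correlation(sample, 0, PAIR)
        assert 0.6 < r <= 1.0


class TestMarginalSummaries:
    def test_constant_sample(self):
        s = marginal_summaries(np.full(50, 3.3))
        assert s.geometric_mean == pytest.approx(3.3)
        assert s.cv == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_cv_identity(self, rng):
        # CV of a lognormal with log-SD 0.25 is sqrt(exp(0.0625) - 1)
        x = np.exp(rng.normal(0.0, 0.25, 200000))
        s = marginal_summaries(x)
        expected = np.sqrt(np.exp(0.0625) - 1)
        assert s.cv == pytest.approx(expected, rel=0.02)
        assert s.geometric_mean == pytest.approx(1.0, abs=0.01)

    def test_kde_integrates_to_one_on_truncated_support(self, rng):
        x = np.abs(rng.normal(1.0, 0.4, 2000)) + 0.1
        s = marginal_summaries(x, lower=0.1, upper=3.0)
        assert np.trapezoid(s.kde_density, s.kde_grid) == pytest.approx(
            1.0, abs=1e-3)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            marginal_summaries(np.array([1.0, -2.0]))
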