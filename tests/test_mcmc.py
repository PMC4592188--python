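"""Sampler machinery: truncated proposals, constrained volume moves,
conjugate oracles, diagnostics, thinning and determinism."""

import numpy as np
import pytest
from scipy import stats

from bayespbpk.mcmc import (
    Chain,
    PBPKSampler,
    SamplerConfig,
    adapt_proposals,
    gelman_rubin,
    mh_block_update,
    organ_volume_logq,
    run_generic_sampler,
    run_sampler,
    sample_organ_volumes,
    thin_subsample,
    truncnorm_sample,
)
from bayespbpk.pbpk import InvalidPhysiologyError


class TestTruncatedProposals:
    def test_samples_within_bounds_and_match_moments(self, rng):
        mu, sd, lo, hi = 1.0, 2.0, 0.0, 2.5
        x = truncnorm_sample(rng, np.full(20000, mu), sd, lo, hi)
        assert np.all((x >= lo) & (x <= hi))
        ref = stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
        assert x.mean() == pytest.approx(ref.mean(), abs=4 * ref.std()
                                         / np.sqrt(x.size))
        assert x.std() == pytest.approx(ref.std(), rel=0.05)

    def test_tiny_proposal_sd_accepts_almost_surely(self, rng):
        # SD -> 0 limit: the proposal equals the current state, ratio = 1
        logp = lambda v: float(-0.5 * v @ v)
        x = np.zeros(3)
        lp = logp(x)
        n_acc = 0
        for _ in range(200):
            x, lp, ok = mh_block_update(x, np.arange(3), logp,
                                        np.full(3, 1e-12), np.full(3, -5.0),
                                        np.full(3, 5.0), rng, lp)
            n_acc += ok
        assert n_acc == 200

    def test_symmetric_unbounded_proposal_reduces_to_posterior_ratio(self, rng):
        # with effectively unbounded symmetric proposals the Hastings
        # correction vanishes, so a flat target accepts everything
        logp = lambda v: 0.0
        x = np.zeros(2)
        lp = 0.0
        acc = 0
        for _ in range(300):
            x, lp, ok = mh_block_update(x, np.arange(2), logp, np.ones(2),
                                        np.full(2, -1e8), np.full(2, 1e8),
                                        rng, lp)
            acc += ok
        assert acc == 300

    def test_1d_truncated_normal_target_moments(self, rng):
        # standard normal truncated to [0, 2]: analytic moments
        logp = lambda v: float(-0.5 * v[0] ** 2) if 0 <= v[0] <= 2 else -np.inf
        samples, _ = run_generic_sampler(
            logp, np.array([1.0]), [np.array([0])], np.array([0.8]),
            np.array([0.0]), np.array([2.0]), 40000, rng)
        ref = stats.truncnorm(0.0, 2.0)
        x = samples[2000:, 0]
        ess = x.size / (1 + 2 * 5)  # conservative autocorrelation allowance
        se_mean = ref.std() / np.sqrt(ess)
        assert x.mean() == pytest.approx(ref.mean(), abs=3 * se_mean)
        assert x.var() == pytest.approx(ref.var(),
                                        abs=3 * ref.var() * np.sqrt(2 / ess))

    def test_nan_posterior_treated_as_minus_inf(self, rng):
        calls = {"n": 0}

        def logp(v):
            calls["n"] += 1
            return np.nan if calls["n"] > 1 else 0.0

        with pytest.warns(UserWarning, match="NaN"):
            _x, _lp, ok = mh_block_update(
                np.zeros(1), np.array([0]), logp, np.array([1.0]),
                np.array([-5.0]), np.array([5.0]), rng)
        assert not ok


class TestConjugateOracle:
    def test_block_sampler_recovers_analytic_posterior(self, rng):
        # normal hierarchy: y_ij ~ N(mu_i, 1), mu_i ~ N(M, 1), M ~ N(0, 10^2)
        # integrating mu out: ybar_i | M ~ N(M, 1 + 1/n); M | y is Gaussian
        N, n = 6, 4
        truth_rng = np.random.default_rng(7)
        mus = truth_rng.normal(2.0, 1.0, N)
        y = truth_rng.normal(mus[:, None], 1.0, (N, n))
        ybar = y.mean(axis=1)
        prec = 1 / 100.0 + N / (1.0 + 1.0 / n)
        post_var = 1.0 / prec
        post_mean = post_var * ybar.sum() / (1.0 + 1.0 / n)

        def logp(v):
            mu, M = v[:N], v[N]
            ll = -0.5 * np.sum((y - mu[:, None]) ** 2)
            lp = -0.5 * np.sum((mu - M) ** 2) - 0.5 * M ** 2 / 100.0
            return float(ll + lp)

        blocks = [np.array([i]) for i in range(N)] + [np.array([N])]
        x0 = np.zeros(N + 1)
        lo, hi = np.full(N + 1, -50.0), np.full(N + 1, 50.0)
        samples, acc = run_generic_sampler(logp, x0, blocks,
                                           np.full(N + 1, 0.8), lo, hi,
                                           20000, rng)
        M_draws = samples[2000:, N]
        ess = M_draws.size / 20  # conservative
        se = np.sqrt(post_var / ess)
        assert M_draws.mean() == pytest.approx(post_mean, abs=3 * se)
        assert M_draws.var() == pytest.approx(
            post_var, abs=3 * post_var * np.sqrt(2 / ess))
        assert all(0 < a < 1 for a in acc)


class TestOrganVolumeSampler:
    def test_two_organ_hand_enumerated_feasible_region(self, rng):
        # bounds A [0.5, 1.5], B [0.2, 1.0], BW = 2.0; by hand the feasible
        # region is A in [1.0, 1.5] with B the remainder
        lower = np.array([0.5, 0.2])
        upper = np.array([1.5, 1.0])
        cur = np.array([1.2, 0.8])
        for _ in range(500):
            cand, _lq = sample_organ_volumes(cur, lower, upper, 2.0,
                                             np.array([0.3, 0.3]), rng)
            assert cand.sum() == pytest.approx(2.0, abs=1e-12)
            assert 1.0 - 1e-12 <= cand[0] <= 1.5 + 1e-12
            assert 0.5 - 1e-12 <= cand[1] <= 1.0 + 1e-12

    def test_degenerate_bounds_return_exactly_bounds(self, rng):
        lower = upper = np.array([1.0, 2.0, 0.5])
        cand, lq = sample_organ_volumes(np.array([1.0, 2.0, 0.5]), lower,
                                        upper, 3.5, np.full(3, 0.1), rng)
        np.testing.assert_array_equal(cand, lower)
        assert lq == 0.0

    def test_many_draws_sum_and_bounds(self, rng):
        lower = np.array([0.5, 0.2, 0.1])
        upper = np.array([3.0, 2.0, 1.0])
        cur = np.array([1.5, 1.0, 0.5])
        bw = 3.0
        sd = np.full(3, 0.4)
        for _ in range(20000):
            cand, _ = sample_organ_volumes(cur, lower, upper, bw, sd, rng)
            assert abs(cand.sum() - bw) <= 1e-12 * bw
            assert np.all(cand >= lower - 1e-12)
            assert np.all(cand <= upper + 1e-12)
            cur = cand

    def test_infeasible_body_weight_raises(self, rng):
        with pytest.raises(InvalidPhysiologyError):
            sample_organ_volumes(np.array([1.0]), np.array([0.5]),
                                 np.array([1.5]), 99.0, np.array([0.1]), rng)

    def test_reverse_density_matches_forward_on_swap(self, rng):
        # q(a -> b) evaluated by the sweep equals the forward log density
        # returned when the draw is forced to b
        lower = np.array([0.5, 0.2, 0.1])
        upper = np.array([3.0, 2.0, 1.0])
        sd = np.full(3, 0.3)
        a, _ = sample_organ_volumes(np.array([1.5, 1.0, 0.5]), lower, upper,
                                    3.0, sd, rng)
        b, lq_fwd = sample_organ_volumes(a, lower, upper, 3.0, sd, rng)
        lq_eval = organ_volume_logq(b, a, lower, upper, 3.0, sd)
        assert lq_eval == pytest.approx(lq_fwd, rel=1e-12)

    def test_constrained_sampler_matches_rejection_sampling(self, rng):
        # 3-organ toy target: product of truncated normals restricted to the
        # sum constraint; MH with the sweep proposal vs rejection sampling
        lower = np.array([0.5, 0.2, 0.1])
        upper = np.array([3.0, 2.0, 1.0])
        mu = np.array([1.6, 1.1, 0.6])
        s = np.array([0.5, 0.4, 0.2])
        bw = 3.0
        sd = np.full(3, 0.35)

        def log_target(v):
            if np.any(v < lower) or np.any(v > upper):
                return -np.inf
            return float(-0.5 * np.sum(((v - mu) / s) ** 2))

        cur = np.array([1.5, 1.0, 0.5])
        lp = log_target(cur)
        draws = []
        for it in range(40000):
            cand, lq_f = sample_organ_volumes(cur, lower, upper, bw, sd, rng)
            lq_r = organ_volume_logq(cur, cand, lower, upper, bw, sd)
            lp_c = log_target(cand)
            if np.log(rng.random()) <= lp_c - lp + lq_r - lq_f:
                cur, lp = cand, lp_c
            draws.append(cur.copy())
        draws = np.asarray(draws[2000:])

        # rejection sampler: draw (v1, v2) ~ their truncated normals, set
        # v3 = bw - v1 - v2, accept w.p. proportional to N(v3; mu3, s3)
        m = 200000
        v1 = truncnorm_sample(rng, np.full(m, mu[0]), s[0], lower[0], upper[0])
        v2 = truncnorm_sample(rng, np.full(m, mu[1]), s[1], lower[1], upper[1])
        v3 = bw - v1 - v2
        w = np.exp(-0.5 * ((v3 - mu[2]) / s[2]) ** 2)
        keep = (v3 >= lower[2]) & (v3 <= upper[2]) & (rng.random(m) < w)
        ref = np.stack([v1[keep], v2[keep], v3[keep]], axis=1)
        assert ref.shape[0] > 5000
        ess = draws.shape[0] / 30  # conservative autocorrelation allowance
        for j in range(3):
            se = np.sqrt(ref[:, j].var() / ess + ref[:, j].var() / ref.shape[0])
            assert draws[:, j].mean() == pytest.approx(ref[:, j].mean(),
                                                       abs=3 * se)


class TestAdaptation:
    def test_constant_segment_floors_all_sds(self):
        seg = np.ones((10, 4))
        with pytest.warns(UserWarning, match="zero empirical"):
            prop = adapt_proposals(seg, 0.5, floor=1e-6)
        assert np.all(prop.sd == 1e-6)

    def test_known_sd_and_fraction(self):
        seg = np.array([[1.0], [3.0], [5.0]])  # ddof=1 sample SD = 2.0
        prop = adapt_proposals(seg, 0.5)
        assert prop.sd[0] == pytest.approx(1.0)

    def test_matches_independent_sd_computation(self, rng):
        seg = rng.standard_normal((500, 7)) * np.arange(1, 8)
        prop = adapt_proposals(seg, 0.3)
        np.testing.assert_allclose(prop.sd, 0.3 * seg.std(axis=0, ddof=1),
                                   rtol=1e-12)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            adapt_proposals(np.ones((1, 3)), 0.5)


class TestGelmanRubin:
    def test_identical_halves_give_unit_rhat(self, rng):
        half = rng.standard_normal(500)
        x = np.concatenate([half, half])
        assert gelman_rubin(x)[0] == pytest.approx(1.0, abs=0.05)

    def test_disjoint_supports_give_large_rhat(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert gelman_rubin(x)[0] > 10

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal((1000, 3)).cumsum(axis=0)
        rhat = gelman_rubin(x)
        # independent implementation of the split-chain formula
        for j in range(3):
            c1, c2 = x[:500, j], x[500:, j]
            W = 0.5 * (c1.var(ddof=1) + c2.var(ddof=1))
            B = 500 * np.var([c1.mean(), c2.mean()], ddof=1)
            expected = np.sqrt((499 / 500 * W + B / 500) / W)
            assert rhat[j] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_reported_as_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            r = gelman_rubin(np.ones(100))
        assert np.isnan(r[0])


class TestThinning:
    def _chain(self, rng, n=200, dim=3):
        states = rng.standard_normal((n, dim))
        return Chain(states=states, log_posterior=np.zeros(n), acceptance={},
                     burn_in=50)

    def test_full_subsample_is_permutation(self, rng):
        ch = self._chain(rng)
        states, idx = thin_subsample(ch, 150, rng)
        assert sorted(idx) == list(range(50, 200))
        np.testing.assert_array_equal(states, ch.states[idx])

    def test_single_draw_valid(self, rng):
        ch = self._chain(rng)
        states, idx = thin_subsample(ch, 1, rng)
        assert states.shape == (1, 3)
        assert 50 <= idx[0] < 200

    def test_oversized_request_raises(self, rng):
        with pytest.raises(ValueError):
            thin_subsample(self._chain(rng), 151, rng)

    def test_subsample_mean_close_to_chain_mean(self, rng):
        ch = self._chain(rng, n=4050)
        states, _ = thin_subsample(ch, 500, rng)
        post = ch.post_burn_in()
        se = post[:, 0].std() * np.sqrt(1 / 500 + 1 / post.shape[0])
        assert states[:, 0].mean() == pytest.approx(post[:, 0].mean(),
                                                    abs=3 * se)


class TestFullSampler:
    def test_zero_iterations_returns_initial_state_only(self, small_model):
        sampler = PBPKSampler(small_model, rng=3)
        chain = sampler.run(0)
        assert chain.states.shape[0] == 1
        np.testing.assert_array_equal(chain.states[0],
                                      small_model.initial_state())

    def test_fixed_seed_chains_are_bit_identical(self, small_model):
        cfg = SamplerConfig(n_iter=25, burn_in=5, pre_runs=(10,), seed=42)
        c1 = run_sampler(small_model, cfg)
        c2 = run_sampler(small_model, cfg)
        np.testing.assert_array_equal(c1.states, c2.states)
        assert c1.acceptance == c2.acceptance

    def test_chain_respects_constraints_and_bounds(self, small_model):
        chain = run_sampler(small_model, SamplerConfig(
            n_iter=30, burn_in=5, pre_runs=(), seed=0))
        lay = small_model.layout
        pr = small_model.priors
        vm = small_model.volume_mask
        for vec in chain.states[::10]:
            theta = lay.unpack(vec)[0]
            for i in range(lay.n_individuals):
                assert theta[i, vm].sum() == pytest.approx(
                    small_model.body_weights[i], rel=1e-9)
                assert np.all(theta[i] >= pr.x_lower - 1e-9)
                assert np.all(theta[i] <= pr.x_upper + 1e-9)

    def test_acceptance_rates_logged_and_nondegenerate(self, small_model):
        chain = run_sampler(small_model, SamplerConfig(
            n_iter=60, burn_in=10, pre_runs=(30,), seed=5))
        assert chain.acceptance  # per-block bookkeeping exists
        for name, rate in chain.acceptance.items():
            assert 0.0 <= rate <= 1.0

    def test_save_load_round_trip(self, small_model, tmp_path):
        chain = run_sampler(small_model, SamplerConfig(
            n_iter=10, burn_in=2, pre_runs=(), seed=0))
        path = tmp_path / "chain.h5"
        chain.save(path)
        back = Chain.load(path)
        np.testing.assert_array_equal(back.states, chain.states)
        assert back.burn_in == chain.burn_in
        assert back.acceptance == chain.acceptance
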