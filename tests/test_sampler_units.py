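"""Unit-level checks of the MCMC building blocks: each full-conditional or
MH step is tested against closed-form moments or conjugate algebra."""

import numpy as np
import pytest

from mugrm.bayesian_samplers import (
    ChainState,
    SamplerConfig,
    _propose_ordered,
    _truncated_normal,
    adapt_proposals,
    effective_sample_size,
    estimate_rho_cor,
    geweke_z,
    sample_augmented_Z,
    update_alpha,
    update_correlation,
    update_theta,
    update_thresholds_gibbs,
)
from mugrm.grm_core import TestDesign, TraitCorrelation
from mugrm.synthetic_data import StudyCondition, generate_dataset


def _state(theta, alpha, delta, rho=0.0, C=3):
    return ChainState(
        np.atleast_2d(np.asarray(theta, dtype=float)),
        np.asarray(alpha, dtype=float),
        np.atleast_2d(np.asarray(delta, dtype=float)),
        rho,
        C,
    )


class TestAugmentedZ:
    def test_positive_half_normal_moment(self, rng):
        # binary item, cut at 0, observed category 2, zero mean:
        # Z | Y=2 is half-normal with mean sqrt(2/pi)
        design = TestDesign(1, 1, [0], [2])
        state = _state(np.zeros((100_000, 1)), [1.0], [[0.0]], C=2)
        Y = np.full((100_000, 1), 2)
        Z = sample_augmented_Z(state, Y, design, rng)
        assert (Z > 0).all()
        assert Z.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_unbounded_interval_reduces_to_normal(self, rng):
        x = _truncated_normal(np.full(50_000, 1.5), 1.0, -np.inf, np.inf, rng)
        assert x.mean() == pytest.approx(1.5, abs=0.02)
        assert x.std() == pytest.approx(1.0, abs=0.02)

    def test_draws_respect_category_intervals(self, small_bundle, rng):
        b = small_bundle
        state = _state(
            b.theta, b.params.alpha, b.params.thresholds_matrix(), b.condition.rho
        )
        Z = sample_augmented_Z(state, b.Y, b.design, rng)
        D = state.padded()
        cols = np.arange(b.design.n_items)
        assert (Z > D[cols, b.Y - 1]).all()
        assert (Z < D[cols, b.Y]).all()

    def test_deterministic_given_seed(self, small_bundle):
        b = small_bundle
        draws = []
        for _ in range(2):
            state = _state(
                b.theta, b.params.alpha, b.params.thresholds_matrix(), b.condition.rho
            )
            draws.append(
                sample_augmented_Z(state, b.Y, b.design, np.random.default_rng(3))
            )
        np.testing.assert_array_equal(draws[0], draws[1])


class TestThetaConditional:
    def test_vanishing_slopes_recover_prior(self, rng):
        # alpha ~ 0: the full conditional is the N_2(0, P) prior
        design = TestDesign.simple_structure(4, 2, 3)
        P = TraitCorrelation.from_rho(0.6)
        state = _state(np.zeros((40_000, 2)), np.full(4, 1e-6), np.tile([-0.5, 0.5], (4, 1)), 0.6)
        state.Z = rng.normal(size=(40_000, 4))
        theta = update_theta(state, design, P, rng)
        emp = np.corrcoef(theta.T)[0, 1]
        assert emp == pytest.approx(0.6, abs=0.02)
        assert theta.std(axis=0) == pytest.approx([1.0, 1.0], abs=0.02)

    def test_single_item_conjugate_posterior(self, rng):
        # m=1, one item, alpha=1: posterior mean z/2, variance 1/2
        design = TestDesign(1, 1, [0], [3])
        z = 1.8
        state = _state(np.zeros((200_000, 1)), [1.0], [[-0.5, 0.5]], 0.0)
        state.Z = np.full((200_000, 1), z)
        theta = update_theta(state, design, TraitCorrelation(np.eye(1)), rng)
        assert theta.mean() == pytest.approx(z / 2, abs=0.01)
        assert theta.var() == pytest.approx(0.5, abs=0.01)

    def test_draw_covariance_matches_closed_form(self, small_bundle, rng):
        b = small_bundle
        P = TraitCorrelation.from_rho(0.5)
        state = _state(
            b.theta, b.params.alpha, b.params.thresholds_matrix(), 0.5
        )
        sample_augmented_Z(state, b.Y, b.design, rng)
        Z = state.Z
        d = [
            np.square(b.params.alpha[b.design.items_on(v)]).sum() for v in range(2)
        ]
        cov_expected = np.linalg.inv(np.linalg.inv(P.P) + np.diag(d))
        draws = np.empty((4000, 2))
        for k in range(4000):
            state.Z = Z
            state.theta = b.theta  # keep the conditional fixed
            draws[k] = update_theta(state, b.design, P, rng)[0]
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, cov_expected, atol=4 * np.abs(cov_expected).max() / np.sqrt(4000) * 3)


class TestAlphaConditional:
    def test_least_squares_form(self, rng):
        design = TestDesign(1, 1, [0], [3])
        state = _state(np.array([[1.0], [-1.0]]), [1.0], [[-0.5, 0.5]])
        Z = np.array([[1.0], [-1.0]])
        sample = []
        for _ in range(20_000):
            state.Z = Z
            sample.append(update_alpha(state, design, rng)[0])
            state.alpha = np.array([1.0])
        sample = np.array(sample)
        # truncated-at-zero normal with mean 1, var 1/2
        from scipy.stats import truncnorm

        sd = np.sqrt(0.5)
        tn = truncnorm(-1 / sd, np.inf, loc=1.0, scale=sd)
        assert (sample > 0).all()
        assert sample.mean() == pytest.approx(tn.mean(), abs=0.02)
        assert sample.std() == pytest.approx(tn.std(), abs=0.02)

    def test_concentrates_on_generating_slope(self, rng):
        # huge augmented dataset: conditional collapses onto the true alpha
        N, true_alpha = 100_000, 1.5
        design = TestDesign(1, 1, [0], [3])
        theta = rng.normal(size=(N, 1))
        state = _state(theta, [1.0], [[-0.5, 0.5]])
        state.Z = true_alpha * theta + rng.normal(size=(N, 1))
        a = update_alpha(state, design, rng)
        assert a[0] == pytest.approx(true_alpha, abs=0.02)


class TestThresholdUpdates:
    def test_gibbs_interval_definition(self, rng):
        # the uniform interval is (max Z in c, min Z in c+1)
        design = TestDesign(1, 1, [0], [2])
        state = _state(np.zeros((2, 1)), [1.0], [[0.05]], C=2)
        state.Z = np.array([[-0.2], [0.3]])
        Y = np.array([[1], [2]])
        draws = []
        for _ in range(2000):
            state.delta = np.array([[0.05]])
            draws.append(update_thresholds_gibbs(state, Y, rng)[0, 0])
        draws = np.array(draws)
        assert draws.min() > -0.2 and draws.max() < 0.3
        assert draws.mean() == pytest.approx(0.05, abs=0.01)

    def test_gibbs_preserves_ordering(self, small_bundle, rng):
        b = small_bundle
        state = _state(
            b.theta, b.params.alpha, b.params.thresholds_matrix(), b.condition.rho
        )
        for _ in range(50):
            sample_augmented_Z(state, b.Y, b.design, rng)
            update_thresholds_gibbs(state, b.Y, rng)
            assert (np.diff(state.delta, axis=1) > 0).all()

    def test_ordered_proposal_correction_vanishes_for_wide_scale_limit(self, rng):
        # with symmetric intervals the correction is finite and the
        # candidate stays ordered
        delta = np.array([[-0.5, 0.5], [0.0, 1.0]])
        cand, corr = _propose_ordered(delta, np.array([0.3, 0.3]), rng)
        assert (np.diff(cand, axis=1) > 0).all()
        assert np.isfinite(corr).all()

    def test_tiny_proposal_scale_accepts_almost_always(self, small_bundle, rng):
        b = small_bundle
        state = _state(
            b.theta, b.params.alpha, b.params.thresholds_matrix(), b.condition.rho
        )
        state.proposal_scales["thresh"] = np.full(b.design.n_items, 1e-5)
        from mugrm.bayesian_samplers import update_thresholds_cowles

        for _ in range(50):
            update_thresholds_cowles(state, b.Y, b.design, rng)
        rates = state.acceptance_counts["thresh"] / state.proposal_totals["thresh"]
        assert (rates > 0.95).all()


class TestCorrelationUpdate:
    def test_posterior_tracks_sample_correlation(self, rng):
        theta = np.random.default_rng(5).multivariate_normal(
            [0, 0], [[1, 0.8], [0.8, 1]], size=1000
        )
        state = _state(theta, [1.0], [[-0.5, 0.5]], rho=0.5)
        draws = [update_correlation(state, rng) for _ in range(4000)]
        post_mean = np.mean(draws[500:])
        emp = np.corrcoef(theta.T)[0, 1]
        assert post_mean == pytest.approx(emp, abs=0.05)

    def test_independent_traits_concentrate_near_zero(self, rng):
        theta = np.random.default_rng(6).normal(size=(5000, 2))
        state = _state(theta, [1.0], [[-0.5, 0.5]], rho=0.3)
        draws = [update_correlation(state, rng) for _ in range(3000)]
        assert abs(np.mean(draws[500:])) < 0.05


class TestAdaptationAndDiagnostics:
    def test_scale_moves_toward_target(self):
        cfg = SamplerConfig(n_iterations=100, burn_in=50, adapt_until=50)
        state = _state(np.zeros((2, 2)), [1.0, 1.0], [[-0.5, 0.5], [-0.5, 0.5]])
        state.iteration = 25
        state.batch_counts["thresh"] = np.array([25.0, 0.0])  # rates 1.0 and 0.0
        s0 = state.proposal_scales["thresh"].copy()
        adapt_proposals(state, cfg)
        assert state.proposal_scales["thresh"][0] > s0[0]  # too many accepts
        assert state.proposal_scales["thresh"][1] < s0[1]  # too few

    def test_adaptation_frozen_after_window(self):
        cfg = SamplerConfig(n_iterations=100, burn_in=50, adapt_until=50)
        state = _state(np.zeros((2, 2)), [1.0, 1.0], [[-0.5, 0.5], [-0.5, 0.5]])
        state.iteration = 75
        state.batch_counts["thresh"] = np.array([25.0, 25.0])
        s0 = state.proposal_scales["thresh"].copy()
        adapt_proposals(state, cfg)
        np.testing.assert_array_equal(state.proposal_scales["thresh"], s0)

    def test_realized_acceptance_near_target_on_toy_target(self):
        # adapted random walk on a standard normal reaches the target rate
        rng = np.random.default_rng(8)
        scale, x = 5.0, 0.0
        target = 0.4
        for batch in range(1, 60):
            acc = 0
            for _ in range(50):
                prop = x + scale * rng.standard_normal()
                if np.log(rng.uniform()) < 0.5 * (x * x - prop * prop):
                    x, acc = prop, acc + 1
            gain = min(0.5, 2.0 / np.sqrt(batch))
            scale *= np.exp(gain * (acc / 50 - target))
        acc = 0
        for _ in range(4000):
            prop = x + scale * rng.standard_normal()
            if np.log(rng.uniform()) < 0.5 * (x * x - prop * prop):
                x, acc = prop, acc + 1
        assert acc / 4000 == pytest.approx(target, abs=0.10)

    def test_ess_of_iid_draws_near_n(self, rng):
        x = rng.normal(size=2000)
        assert effective_sample_size(x) > 1200

    def test_ess_of_correlated_chain_much_smaller(self, rng):
        eps = rng.normal(size=2000)
        x = np.empty(2000)
        x[0] = 0
        for t in range(1, 2000):
            x[t] = 0.95 * x[t - 1] + eps[t]
        assert effective_sample_size(x) < 500

    def test_geweke_flags_drifting_chain(self, rng):
        stable = rng.normal(size=3000)
        drifting = stable + np.linspace(0, 3, 3000)
        assert abs(geweke_z(stable)) < 3
        assert abs(geweke_z(drifting)) > 5


class TestRhoCor:
    def test_duplicated_subscales_give_one(self):
        design = TestDesign.simple_structure(4, 2, 3)
        half = np.random.default_rng(0).integers(1, 4, size=(100, 2))
        Y = np.hstack([half, half])
        assert estimate_rho_cor(Y, design) == pytest.approx(1.0)

    def test_independent_responses_near_zero(self):
        design = TestDesign.simple_structure(20, 2, 3)
        Y = np.random.default_rng(1).integers(1, 4, size=(20_000, 20))
        assert abs(estimate_rho_cor(Y, design)) < 0.03

    def test_attenuated_below_generating_correlation(self):
        cond = StudyCondition(100_000, 20, 0.8, seed=19)
        b = generate_dataset(cond, 0)
        r = estimate_rho_cor(b.Y, b.design)
        assert 0.4 < r < 0.8
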