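"""MML-EM engine: quadrature accuracy, E-step bookkeeping, M-step ascent."""

import numpy as np
import pytest
from mugrm.grm_core import ItemParameters, TestDesign, category_probability
from mugrm.mml_baem import (
    EMConfig,
    EMState,
    _rho_m_step,
    build_grid,
    e_step,
    fit_baem,
    m_step_item,
    marginal_loglik,
)
from mugrm.synthetic_data import StudyCondition, generate_dataset


class TestQuadratureGrid:
    def test_integrates_bivariate_normal_moments(self):
        for rho in (0.0, 0.5, 0.8):
            g = build_grid(rho, 21)
            w = g.weights
            assert w.sum() == pytest.approx(1.0)
            assert (w > 0).all()
            assert w @ g.nodes[:, 0] == pytest.approx(0.0, abs=1e-12)
            assert w @ np.square(g.nodes[:, 0]) == pytest.approx(1.0)
            assert w @ np.square(g.nodes[:, 1]) == pytest.approx(1.0)
            assert w @ (g.nodes[:, 0] * g.nodes[:, 1]) == pytest.approx(rho)

    def test_integrates_higher_even_moment(self):
        g = build_grid(0.3, 21)
        assert g.weights @ g.nodes[:, 0] ** 4 == pytest.approx(3.0)


class TestMarginalLoglik:
    def test_zero_slope_reduces_to_multinomial(self):
        # traits drop out: the marginal equals the threshold-only multinomial
        design = TestDesign.simple_structure(2, 2, 3)
        params = ItemParameters(
            [1e-9, 1e-9], [np.array([-0.4, 0.6]), np.array([-0.2, 0.3])]
        )
        rng = np.random.default_rng(4)
        Y = rng.integers(1, 4, size=(200, 2))
        expected = 0.0
        for j in range(2):
            p = [category_probability(0.0, 0.001, params.thresholds[j], c) for c in (1, 2, 3)]
            counts = [(Y[:, j] == c).sum() for c in (1, 2, 3)]
            expected += sum(n * np.log(pc) for n, pc in zip(counts, p))
        for rho in (0.0, 0.7):
            got = marginal_loglik(Y, params, rho, design, grid_size=11)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_single_binary_item_closed_form(self):
        # alpha=1, delta=0 probit: marginal P(Y=2) = Phi(0 / sqrt(2)) = 1/2
        design = TestDesign(2, 2, [0, 1], [2, 2])
        params = ItemParameters([1.0, 1.0], [np.array([0.0]), np.array([0.0])])
        Y = np.array([[2, 1]] * 50)
        ll = marginal_loglik(Y, params, 0.0, design, grid_size=31)
        assert ll == pytest.approx(100 * np.log(0.5), rel=1e-9)

    def test_grid_convergence_on_small_test(self):
        cond = StudyCondition(100, 4, 0.5, seed=3)
        b = generate_dataset(cond, 0)
        l21 = marginal_loglik(b.Y, b.params, 0.5, b.design, 21)
        l41 = marginal_loglik(b.Y, b.params, 0.5, b.design, 41)
        assert abs(l21 - l41) < 1e-5

    def test_agrees_with_monte_carlo_marginalisation(self):
        # independent oracle: average the conditional likelihood over a
        # large trait sample instead of quadrature
        cond = StudyCondition(50, 4, 0.6, seed=8)
        b = generate_dataset(cond, 0)
        rng = np.random.default_rng(9)
        L = np.linalg.cholesky([[1, 0.6], [0.6, 1]])
        theta = rng.standard_normal((200_000, 2)) @ L.T
        from mugrm.grm_core import response_logprob_matrix

        total = 0.0
        ses = []
        for i in range(b.Y.shape[0]):
            lp = response_logprob_matrix(
                np.tile(b.Y[i], (theta.shape[0], 1)), theta, b.params, b.design
            ).sum(axis=1)
            w = np.exp(lp)
            total += np.log(w.mean())
            ses.append(w.std() / (w.mean() * np.sqrt(w.size)))
        quad = marginal_loglik(b.Y, b.params, 0.6, b.design, 21)
        mc_se = np.sqrt(np.sum(np.square(ses)))
        assert abs(quad - total) < 3 * mc_se


class TestEStep:
    def _toy(self):
        cond = StudyCondition(50, 4, 0.5, seed=5)
        b = generate_dataset(cond, 0)
        state = EMState(b.params, 0.5, -np.inf, 0, np.inf)
        return b, state

    def test_counts_match_naive_bayes_oracle(self):
        b, state = self._toy()
        grid = build_grid(0.5, 7)
        rbar, nbar, ll = e_step(b.Y, state, grid, b.design)
        assert nbar.sum() == pytest.approx(b.Y.shape[0])
        # brute-force per-person posterior
        Q = grid.nodes.shape[0]
        rbar_oracle = np.zeros_like(rbar)
        for i in range(b.Y.shape[0]):
            lik = np.empty(Q)
            for q in range(Q):
                p = 1.0
                for j in range(4):
                    p *= category_probability(
                        grid.nodes[q, b.design.loading[j]],
                        b.params.alpha[j],
                        b.params.thresholds[j],
                        int(b.Y[i, j]),
                    )
                lik[q] = p * grid.weights[q]
            w = lik / lik.sum()
            for j in range(4):
                rbar_oracle[j, :, b.Y[i, j] - 1] += w
        np.testing.assert_allclose(rbar, rbar_oracle, atol=1e-10)

    def test_flat_likelihood_returns_prior_weights(self):
        design = TestDesign.simple_structure(2, 2, 3)
        params = ItemParameters(
            [1e-9, 1e-9], [np.array([-0.4305, 0.4307]), np.array([-0.4305, 0.4307])]
        )
        state = EMState(params, 0.3, -np.inf, 0, np.inf)
        grid = build_grid(0.3, 9)
        Y = np.array([[1, 2], [2, 3], [3, 1], [2, 2]])
        rbar, nbar, _ = e_step(Y, state, grid, design)
        np.testing.assert_allclose(nbar / nbar.sum(), grid.weights, atol=1e-6)


class TestMStep:
    def test_recovers_generating_values_from_exact_counts(self):
        # counts generated exactly at the parameters: the fixed point
        alpha, delta = 1.2, np.array([-0.5, 0.7])
        g = build_grid(0.0, 41, m=1)
        t = g.nodes[:, 0]
        probs = np.stack(
            [category_probability(t, alpha, delta, c) for c in (1, 2, 3)], axis=1
        )
        rbar = 1000 * g.weights[:, None] * probs
        a, d = m_step_item(rbar, t, 3, 1.0, np.array([-0.2, 0.2]), maxiter=200)
        assert a == pytest.approx(alpha, abs=1e-3)
        np.testing.assert_allclose(d, delta, atol=1e-3)

    def test_never_decreases_expected_loglik(self):
        rng = np.random.default_rng(11)
        g = build_grid(0.0, 15, m=1)
        t = g.nodes[:, 0]
        rbar = rng.uniform(0.1, 5.0, size=(15, 3))

        def expected_ll(a, d):
            p = np.stack(
                [category_probability(t, a, d, c) for c in (1, 2, 3)], axis=1
            )
            return (rbar * np.log(np.maximum(p, 1e-300))).sum()

        a0, d0 = 0.8, np.array([-0.1, 0.4])
        a1, d1 = m_step_item(rbar, t, 3, a0, d0)
        assert expected_ll(a1, d1) >= expected_ll(a0, d0) - 1e-9
        assert d1[0] < d1[1]


class TestRhoMStep:
    def test_matches_grid_search(self):
        for s11, s22, s12 in [(1.0, 1.0, 0.5), (1.2, 0.9, 0.7), (1.0, 1.0, -0.3)]:
            got = _rho_m_step(s11, s22, s12)
            grid = np.linspace(-0.995, 0.995, 4001)
            obj = -0.5 * np.log(1 - grid**2) - (s11 + s22 - 2 * grid * s12) / (
                2 * (1 - grid**2)
            )
            best = grid[np.argmax(obj)]
            assert got == pytest.approx(best, abs=1e-3)


class TestFitBaem:
    def test_recovery_and_ascent_on_moderate_dataset(self):
        cond = StudyCondition(2000, 20, 0.5, seed=23)
        b = generate_dataset(cond, 0)
        state = fit_baem(b.Y, b.design, EMConfig(tol=5e-4))
        assert abs(state.rho - 0.5) < 0.1
        assert np.corrcoef(state.params.alpha, b.params.alpha)[0, 1] > 0.9
        trace = np.array(state.trace)
        assert (np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1]))).all()

    def test_fixed_grid_trace_is_monotone_to_tight_tolerance(self):
        # with rho held fixed the grid never changes and EM ascent is exact
        cond = StudyCondition(300, 4, 0.5, seed=29)
        b = generate_dataset(cond, 0)
        state = fit_baem(
            b.Y, b.design, EMConfig(rho_mode="fixed", fixed_rho=0.5, max_cycles=80)
        )
        trace = np.array(state.trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_unobserved_category_rejected(self):
        design = TestDesign.simple_structure(2, 2, 3)
        Y = np.array([[1, 1], [2, 2], [1, 2], [2, 1]])  # category 3 never seen
        with pytest.raises(ValueError, match="unobserved"):
            fit_baem(Y, design)
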