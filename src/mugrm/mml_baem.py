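"""Marginal maximum likelihood for the multi-unidimensional GRM via the
Bock–Aitkin EM algorithm with a fixed Gauss–Hermite quadrature.

The traits are integrated out of the likelihood over a tensor-product
Gauss–Hermite grid rotated by the Cholesky factor of the trait correlation
matrix P, so the grid integrates the N_m(0, P) prior exactly for
polynomials up to the rule's degree.  The E-step turns each person's
posterior over nodes into expected per-(item, node, category) counts; the
M-step maximises each item's expected complete-data log-likelihood by
quasi-Newton ascent in an order-free parameterisation (log slope, first
cut-point, log gaps).  The intertrait correlation is re-estimated each
cycle by maximising the expected complete-data normal log-likelihood of
the traits (an exact one-dimensional M-step solved as a cubic), and the
grid is rebuilt whenever rho changes.

The quadrature marginal-likelihood evaluator is also what the AIC
criterion of the MH engine scores candidate correlations with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grm_core import (
    ItemParameters,
    Link,
    TestDesign,
    TraitCorrelation,
    link_cdf,
    padded_thresholds,
    validate_responses,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QuadratureGrid",
    "EMConfig",
    "EMState",
    "EMConvergenceError",
    "build_grid",
    "marginal_loglik",
    "e_step",
    "m_step_item",
    "fit_baem",
]


class EMConvergenceError(RuntimeError):
    """The marginal log-likelihood decreased beyond numerical tolerance."""


@dataclass(frozen=True)
class QuadratureGrid:
    """Tensor Gauss–Hermite grid adapted to the trait prior N_m(0, P)."""

    nodes: np.ndarray  # (Q, m)
    weights: np.ndarray  # (Q,), positive, sum to 1
    rho_used: float


def build_grid(rho: float, n_points: int = 21, m: int = 2) -> QuadratureGrid:
    """Probabilists' Gauss–Hermite rule per dimension, tensorised and
    rotated by chol(P) so node averages reproduce N_m(0, P) moments."""
    x, w = np.polynomial.hermite_e.hermegauss(n_points)
    w = w / w.sum()
    if m == 1:
        return QuadratureGrid(x[:, None], w, 0.0)
    grids = np.meshgrid(*([x] * m), indexing="ij")
    base = np.stack([g.ravel() for g in grids], axis=1)  # (Q, m)
    weights = np.ones(base.shape[0])
    for g in np.meshgrid(*([w] * m), indexing="ij"):
        weights = weights * g.ravel()
    P = TraitCorrelation.from_rho(rho, m)
    nodes = base @ P.cholesky().T
    return QuadratureGrid(nodes, weights / weights.sum(), float(rho))


@dataclass
class EMConfig:
    grid_size: int = 21
    max_cycles: int = 500
    tol: float = 1e-4  # max absolute parameter change
    link: Link = "probit"
    rho_mode: Literal["update", "fixed"] = "update"
    fixed_rho: Optional[float] = None
    m_step_maxiter: int = 15
    ascent_tol: float = 1e-6  # relative slack on the monotonicity guard


@dataclass
class EMState:
    params: ItemParameters
    rho: float
    marginal_loglik: float
    iteration: int
    max_param_change: float
    trace: list = field(default_factory=list)
    aic: float = np.nan
    converged: bool = False


# ---------------------------------------------------------------------------
# Likelihood over the grid
# ---------------------------------------------------------------------------


def _log_prob_table(
    params: ItemParameters, design: TestDesign, nodes: np.ndarray, link: Link
) -> np.ndarray:
    """log P(category | node) as a (Q, K, Cmax) table; impossible padded
    categories get -inf and are never indexed."""
    D = padded_thresholds(params, design.max_categories)
    eta = nodes[:, design.loading] * params.alpha  # (Q, K)
    F = link_cdf(eta[:, :, None] - D[None, :, :], link)  # (Q, K, Cmax+1)
    probs = F[:, :, :-1] - F[:, :, 1:]
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(probs, 1e-300))


def _response_onehot(Y: np.ndarray, design: TestDesign) -> np.ndarray:
    """(N, K * Cmax) one-hot encoding of the 1-based response matrix."""
    N, K = Y.shape
    C = design.max_categories
    onehot = np.zeros((N, K * C))
    flat = np.arange(K) * C + (Y - 1)
    onehot[np.arange(N)[:, None], flat] = 1.0
    return onehot


def _person_log_weights(
    onehot: np.ndarray, logtab: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """(N, Q) unnormalised posterior log-weights log w_q + sum_j log P."""
    Q = logtab.shape[0]
    L = onehot @ logtab.reshape(Q, -1).T  # (N, Q)
    return L + np.log(weights)[None, :]


def marginal_loglik(
    Y: np.ndarray,
    params: ItemParameters,
    rho: float,
    design: TestDesign,
    grid_size: int = 21,
    link: Link = "probit",
) -> float:
    """sum_i log sum_q w_q prod_j P(Y_ij | node_q), log-sum-exp guarded."""
    Y = validate_responses(Y, design)
    if grid_size < 2:
        raise ValueError("need at least 2 quadrature points per dimension")
    grid = build_grid(rho, grid_size, design.n_dims)
    logtab = _log_prob_table(params, design, grid.nodes, link)
    lw = _person_log_weights(_response_onehot(Y, design), logtab, grid.weights)
    return float(logsumexp(lw, axis=1).sum())


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def e_step(
    Y: np.ndarray,
    state: EMState,
    grid: QuadratureGrid,
    design: TestDesign,
    link: Link = "probit",
    onehot: Optional[np.ndarray] = None,
):
    """Posterior node weights per person, aggregated into expected
    category counts rbar (K, Q, Cmax) and node totals nbar (Q,).

    Returns ``(rbar, nbar, loglik)``; sum(nbar) equals the person count.
    """
    if onehot is None:
        onehot = _response_onehot(Y, design)
    logtab = _log_prob_table(state.params, design, grid.nodes, link)
    lw = _person_log_weights(onehot, logtab, grid.weights)
    norm = logsumexp(lw, axis=1, keepdims=True)
    post = np.exp(lw - norm)  # (N, Q)
    nbar = post.sum(axis=0)
    K = design.n_items
    C = design.max_categories
    rbar = (onehot.T @ post).reshape(K, C, post.shape[1]).transpose(0, 2, 1)
    return rbar, nbar, float(norm.sum())


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    alpha = float(np.exp(x[0]))
    delta = np.empty(x.size - 1)
    delta[0] = x[1]
    if x.size > 2:
        delta[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    return alpha, delta


def _pack(alpha: float, delta: np.ndarray) -> np.ndarray:
    x = np.empty(delta.size + 1)
    x[0] = np.log(alpha)
    x[1] = delta[0]
    if delta.size > 1:
        x[2:] = np.log(np.maximum(np.diff(delta), 1e-8))
    return x


def m_step_item(
    rbar_j: np.ndarray,
    t: np.ndarray,
    n_cat: int,
    alpha0: float,
    delta0: np.ndarray,
    link: Link = "probit",
    maxiter: int = 15,
) -> tuple[float, np.ndarray]:
    """Maximise one item's expected complete-data log-likelihood
    sum_{q,c} rbar[q,c] log P_c(alpha, delta; t_q).

    ``t`` is the grid's coordinate on the item's own dimension.  The search
    runs in (log alpha, delta_1, log gaps), which keeps alpha positive and
    the cut-points strictly ordered by construction; the step is rejected
    if the optimiser fails to improve, so each cycle is a generalised-EM
    ascent.
    """
    r = rbar_j[:, :n_cat]

    def negloglik(x: np.ndarray) -> float:
        alpha, delta = _unpack(x)
        bounds = np.concatenate(([-np.inf], delta, [np.inf]))
        F = link_cdf(alpha * t[:, None] - bounds[None, :], link)
        probs = np.maximum(F[:, :-1] - F[:, 1:], 1e-300)
        return -float((r * np.log(probs)).sum())

    x0 = _pack(alpha0, delta0)
    f0 = negloglik(x0)
    res = minimize(negloglik, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    if not np.isfinite(res.fun) or res.fun > f0:
        return alpha0, delta0.copy()
    return _unpack(res.x)


def _rho_m_step(s11: float, s22: float, s12: float) -> float:
    """Exact M-step for the free correlation of a bivariate normal with
    unit variances: stationary points of the expected log-likelihood solve
    -rho^3 + s12 rho^2 + (1 - s11 - s22) rho + s12 = 0."""

    def objective(r: float) -> float:
        one = 1.0 - r * r
        return -0.5 * np.log(one) - (s11 + s22 - 2.0 * r * s12) / (2.0 * one)

    roots = np.roots([-1.0, s12, 1.0 - s11 - s22, s12])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and abs(r.real) < 0.999]
    if not real:
        return float(np.clip(s12 / np.sqrt(s11 * s22), -0.99, 0.99))
    return max(real, key=objective)


# ---------------------------------------------------------------------------
# Full EM fit
# ---------------------------------------------------------------------------


def fit_baem(
    Y: np.ndarray,
    design: TestDesign,
    config: EMConfig | None = None,
) -> EMState:
    """Bock–Aitkin MML-EM fit of item parameters and (optionally) the
    intertrait correlation.

    Alternates the quadrature E-step with per-item M-steps, re-estimates
    rho from the expected posterior trait cross-moments each cycle, and
    stops when the largest parameter change falls below ``config.tol`` or
    after ``config.max_cycles`` cycles.  Raises
    :class:`EMConvergenceError` if the marginal log-likelihood decreases
    beyond tolerance.
    """
    config = config or EMConfig()
    Y = validate_responses(Y, design)
    for j in range(design.n_items):
        if np.unique(Y[:, j]).size < design.n_categories[j]:
            raise ValueError(f"item {j} has an unobserved category")

    # starting values: unit slopes, cut-points at observed-frequency quantiles
    from scipy.special import ndtri

    C = design.n_categories
    thresholds = []
    for j in range(design.n_items):
        cum = np.array([(Y[:, j] <= c).mean() for c in range(1, C[j])])
        d = ndtri(np.clip(cum, 1e-3, 1 - 1e-3))
        for c in range(1, d.size):
            d[c] = max(d[c], d[c - 1] + 1e-3)
        thresholds.append(d)
    params = ItemParameters(np.ones(design.n_items), thresholds)

    if config.rho_mode == "fixed":
        if config.fixed_rho is None:
            raise ValueError("rho_mode='fixed' requires fixed_rho")
        rho = float(config.fixed_rho)
    elif design.n_dims == 2:
        from .bayesian_samplers import estimate_rho_cor

        rho = float(np.clip(estimate_rho_cor(Y, design), -0.9, 0.9))
    else:
        rho = 0.0

    onehot = _response_onehot(Y, design)
    state = EMState(params, rho, -np.inf, 0, np.inf)
    grid = build_grid(rho, config.grid_size, design.n_dims)
    prev_ll = -np.inf
    for cycle in range(1, config.max_cycles + 1):
        rbar, nbar, ll = e_step(Y, state, grid, design, config.link, onehot)
        if ll < prev_ll - config.ascent_tol * (1.0 + abs(prev_ll)):
            raise EMConvergenceError(
                f"marginal log-likelihood decreased at cycle {cycle}: "
                f"{prev_ll:.6f} -> {ll:.6f}; trace={state.trace}"
            )
        state.trace.append(ll)
        prev_ll = ll

        max_change = 0.0
        new_alpha = state.params.alpha.copy()
        new_thresholds = [t.copy() for t in state.params.thresholds]
        for j in range(design.n_items):
            t = grid.nodes[:, design.loading[j]]
            a, d = m_step_item(
                rbar[j],
                t,
                int(C[j]),
                state.params.alpha[j],
                state.params.thresholds[j],
                config.link,
                config.m_step_maxiter,
            )
            max_change = max(
                max_change,
                abs(a - state.params.alpha[j]),
                float(np.max(np.abs(d - state.params.thresholds[j]))),
            )
            new_alpha[j] = a
            new_thresholds[j] = d
        state.params = ItemParameters(new_alpha, new_thresholds)

        if config.rho_mode == "update" and design.n_dims == 2:
            w = nbar / nbar.sum()
            s11 = float(w @ np.square(grid.nodes[:, 0]))
            s22 = float(w @ np.square(grid.nodes[:, 1]))
            s12 = float(w @ (grid.nodes[:, 0] * grid.nodes[:, 1]))
            new_rho = _rho_m_step(s11, s22, s12)
            max_change = max(max_change, abs(new_rho - state.rho))
            if new_rho != state.rho:
                state.rho = new_rho
                grid = build_grid(state.rho, config.grid_size, design.n_dims)

        state.iteration = cycle
        state.max_param_change = max_change
        state.marginal_loglik = ll
        if max_change < config.tol:
            state.converged = True
            break

    # final likelihood at the converged parameters
    state.marginal_loglik = marginal_loglik(
        Y, state.params, state.rho, design, config.grid_size, config.link
    )
    state.trace.append(state.marginal_loglik)
    n_item_params = int(design.n_categories.sum())
    state.aic = -2.0 * state.marginal_loglik + 2.0 * n_item_params
    if not state.converged:
        logger.warning("EM hit max_cycles=%d without converging", config.max_cycles)
    return state
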