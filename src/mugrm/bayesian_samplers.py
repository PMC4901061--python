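"""Fully Bayesian estimation of the multi-unidimensional GRM.

Three MCMC engines share one posterior (probit link, flat priors on the
positive discriminations and on the ordered thresholds, N_m(0, P) prior on
the traits with P a correlation matrix):

* ``run_gibbs`` — data-augmentation Gibbs sampling in the Albert–Chib style:
  continuous latent responses Z_ij ~ N(alpha_j * theta_vi, 1) truncated to
  the observed category's threshold interval make every full conditional a
  standard distribution; thresholds are drawn uniformly on the interval the
  augmented data leave free.
* ``run_hwg`` — Hastings-within-Gibbs in the Cowles style: identical to the
  Gibbs engine except thresholds are updated by a Metropolis–Hastings step
  targeting the observed-data likelihood (Z integrated out), with an
  order-preserving truncated-normal proposal.  This decouples the threshold
  moves from the extremes of Z and mixes much faster.
* ``run_mh`` — blocked random-walk Metropolis–Hastings without augmentation
  (Patz–Junker style): person blocks theta_i and item blocks (alpha_j,
  delta_j) with order-preserving threshold proposals.  The intertrait
  correlation is either fixed by one of three criteria — TRUE (the known
  generating value), COR (sum-score correlation of the subscales), AIC
  (grid search minimising AIC with the quadrature marginal likelihood) —
  or sampled, which realises the blocked-Metropolis (BM) arm.

Proposal scales adapt multiplicatively toward target acceptance rates
during burn-in only, so the post-burn-in chain is a fixed Markov kernel.

Identification: trait location/scale are fixed by the N_m(0, P) prior with
unit variances; axis reflection by alpha > 0.  Point estimates are
posterior means (EAP).  The samplers require a homogeneous category count
across items (the heterogeneous case is supported by the core model and
the EM engine).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .grm_core import (
    ItemParameters,
    TestDesign,
    TraitCorrelation,
    validate_responses,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "ChainState",
    "PosteriorSummary",
    "DivergenceError",
    "InvariantViolationError",
    "sample_augmented_Z",
    "update_theta",
    "update_alpha",
    "update_thresholds_gibbs",
    "update_thresholds_cowles",
    "update_correlation",
    "adapt_proposals",
    "run_gibbs",
    "run_hwg",
    "run_mh",
    "estimate_rho_cor",
    "select_rho_aic",
    "effective_sample_size",
    "geweke_z",
]


class DivergenceError(RuntimeError):
    """A sampler state became non-finite."""


class InvariantViolationError(RuntimeError):
    """A chain invariant (threshold ordering, alpha positivity, truncation
    consistency) was violated."""


# ---------------------------------------------------------------------------
# Configuration and state
# ---------------------------------------------------------------------------


@dataclass
class SamplerConfig:
    """Chain-length, adaptation and seeding knobs shared by all engines."""

    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    target_acceptance: float = 0.40  # item / threshold / correlation blocks
    target_acceptance_person: float = 0.25  # multivariate person blocks
    adapt_until: Optional[int] = None  # defaults to burn_in
    adapt_batch: int = 25
    seed: int = 0
    rho_mode: Literal["sampled", "fixed"] = "sampled"
    fixed_rho: Optional[float] = None
    store_chains: bool = False
    validate: bool = True

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.adapt_until is None:
            self.adapt_until = self.burn_in
        if self.adapt_until > self.burn_in:
            raise ValueError("adaptation must stop at or before burn_in")
        if self.rho_mode == "fixed" and self.fixed_rho is None:
            raise ValueError("rho_mode='fixed' requires fixed_rho")


class ChainState:
    """Mutable MCMC state: augmented data, traits, item parameters, rho,
    and per-block proposal scales / acceptance counters."""

    def __init__(
        self,
        theta: np.ndarray,
        alpha: np.ndarray,
        delta: np.ndarray,
        rho: float,
        n_categories: int,
    ) -> None:
        self.theta = theta
        self.alpha = alpha
        self.delta = delta  # (K, C-1), strictly increasing rows
        self.rho = float(rho)
        self.n_categories = int(n_categories)
        self.Z: Optional[np.ndarray] = None
        K = alpha.shape[0]
        self.proposal_scales = {
            "thresh": np.full(K, 0.1),
            "alpha": np.full(K, 0.1),
            "person": 0.5,
            "rho": 0.2,
        }
        self.acceptance_counts = {
            "thresh": np.zeros(K),
            "alpha": np.zeros(K),
            "person": 0.0,
            "rho": 0.0,
        }
        self.batch_counts = {
            "thresh": np.zeros(K),
            "alpha": np.zeros(K),
            "person": 0.0,
            "rho": 0.0,
        }
        self.proposal_totals = {"thresh": 0, "alpha": 0, "person": 0, "rho": 0}
        self.iteration = 0

    # -- threshold boundary table ------------------------------------------
    def padded(self) -> np.ndarray:
        K, Cm1 = self.delta.shape
        D = np.empty((K, Cm1 + 2))
        D[:, 0] = -np.inf
        D[:, 1:-1] = self.delta
        D[:, -1] = np.inf
        return D

    def correlation(self) -> TraitCorrelation:
        return TraitCorrelation.from_rho(self.rho, self.theta.shape[1])

    def check_invariants(self) -> None:
        if (self.alpha <= 0).any():
            raise InvariantViolationError("alpha left the positive half-line")
        if (np.diff(self.delta, axis=1) <= 0).any():
            raise InvariantViolationError("threshold ordering broken")
        if not (
            np.isfinite(self.alpha).all()
            and np.isfinite(self.delta).all()
            and np.isfinite(self.theta).all()
        ):
            raise DivergenceError(f"non-finite state at iteration {self.iteration}")


# ---------------------------------------------------------------------------
# Numerics: truncated-normal draws, chain diagnostics
# ---------------------------------------------------------------------------

_TINY = 1e-14


def _truncated_normal(
    mean: np.ndarray,
    sd: np.ndarray | float,
    lower: np.ndarray | float,
    upper: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised inverse-CDF sampling of N(mean, sd^2) on (lower, upper),
    with tail guards that keep draws strictly inside finite bounds."""
    a = ndtr((lower - mean) / sd)
    b = ndtr((upper - mean) / sd)
    u = a + rng.uniform(size=np.broadcast_shapes(np.shape(mean), np.shape(a))) * (b - a)
    x = mean + sd * ndtri(np.clip(u, _TINY, 1.0 - _TINY))
    # deep-tail draws can collapse onto a bound; nudge back inside
    lo = np.broadcast_to(np.asarray(lower, dtype=float), x.shape)
    hi = np.broadcast_to(np.asarray(upper, dtype=float), x.shape)
    bad = ~((x > lo) & (x < hi))
    if bad.any():
        mid = np.where(
            np.isfinite(lo) & np.isfinite(hi),
            0.5 * (lo + hi),
            np.where(np.isfinite(lo), lo + 1e-6, hi - 1e-6),
        )
        x = np.where(bad, mid, x)
    return x


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence (capped at the draw count)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8 or np.var(x) < 1e-300:
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]
    # pair sums Gamma_k = rho_{2k} + rho_{2k+1}; stop at the first negative
    tau = -1.0
    for k in range(0, n // 2):
        g = rho[2 * k] + (rho[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if g < 0:
            break
        tau += 2.0 * g
    tau = max(tau, 1.0 / n)
    return float(min(n, n / tau))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means,
    with ESS-adjusted standard errors."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        return 0.0
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)) :]
    va = np.var(a, ddof=1) / max(effective_sample_size(a), 1.0)
    vb = np.var(b, ddof=1) / max(effective_sample_size(b), 1.0)
    denom = np.sqrt(va + vb)
    if denom < 1e-300:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


# ---------------------------------------------------------------------------
# Shared likelihood pieces (probit only: augmentation requires it)
# ---------------------------------------------------------------------------


def _item_loglik_rows(
    Y: np.ndarray, eta: np.ndarray, D: np.ndarray
) -> np.ndarray:
    """Per-(person, item) observed-data log-probability, probit link."""
    cols = np.arange(Y.shape[1])
    prob = ndtr(eta - D[cols, Y - 1]) - ndtr(eta - D[cols, Y])
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(prob, 1e-300))


# ---------------------------------------------------------------------------
# Full-conditional updates (Gibbs / HwG)
# ---------------------------------------------------------------------------


def sample_augmented_Z(
    state: ChainState, Y: np.ndarray, design: TestDesign, rng: np.random.Generator
) -> np.ndarray:
    """Draw Z_ij ~ N(alpha_j theta_vi, 1) truncated to the observed
    category's interval (delta_{j,c-1}, delta_{j,c})."""
    D = state.padded()
    cols = np.arange(design.n_items)
    lower = D[cols, Y - 1]
    upper = D[cols, Y]
    if not (lower < upper).all():
        raise InvariantViolationError("empty truncation interval for Z")
    mu = state.theta[:, design.loading] * state.alpha
    state.Z = _truncated_normal(mu, 1.0, lower, upper, rng)
    return state.Z


def update_theta(
    state: ChainState,
    design: TestDesign,
    P: TraitCorrelation,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact multivariate-normal full conditional for every person's traits.

    Under simple structure A^T A is diagonal, so the conditional precision
    P^-1 + A^T A and covariance are shared across persons.
    """
    m = P.m
    d = np.zeros(m)
    for v in range(m):
        idx = design.items_on(v)
        d[v] = np.square(state.alpha[idx]).sum()
    prec = np.linalg.inv(P.P) + np.diag(d)
    cov = np.linalg.inv(prec)
    ZA = np.empty((state.Z.shape[0], m))
    for v in range(m):
        idx = design.items_on(v)
        ZA[:, v] = state.Z[:, idx] @ state.alpha[idx]
    mean = ZA @ cov  # cov is symmetric
    L = np.linalg.cholesky(cov)
    state.theta = mean + rng.standard_normal(mean.shape) @ L.T
    return state.theta


def update_alpha(
    state: ChainState, design: TestDesign, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal full conditional on (0, inf) under a flat prior:
    the least-squares regression of Z_j on the item's own trait column."""
    th = state.theta[:, design.loading]  # (N, K)
    den = np.square(th).sum(axis=0)
    if (den <= 0).any():
        raise InvariantViolationError("degenerate trait column in alpha update")
    mean = (th * state.Z).sum(axis=0) / den
    sd = 1.0 / np.sqrt(den)
    state.alpha = _truncated_normal(mean, sd, 0.0, np.inf, rng)
    return state.alpha


def update_thresholds_gibbs(
    state: ChainState, Y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform full conditional: delta_{j,c} lies between the largest Z in
    category c and the smallest Z in category c+1 (clipped by neighbours)."""
    Z = state.Z
    C = state.n_categories
    D = state.padded()
    for c in range(1, C):
        below = np.where(Y == c, Z, -np.inf).max(axis=0)
        above = np.where(Y == c + 1, Z, np.inf).min(axis=0)
        lo = np.maximum(below, D[:, c - 1])
        hi = np.minimum(above, D[:, c + 1])
        if not (lo < hi).all():
            raise InvariantViolationError("empty threshold interval")
        D[:, c] = lo + rng.uniform(size=lo.shape) * (hi - lo)
    state.delta = D[:, 1:-1]
    return state.delta


def _propose_ordered(
    delta: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential order-preserving truncated-normal proposal (Cowles).

    Candidate delta*_c ~ N(delta_c, sigma^2) truncated to
    (delta*_{c-1}, delta_{c+1}).  Returns the candidate matrix and the log
    proposal-normaliser correction log q(old|new) - log q(new|old).
    """
    K, Cm1 = delta.shape
    cand = np.empty_like(delta)
    log_corr = np.zeros(K)
    for c in range(Cm1):
        lower = cand[:, c - 1] if c > 0 else np.full(K, -np.inf)
        upper = delta[:, c + 1] if c + 1 < Cm1 else np.full(K, np.inf)
        cand[:, c] = _truncated_normal(delta[:, c], sigma, lower, upper, rng)
        # forward normaliser: Phi((delta_{c+1}-delta_c)/s) - Phi((cand_{c-1}-delta_c)/s)
        fwd = ndtr((upper - delta[:, c]) / sigma) - ndtr((lower - delta[:, c]) / sigma)
        rev_upper = cand[:, c + 1] if c + 1 < Cm1 else np.full(K, np.inf)
        rev_lower = delta[:, c - 1] if c > 0 else np.full(K, -np.inf)
        rev = ndtr((rev_upper - cand[:, c]) / sigma) - ndtr((rev_lower - cand[:, c]) / sigma)
        log_corr += np.log(np.maximum(fwd, _TINY)) - np.log(np.maximum(rev, _TINY))
    return cand, log_corr


def _padded_from_delta(delta: np.ndarray) -> np.ndarray:
    K, Cm1 = delta.shape
    D = np.empty((K, Cm1 + 2))
    D[:, 0] = -np.inf
    D[:, 1:-1] = delta
    D[:, -1] = np.inf
    return D


def update_thresholds_cowles(
    state: ChainState,
    Y: np.ndarray,
    design: TestDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cowles MH threshold step: accept each item's candidate cut-points
    jointly with the observed-data (Z marginalised) likelihood ratio times
    the truncated-proposal correction.  Z is redrawn consistently at the
    next augmentation step."""
    sigma = state.proposal_scales["thresh"]
    cand, log_corr = _propose_ordered(state.delta, sigma, rng)
    eta = state.theta[:, design.loading] * state.alpha
    ll_cur = _item_loglik_rows(Y, eta, state.padded()).sum(axis=0)
    ll_new = _item_loglik_rows(Y, eta, _padded_from_delta(cand)).sum(axis=0)
    log_ratio = ll_new - ll_cur + log_corr
    accept = np.log(rng.uniform(size=log_ratio.shape)) < log_ratio
    state.delta = np.where(accept[:, None], cand, state.delta)
    state.acceptance_counts["thresh"] += accept
    state.batch_counts["thresh"] += accept
    state.proposal_totals["thresh"] += 1
    return state.delta


def update_correlation(state: ChainState, rng: np.random.Generator) -> float:
    """Random-walk MH on Fisher-z(rho), flat prior on rho in (-1, 1).

    The target is the bivariate-normal density of the current traits; the
    Jacobian (1 - rho^2) of the z-transform enters the ratio because the
    proposal is symmetric on the z scale."""
    th = state.theta
    if th.shape[1] != 2:
        raise NotImplementedError("correlation sampling implemented for m = 2")
    n = th.shape[0]
    s11 = float(np.square(th[:, 0]).sum())
    s22 = float(np.square(th[:, 1]).sum())
    s12 = float((th[:, 0] * th[:, 1]).sum())

    def loglik(r: float) -> float:
        one = 1.0 - r * r
        return -0.5 * n * np.log(one) - (s11 - 2.0 * r * s12 + s22) / (2.0 * one)

    z = np.arctanh(state.rho)
    z_new = z + state.proposal_scales["rho"] * rng.standard_normal()
    r_new = float(np.tanh(z_new))
    log_ratio = (
        loglik(r_new)
        - loglik(state.rho)
        + np.log1p(-r_new * r_new)
        - np.log1p(-state.rho * state.rho)
    )
    if np.log(rng.uniform()) < log_ratio:
        state.rho = r_new
        state.acceptance_counts["rho"] += 1
        state.batch_counts["rho"] += 1
    state.proposal_totals["rho"] += 1
    return state.rho


def adapt_proposals(state: ChainState, config: SamplerConfig) -> None:
    """Robbins–Monro-style multiplicative scale adaptation toward the target
    acceptance rates; called every ``adapt_batch`` iterations during the
    adaptation window and frozen afterwards."""
    if state.iteration > config.adapt_until:
        return
    batch_idx = max(1, state.iteration // config.adapt_batch)
    gain = min(0.5, 2.0 / np.sqrt(batch_idx))
    nb = config.adapt_batch
    for block in ("thresh", "alpha"):
        rate = state.batch_counts[block] / nb
        state.proposal_scales[block] = np.clip(
            state.proposal_scales[block]
            * np.exp(gain * (rate - config.target_acceptance)),
            1e-4,
            10.0,
        )
        state.batch_counts[block] = np.zeros_like(state.batch_counts[block])
    rate = state.batch_counts["person"] / nb
    state.proposal_scales["person"] = float(
        np.clip(
            state.proposal_scales["person"]
            * np.exp(gain * (rate - config.target_acceptance_person)),
            1e-4,
            10.0,
        )
    )
    state.batch_counts["person"] = 0.0
    rate = state.batch_counts["rho"] / nb
    state.proposal_scales["rho"] = float(
        np.clip(
            state.proposal_scales["rho"]
            * np.exp(gain * (rate - config.target_acceptance)),
            1e-4,
            10.0,
        )
    )
    state.batch_counts["rho"] = 0.0


# ---------------------------------------------------------------------------
# Blocked Metropolis updates (no augmentation)
# ---------------------------------------------------------------------------


def _update_persons_mh(
    state: ChainState,
    Y: np.ndarray,
    design: TestDesign,
    Pinv: np.ndarray,
    ll_mat: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-walk update of every person's trait vector; ``ll_mat`` is the
    cached per-(person, item) log-likelihood at the current state and is
    returned updated in place for accepted rows."""
    th = state.theta
    scale = state.proposal_scales["person"]
    cand = th + scale * rng.standard_normal(th.shape)
    D = state.padded()
    ll_new_mat = _item_loglik_rows(Y, cand[:, design.loading] * state.alpha, D)
    lp_cur = -0.5 * np.einsum("ij,jk,ik->i", th, Pinv, th)
    lp_new = -0.5 * np.einsum("ij,jk,ik->i", cand, Pinv, cand)
    log_ratio = ll_new_mat.sum(axis=1) - ll_mat.sum(axis=1) + lp_new - lp_cur
    accept = np.log(rng.uniform(size=th.shape[0])) < log_ratio
    state.theta = np.where(accept[:, None], cand, th)
    ll_mat[accept] = ll_new_mat[accept]
    rate = accept.mean()
    state.acceptance_counts["person"] += rate
    state.batch_counts["person"] += rate
    state.proposal_totals["person"] += 1
    return ll_mat


def _update_items_mh(
    state: ChainState,
    Y: np.ndarray,
    design: TestDesign,
    ll_mat: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Joint (alpha_j, delta_j) block per item: symmetric normal walk on
    alpha (candidates <= 0 rejected by the flat positive prior) and an
    order-preserving Cowles proposal on the thresholds.  Updates the cached
    log-likelihood columns of accepted items."""
    alpha_cand = state.alpha + state.proposal_scales["alpha"] * rng.standard_normal(
        state.alpha.shape
    )
    delta_cand, log_corr = _propose_ordered(
        state.delta, state.proposal_scales["thresh"], rng
    )
    th = state.theta[:, design.loading]
    ll_new_mat = _item_loglik_rows(Y, th * alpha_cand, _padded_from_delta(delta_cand))
    log_ratio = np.where(
        alpha_cand > 0,
        ll_new_mat.sum(axis=0) - ll_mat.sum(axis=0) + log_corr,
        -np.inf,
    )
    accept = np.log(rng.uniform(size=log_ratio.shape)) < log_ratio
    state.alpha = np.where(accept, alpha_cand, state.alpha)
    state.delta = np.where(accept[:, None], delta_cand, state.delta)
    ll_mat[:, accept] = ll_new_mat[:, accept]
    for block in ("alpha", "thresh"):
        state.acceptance_counts[block] += accept
        state.batch_counts[block] += accept
        state.proposal_totals[block] += 1
    return ll_mat


# ---------------------------------------------------------------------------
# Initialisation, summaries
# ---------------------------------------------------------------------------


def estimate_rho_cor(Y: np.ndarray, design: TestDesign) -> float:
    """COR criterion: Pearson correlation between the two subscale sum
    scores (attenuated toward zero by measurement error)."""
    if design.n_dims != 2:
        raise ValueError("COR criterion needs exactly two subscales")
    s1 = Y[:, design.items_on(0)].sum(axis=1).astype(float)
    s2 = Y[:, design.items_on(1)].sum(axis=1).astype(float)
    if s1.std() == 0 or s2.std() == 0:
        raise ValueError("degenerate (constant) subscale sum score")
    return float(np.corrcoef(s1, s2)[0, 1])


def _initial_state(
    Y: np.ndarray,
    design: TestDesign,
    rho0: float,
    theta_fixed: Optional[np.ndarray] = None,
) -> ChainState:
    """Deterministic near-consistent starting values: alpha = 1, thresholds
    at normal quantiles of the observed cumulative category frequencies,
    traits at standardised subscale sum scores."""
    N, K = Y.shape
    C = int(design.n_categories[0])
    cum = np.stack([(Y <= c).mean(axis=0) for c in range(1, C)], axis=1)
    delta = ndtri(np.clip(cum, 1e-3, 1.0 - 1e-3))
    # enforce strict ordering with a minimal gap
    for c in range(1, C - 1):
        delta[:, c] = np.maximum(delta[:, c], delta[:, c - 1] + 1e-3)
    if theta_fixed is not None:
        theta = np.array(theta_fixed, dtype=float)
    else:
        theta = np.empty((N, design.n_dims))
        for v in range(design.n_dims):
            s = Y[:, design.items_on(v)].sum(axis=1).astype(float)
            sd = s.std()
            theta[:, v] = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return ChainState(theta, np.ones(K), delta, rho0, C)


@dataclass
class PosteriorSummary:
    """Post-burn-in, thinned posterior summaries for one fitted chain."""

    method: str
    alpha: np.ndarray
    thresholds: np.ndarray  # (K, C-1)
    rho: float
    alpha_sd: np.ndarray
    thresholds_sd: np.ndarray
    rho_sd: float
    alpha_ess: np.ndarray
    thresholds_ess: np.ndarray
    rho_ess: float
    alpha_geweke: np.ndarray
    thresholds_geweke: np.ndarray
    rho_geweke: float
    acceptance_rates: dict
    n_draws: int
    seed: int
    rho_fixed: bool = False
    chains: Optional[dict] = None

    def alpha_mcse(self) -> np.ndarray:
        return self.alpha_sd / np.sqrt(np.maximum(self.alpha_ess, 1.0))

    def thresholds_mcse(self) -> np.ndarray:
        return self.thresholds_sd / np.sqrt(np.maximum(self.thresholds_ess, 1.0))

    def rho_mcse(self) -> float:
        return self.rho_sd / np.sqrt(max(self.rho_ess, 1.0))

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if k == "chains":
                continue
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorSummary":
        arrays = {
            "alpha",
            "thresholds",
            "alpha_sd",
            "thresholds_sd",
            "alpha_ess",
            "thresholds_ess",
            "alpha_geweke",
            "thresholds_geweke",
        }
        kw = {k: (np.asarray(v) if k in arrays else v) for k, v in d.items()}
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PosteriorSummary":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def dump_chains_csv(self, path: str | Path) -> Path:
        """Flat (iteration, parameter, value) chain dump, gzipped when the
        path ends in .gz; requires the fit to have stored chains."""
        if self.chains is None:
            raise ValueError("fit was run without store_chains=True")
        import gzip

        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write("iteration,parameter,value\n")
            for it in range(self.n_draws):
                for j, a in enumerate(self.chains["alpha"][it]):
                    fh.write(f"{it},alpha_{j + 1},{float(a)!r}\n")
                for j, row in enumerate(self.chains["thresholds"][it]):
                    for c, d in enumerate(row):
                        fh.write(f"{it},delta_{j + 1}_{c + 1},{float(d)!r}\n")
                fh.write(f"{it},rho,{float(self.chains['rho'][it])!r}\n")
        return path


def _summarise(
    method: str,
    kept_alpha: np.ndarray,
    kept_delta: np.ndarray,
    kept_rho: np.ndarray,
    state: ChainState,
    config: SamplerConfig,
    rho_fixed: bool,
) -> PosteriorSummary:
    n_draws, K, Cm1 = kept_delta.shape
    alpha_ess = np.array([effective_sample_size(kept_alpha[:, j]) for j in range(K)])
    delta_ess = np.array(
        [
            [effective_sample_size(kept_delta[:, j, c]) for c in range(Cm1)]
            for j in range(K)
        ]
    )
    alpha_gw = np.array([geweke_z(kept_alpha[:, j]) for j in range(K)])
    delta_gw = np.array(
        [[geweke_z(kept_delta[:, j, c]) for c in range(Cm1)] for j in range(K)]
    )
    acc = {}
    for block, counts in state.acceptance_counts.items():
        total = state.proposal_totals[block]
        if total:
            acc[block] = (np.asarray(counts) / total).tolist() if np.ndim(counts) else counts / total
    chains = None
    if config.store_chains:
        chains = {"alpha": kept_alpha, "thresholds": kept_delta, "rho": kept_rho}
    return PosteriorSummary(
        method=method,
        alpha=kept_alpha.mean(axis=0),
        thresholds=kept_delta.mean(axis=0),
        rho=float(kept_rho.mean()),
        alpha_sd=kept_alpha.std(axis=0, ddof=1) if n_draws > 1 else np.zeros(K),
        thresholds_sd=kept_delta.std(axis=0, ddof=1)
        if n_draws > 1
        else np.zeros((K, Cm1)),
        rho_sd=float(kept_rho.std(ddof=1)) if n_draws > 1 else 0.0,
        alpha_ess=alpha_ess,
        thresholds_ess=delta_ess,
        rho_ess=effective_sample_size(kept_rho) if not rho_fixed else float(n_draws),
        alpha_geweke=alpha_gw,
        thresholds_geweke=delta_gw,
        rho_geweke=geweke_z(kept_rho) if not rho_fixed else 0.0,
        acceptance_rates=acc,
        n_draws=n_draws,
        seed=config.seed,
        rho_fixed=rho_fixed,
        chains=chains,
    )


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------


def _require_homogeneous(design: TestDesign) -> None:
    if np.unique(design.n_categories).size != 1:
        raise NotImplementedError(
            "MCMC engines require a homogeneous category count across items"
        )


def _run_augmented(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    threshold_step: Literal["gibbs", "cowles"],
    method: str,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    Y = validate_responses(Y, design)
    _require_homogeneous(design)
    rng = np.random.default_rng(config.seed)
    sample_rho = (
        config.rho_mode == "sampled" and design.n_dims == 2 and theta_fixed is None
    )
    if config.rho_mode == "fixed":
        rho0 = float(config.fixed_rho)
    elif design.n_dims == 2:
        rho0 = float(np.clip(estimate_rho_cor(Y, design), -0.95, 0.95))
    else:
        rho0 = 0.0
    state = _initial_state(Y, design, rho0, theta_fixed)
    kept_alpha, kept_delta, kept_rho = [], [], []
    for it in range(1, config.n_iterations + 1):
        state.iteration = it
        sample_augmented_Z(state, Y, design, rng)
        if theta_fixed is None:
            update_theta(state, design, state.correlation(), rng)
        update_alpha(state, design, rng)
        if threshold_step == "gibbs":
            update_thresholds_gibbs(state, Y, rng)
        else:
            update_thresholds_cowles(state, Y, design, rng)
        if sample_rho:
            update_correlation(state, rng)
        if it % config.adapt_batch == 0:
            adapt_proposals(state, config)
        if config.validate:
            state.check_invariants()
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_alpha.append(state.alpha.copy())
            kept_delta.append(state.delta.copy())
            kept_rho.append(state.rho)
    return _summarise(
        method,
        np.asarray(kept_alpha),
        np.asarray(kept_delta),
        np.asarray(kept_rho),
        state,
        config,
        rho_fixed=not sample_rho,
    )


def run_gibbs(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    """Data-augmentation Gibbs sampler (uniform-interval threshold update)."""
    return _run_augmented(Y, design, config, "gibbs", "gibbs", theta_fixed)


def run_hwg(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    """Hastings-within-Gibbs: Cowles MH threshold update inside the Gibbs
    sweep."""
    return _run_augmented(Y, design, config, "cowles", "hwg", theta_fixed)


def run_mh(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    criterion: Optional[Literal["TRUE", "AIC", "COR"]] = None,
    true_rho: Optional[float] = None,
    rho_grid: Optional[np.ndarray] = None,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    """Blocked Metropolis–Hastings without augmentation.

    With a criterion the intertrait correlation is fixed: at the known
    generating value (TRUE), at the subscale sum-score correlation (COR),
    or at the AIC-minimising grid value (AIC).  Without a criterion and
    with ``rho_mode='sampled'`` the correlation is updated by MH — the
    blocked-Metropolis (BM) arm.
    """
    Y = validate_responses(Y, design)
    _require_homogeneous(design)
    if criterion == "TRUE":
        if true_rho is None:
            raise ValueError("criterion TRUE requires the generating rho")
        return _run_mh_fixed(Y, design, config, float(true_rho), "mh_true", theta_fixed)
    if criterion == "COR":
        rho = float(np.clip(estimate_rho_cor(Y, design), -0.99, 0.99))
        return _run_mh_fixed(Y, design, config, rho, "mh_cor", theta_fixed)
    if criterion == "AIC":
        grid = np.arange(0.0, 0.91, 0.1) if rho_grid is None else np.asarray(rho_grid)
        rho, summaries, _ = _aic_scan(Y, design, config, grid)
        best = summaries[rho]
        best.method = "mh_aic"
        return best
    if criterion is not None:
        raise ValueError(f"unknown criterion {criterion!r}")
    if config.rho_mode == "fixed":
        return _run_mh_fixed(Y, design, config, float(config.fixed_rho), "mh", theta_fixed)
    return _run_mh_core(Y, design, config, None, "bm", theta_fixed)


def _run_mh_fixed(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    rho: float,
    method: str,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    return _run_mh_core(Y, design, config, rho, method, theta_fixed)


def _run_mh_core(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    fixed_rho: Optional[float],
    method: str,
    theta_fixed: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    rng = np.random.default_rng(config.seed)
    sample_rho = fixed_rho is None and design.n_dims == 2 and theta_fixed is None
    if fixed_rho is not None:
        rho0 = fixed_rho
    elif design.n_dims == 2:
        rho0 = float(np.clip(estimate_rho_cor(Y, design), -0.95, 0.95))
    else:
        rho0 = 0.0
    state = _initial_state(Y, design, rho0, theta_fixed)
    kept_alpha, kept_delta, kept_rho = [], [], []
    Pinv = np.linalg.inv(state.correlation().P)
    ll_mat = _item_loglik_rows(
        Y, state.theta[:, design.loading] * state.alpha, state.padded()
    )
    for it in range(1, config.n_iterations + 1):
        state.iteration = it
        if theta_fixed is None:
            ll_mat = _update_persons_mh(state, Y, design, Pinv, ll_mat, rng)
        ll_mat = _update_items_mh(state, Y, design, ll_mat, rng)
        if sample_rho:
            old = state.rho
            update_correlation(state, rng)
            if state.rho != old:
                Pinv = np.linalg.inv(state.correlation().P)
        if it % config.adapt_batch == 0:
            adapt_proposals(state, config)
        if config.validate:
            state.check_invariants()
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_alpha.append(state.alpha.copy())
            kept_delta.append(state.delta.copy())
            kept_rho.append(state.rho)
    return _summarise(
        method,
        np.asarray(kept_alpha),
        np.asarray(kept_delta),
        np.asarray(kept_rho),
        state,
        config,
        rho_fixed=not sample_rho,
    )


# ---------------------------------------------------------------------------
# AIC criterion
# ---------------------------------------------------------------------------


def _aic_scan(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    grid: np.ndarray,
) -> tuple[float, dict, dict]:
    """Fit the MH sampler at each fixed rho on the grid and score each fit
    by AIC = -2 * quadrature marginal log-likelihood (at the posterior-mean
    item parameters) + 2 * (number of item parameters)."""
    from .mml_baem import marginal_loglik

    if len(grid) == 0:
        raise ValueError("empty rho grid")
    n_item_params = int(design.n_categories.sum())  # 1 slope + (C_j - 1) cuts each
    summaries: dict[float, PosteriorSummary] = {}
    aics: dict[float, float] = {}
    for r in np.sort(np.asarray(grid, dtype=float)):
        s = _run_mh_fixed(Y, design, config, float(r), "mh_fixed")
        params = ItemParameters(s.alpha, list(s.thresholds))
        ll = marginal_loglik(Y, params, float(r), design)
        summaries[float(r)] = s
        aics[float(r)] = -2.0 * ll + 2.0 * n_item_params
    best = min(aics, key=lambda r: (aics[r], r))  # ties toward smaller rho
    if sum(1 for v in aics.values() if v == aics[best]) > 1:
        logger.info("AIC tie at %.3f broken toward smaller rho", aics[best])
    return best, summaries, aics


def select_rho_aic(
    Y: np.ndarray,
    design: TestDesign,
    config: SamplerConfig,
    grid: np.ndarray,
    return_details: bool = False,
):
    """AIC criterion for the intertrait correlation: the grid value whose
    fixed-rho MH fit minimises AIC (ties broken toward smaller rho)."""
    best, summaries, aics = _aic_scan(Y, design, config, grid)
    if return_details:
        return best, summaries, aics
    return best
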