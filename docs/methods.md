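# Methods

## Model

`mugrm` implements the **multi-unidimensional graded response model**: a
K-item instrument is split into m subscales, each item j loading on exactly
one latent dimension v(j) (simple structure).  For person i with trait
vector θ_i and item parameters (α_j, δ_j), the probability of an ordered
response in category c ∈ {1, …, C_j} is

    P(Y_ij = c) = F(α_j θ_{v(j),i} − δ_{j,c−1}) − F(α_j θ_{j,c}),
    −∞ = δ_{j,0} < δ_{j,1} < … < δ_{j,C_j−1} < δ_{j,C_j} = +∞,

with F the standard-normal CDF (probit / normal ogive) or the logistic CDF.
The unidimensional graded response model is the m = 1 special case; a test
asserts the two code paths coincide.  Traits follow N_m(0, P) with P a
correlation matrix, so the dimensions are standardized and correlate only
through the intertrait correlation ρ (m = 2 throughout the study design).

**Identification.**  Location and scale of each trait axis are fixed by the
zero-mean, unit-variance trait prior; reflection by the constraint α_j > 0.
Without α > 0 each subscale's posterior would have a mirror mode
(α → −α, δ → −δ, θ → −θ); the constraint is also consistent with the
generating distribution α ~ U(0, 2).

**Links.**  The default is probit everywhere because the data-augmentation
samplers exist only for the normal ogive; the logistic link (no 1.7 scaling
constant) is available in the core probabilities and the MML-EM engine.
Cross-method comparisons in the study runner are therefore all on the
probit metric.

## Estimation engines

All Bayesian engines share the same posterior: flat prior on α_j over
(0, ∞), flat order-constrained prior on δ_j, N_m(0, P) prior on θ_i, and a
flat prior on ρ ∈ (−1, 1) where ρ is sampled.  Point estimates are
posterior means (EAP).

### Data-augmentation Gibbs (`run_gibbs`)

Albert–Chib augmentation extended to simple structure: latent continuous
responses Z_ij ~ N(α_j θ_{v(j),i}, 1) truncated to the observed category's
threshold interval make every full conditional standard:

* Z — truncated normal, sampled by vectorized inverse-CDF with tail
  guards that keep draws strictly inside finite bounds;
* θ_i — exact m-variate normal with precision P⁻¹ + AᵀA (diagonal AᵀA
  under simple structure, so one 2×2 covariance serves all persons);
* α_j — the least-squares regression of Z_j on the item's trait column,
  truncated to (0, ∞);
* δ_{j,c} — uniform on the interval between the largest Z in category c
  and the smallest Z in category c + 1 (clipped by neighbouring cuts);
* ρ — random-walk Metropolis on Fisher-z(ρ) with the z-transform Jacobian
  in the ratio (exact for the single free correlation at m = 2; chosen
  over inverse-Wishart rescaling for simplicity and exactness).

The uniform threshold interval narrows like the spacing of extreme order
statistics of Z, so threshold mixing degrades with N — the classic
motivation for the next engine, and visible in the lag-10 autocorrelation
comparison test.

### Hastings-within-Gibbs (`run_hwg`)

Identical sweep except thresholds: per item, candidate cut-points are
proposed sequentially from normals truncated to preserve ordering (Cowles'
proposal) and accepted jointly with the ratio of observed-data likelihoods
(Z integrated out) times the truncated-proposal normalizer correction.  Z
is redrawn from its full conditional at the start of the next sweep, which
makes the composition a valid partially collapsed sampler: nothing reads Z
between the threshold move and its refresh.

### Blocked Metropolis–Hastings (`run_mh`)

No augmentation.  Person blocks: a symmetric normal random walk on θ_i for
all persons in parallel.  Item blocks: joint (α_j, δ_j) proposals — normal
walk on α (candidates ≤ 0 are rejected by the positive flat prior) and the
same order-preserving threshold proposal.  The intertrait correlation is
handled by one of four regimes:

* **TRUE** — fixed at the known generating value (an oracle; its reported
  ρ error is therefore zero by construction);
* **COR** — fixed at the Pearson correlation between the two subscale sum
  scores, which is attenuated toward zero by measurement error;
* **AIC** — fixed at the grid value (ρ ∈ {0.0, 0.1, …, 0.9}) whose
  fixed-ρ fit minimizes AIC = −2·marginal log-likelihood + 2·(number of
  item parameters), the likelihood evaluated by the quadrature below at
  the fit's posterior-mean item parameters; ties break toward smaller ρ.
  The parameter count covers item parameters only (3 per item at C = 3),
  matching a comparison in which ρ is fixed, not estimated;
* **sampled** — the Fisher-z walk, which realizes the blocked-Metropolis
  (BM) study arm.

### Proposal adaptation

Every 25 iterations during burn-in, each block's scale is multiplied by
exp(g·(rate − target)) with gain g = min(0.5, 2/√batch) — a Robbins–Monro
style scheme frozen at `adapt_until ≤ burn_in`, so the post-burn-in kernel
is fixed and chain validity is unaffected.  Targets: 0.40 for item,
threshold and correlation blocks, 0.25 for the m-dimensional person blocks
(standard random-walk guidance).

### Bock–Aitkin MML-EM (`fit_baem`)

Marginal maximum likelihood with a fixed Gauss–Hermite quadrature:
21 probabilists' nodes per dimension (441 in total), tensorized and
rotated by the Cholesky factor of P so the grid integrates N_2(0, P)
exactly for polynomials up to the rule's degree; the grid is rebuilt
whenever ρ changes.  The E-step converts each person's posterior over
nodes into expected per-(item, node, category) counts; the M-step
maximizes each item's expected complete-data log-likelihood by L-BFGS in
(log α, δ_1, log gaps), an order-free parameterization, rejecting any
step that fails to improve — each cycle is therefore a generalized-EM
ascent.  ρ is re-estimated each cycle by the exact one-dimensional M-step
for a unit-variance bivariate normal (a cubic in ρ solved in closed form,
the root chosen by the expected log-likelihood).  Convergence: largest
absolute parameter change < 1e−4 or 500 cycles; a marginal-likelihood
decrease beyond 1e−6·(1 + |ℓ|) raises with the trace attached (the small
relative slack absorbs quadrature re-approximation when the grid rotates
with ρ; with ρ fixed the trace is monotone to 1e−8 and tested so).

21 nodes per dimension keep the evaluator within ~1e−5 of a 41-node rule
on short tests; with 20+ items per dimension the integrand sharpens and
the absolute log-likelihood error grows, but the location of the optimum —
and hence the estimates and AIC rankings — is unaffected at the precision
the recovery metrics resolve.

### Initialization (all engines)

Deterministic, near-consistent starts: α = 1; δ at standard-normal
quantiles of the observed cumulative category frequencies (gap-separated
by 1e−3 if needed); θ at standardized subscale sum scores; ρ at the
subscale sum-score correlation.  These start every chain in the bulk of
the posterior, which is why the default chains are comparatively short.

## Synthetic data generator

One replication of a study condition (N, K, ρ) draws, in order:
α_vj ~ U(0, 2) (exact zeros redrawn), thresholds per item as the order
statistics of two independent N(0, 1) draws, traits from N_2(0, P) by
Cholesky, and responses from the probit model by inverse-CDF.  Defaults
mirror the factorial design: N ∈ {500, 1000}, K ∈ {20, 40} split into two
equal subscales, C = 3 categories, ρ ∈ {0.2, 0.5, 0.8}.  Item parameters,
traits and responses are all redrawn each replication (the conservative
reading of a replicated design; the alternative — truth fixed across
replications — is not offered).  A replication in which some item never
receives some category is regenerated from the stream's next sub-seed and
logged; estimators require every category observed.  Every
(condition, replication) pair owns an independent `SeedSequence` stream
keyed by the master seed and the design fields, so any table cell can be
regenerated in isolation, in any order, bit-for-bit.

What the generator does **not** emulate: real instruments have missing
responses, cross-loading items, non-normal traits, and respondent
behaviours (carelessness, styles) outside the model family.  Passing
recovery tests therefore demonstrate internal consistency of estimator and
generative model, not robustness to model violation.

## Recovery metrics

For each item parameter, RMSD = √(mean over replications of
(estimate − truth)²) and bias = mean(estimate − truth) are computed per
item across replications first; 10% trimmed means (dropping
floor(0.10·n) items per tail after sorting) are then taken across items
within each class: subscale-1 α's, subscale-2 α's, first thresholds of all
items, second thresholds of all items.  ρ, a single parameter, is
aggregated across replications without trimming.  The per-subscale
threshold grouping is available behind a flag.  At the per-item level
RMSD ≥ |bias| always (Jensen).

## Chain lengths and desk scale

The default sampler configuration is 10,000 iterations with 5,000 burn-in
(typical for augmented graded-response samplers); convergence is assessed
by ESS (Geyer initial positive sequence) and Geweke z rather than length
alone.  The shipped acceptance script and test suite run the recovery
cells at 2,000 iterations with 800 burn-in (AIC scans at 800/300): from
the deterministic near-consistent starts, post-burn-in ESS per parameter
is in the hundreds and the chain-length contribution to RMSD (≈ posterior
sd/√ESS ≈ 0.01) is an order of magnitude below the data-limited error
(≈ 0.1–0.15 at N = 500), so cell values are insensitive to the shorter
chains.  The AIC arm runs 3 replications by default (a 10-fit grid per
replication makes it ten times the cost of the other arms).

## Known limitations and observed behaviour

* The MCMC engines require a homogeneous category count across items; the
  core probabilities and the EM engine accept heterogeneous C_j.
* At K = 40 (and occasionally at moderate ρ), single replications exist
  whose posterior is genuinely displaced from the generating values —
  converged chains of *all* engines agree on estimates far from truth for
  a handful of items (trait-scale information is weak enough for the
  flat-prior posterior to drift).  Converged samplers therefore sometimes
  show *larger* threshold RMSD than a slowly mixing Gibbs chain still near
  its data-driven start.  This also means well-converged runs here produce
  smaller errors than software arms whose published values reflect
  non-convergence.
* Standard errors of item parameters are out of scope; the EM engine
  reports point estimates, log-likelihood and AIC only.
* Samplers not in the study design (HMC, tempering) and the
  adaptive-quadrature and Metropolis–Hastings Robbins–Monro comparison
  arms are out of scope: the latter two are proprietary-software arms
  whose internals are unspecified.
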