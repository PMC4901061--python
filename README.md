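# mugrm

Estimation engines and parameter-recovery studies for the
**multi-unidimensional graded response model** (GRM) — the polytomous IRT
model for instruments built from several subscales, each item loading on
exactly one latent trait (simple structure), with traits correlating
through an intertrait correlation matrix.

Ordinal-response instruments with this structure are ubiquitous in health
and behavioural measurement (quality-of-life scales, personality
inventories, patient-reported outcomes).  The model: person i answers item
j of subscale v in category c ∈ {1, …, C_j} with probability

    P(Y_ij = c) = F(α_j θ_vi − δ_{j,c−1}) − F(α_j θ_vi − δ_{j,c}),

where F is the standard-normal (probit) or logistic CDF, α_j > 0 the item
discrimination, δ_{j,1} < … < δ_{j,C_j−1} the ordered category thresholds
(δ_{j,0} = −∞, δ_{j,C_j} = +∞), and θ_i ~ N_m(**0**, **P**) with **P** a
correlation matrix.

Four estimation engines share this model:

| engine | idea |
| --- | --- |
| `run_gibbs` | Albert–Chib data augmentation: truncated-normal latent responses make every full conditional standard |
| `run_hwg` | Hastings-within-Gibbs: a Cowles Metropolis step for the thresholds inside the Gibbs sweep, for much faster threshold mixing |
| `run_mh` | blocked Metropolis–Hastings without augmentation (person and item blocks), with the intertrait correlation fixed by a TRUE / COR / AIC criterion or sampled (the blocked-Metropolis variant) |
| `fit_baem` | Bock–Aitkin marginal maximum likelihood EM over a fixed 21×21 Gauss–Hermite grid rotated to the trait correlation |

Around them: a synthetic-data generator for the N × K × ρ factorial design
(α ~ U(0, 2), thresholds as sorted standard-normal pairs, bivariate-normal
traits), recovery metrics (per-item RMSD and bias across replications, 10%
trimmed means across items), and a resumable study runner with a CLI.
See `docs/methods.md` for the full model and algorithm account.

## Worked example

```python
import numpy as np
import mugrm as mg

cond = mg.StudyCondition(500, 20, 0.5)           # N=500, K=20, rho=0.5
bundle = mg.generate_dataset(cond, replication=0)
fit = mg.run_hwg(bundle.Y, bundle.design,
                 mg.SamplerConfig(n_iterations=2000, burn_in=800, seed=7))
print(f"estimated rho: {fit.rho:.3f}  (generating value {cond.rho})")
print(f"alpha  truth: {np.round(bundle.params.alpha[:5], 2)}")
print(f"alpha  EAP:   {np.round(fit.alpha[:5], 2)}")
```

prints

```
estimated rho: 0.497  (generating value 0.5)
alpha  truth: [1.69 0.16 1.1  0.73 1.11]
alpha  EAP:   [1.99 0.08 1.43 0.68 1.09]
```

The Hastings-within-Gibbs posterior means recover the generating
discriminations to roughly their posterior spread (≈ 0.1–0.3 at N = 500)
and the intertrait correlation to well under 0.05.  `fit` also carries
posterior sds, effective sample sizes, Geweke z diagnostics and
per-block acceptance rates.

The same thing from the shell:

```sh
mugrm simulate --n 500 --k 20 --rho 0.5 --seed 1 --out data/
mugrm fit --method hwg --data data/ --iterations 2000 --burnin 800 --out est.json
mugrm diagnose --summary est.json
```

A full factorial recovery study (all conditions × methods × replications,
resumable, one artifact directory per replication):

```sh
mugrm study --n 500 --k 20 --rho 0.2 --rho 0.8 --method hwg --method baem \
            --reps 10 --out study_out/
```

which ends by printing the long-format recovery table (trimmed-mean RMSD
and bias per parameter class) also written to
`study_out/recovery_table.csv`.

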