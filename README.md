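# cctte

Design and analysis of **covariate-constrained cluster-randomized trials
with time-to-event outcomes**.

Cluster-randomized trials (CRTs) often enroll few clusters, so a single
unlucky randomization can leave prognostic cluster-level covariates badly
imbalanced between arms. Covariate-constrained randomization guards against
this by selecting the final allocation from the subset of candidate
allocations that balance those covariates — here, the schemes whose
inverse-variance-weighted imbalance score

&nbsp;&nbsp;&nbsp;&nbsp;*B* = Σₖ ωₖ (x̄ₐₖ − x̄ᵦₖ)², ωₖ = 1 / varₖ,

falls in the bottom *q* percentile, or alternatively schemes whose
per-covariate arm-mean ratios lie in (1/1.1, 1.1). `cctte` is for
biostatisticians designing or evaluating such trials when the endpoint is a
censored time to event: it simulates clustered exponential survival data,
builds and validates constrained randomization spaces, and analyzes trials
with three methods:

1. **Cox proportional hazards with cluster-robust (Huber sandwich) variance**;
2. **mixed-effects Cox** with a Gaussian cluster random intercept (penalized
   partial likelihood, Laplace-profile variance);
3. a **permutation test on deviance residuals**: fit the treatment-free null
   Cox model (optionally adjusted for the balancing covariates), average the
   deviance residuals r_D = sign(δ−r_C)·√(−2[δ−r_C+δ·log r_C]) within
   clusters, and refer S = g⁻¹ Σᵢ (2Tᵢ−1) r̄ᵢ to its exact permutation
   distribution over the randomization space the design actually used.

A Monte-Carlo engine reproduces the type-I-error / power study comparing
these methods under simple versus constrained randomization, with prognostic
(β > 0) or non-prognostic (gamma-frailty) cluster effects.

## Worked example

```python
from cctte import (Scenario, TrialDesign, generate_replicate, fit_cox,
                   wald_reject, fit_mixed_cox, mixed_wald_reject,
                   permutation_test, empirical_icc)

scenario = Scenario(
    design=TrialDesign(g=8, n=100, delta=0.5, beta=0.25),  # 50% efficacy
    q=0.10,                                                # constrained
    n_sim=1, seed=7,
)
trial, space, allocation = generate_replicate(scenario, 0)

print(f"subjects: {trial.n_subjects}, events: {int(trial.event.sum())}")
print(f"allocation space: {space.size} unique schemes, "
      f"{space.constrained_size} retained at q=0.10")
print(f"empirical ICC (pre-censoring): "
      f"{empirical_icc(trial.latent_time, trial.cluster_id):.4f}")

robust = fit_cox(trial, covariate_count=4, include_treatment=True)
res = wald_reject(robust, variance="robust")
print(f"robust Cox:  HR={res.estimate_hr:.3f} "
      f"CI=({res.ci_low:.3f}, {res.ci_high:.3f}) p={res.p_value:.4f}")

mixed = fit_mixed_cox(trial, covariate_count=4, include_treatment=True)
mres = mixed_wald_reject(mixed)
print(f"mixed Cox:   HR={mres.estimate_hr:.3f} "
      f"CI=({mres.ci_low:.3f}, {mres.ci_high:.3f}) "
      f"p={mres.p_value:.4f} theta={mixed.theta:.3f}")

perm = permutation_test(trial, space, covariate_count=4)
print(f"permutation: S={perm.statistic:.4f} p={perm.p_value:.4f} "
      f"(space of {perm.space_size})")
```

prints:

```
subjects: 1600, events: 382
allocation space: 10115 unique schemes, 2966 retained at q=0.10
empirical ICC (pre-censoring): 0.1237
robust Cox:  HR=0.517 CI=(0.433, 0.618) p=0.0000
mixed Cox:   HR=0.517 CI=(0.412, 0.648) p=0.0000 theta=0.000
permutation: S=-0.2737 p=0.0040 (space of 2966)
```

Reading this: of 20,000 sampled allocation schemes, 10,115 were unique and
the best-balanced 2,966 (score ties at the cutoff are all kept) formed the
constrained space. All three tests recover the simulated hazard ratio of
0.5 and reject H₀: δ = 1 — the permutation p-value of 0.004 means only 0.4%
of allocations in the constrained space produce a cluster-mean residual
contrast as extreme as the observed one.

## Command line

```bash
cctte simulate  --config cfg.yaml --out trial.csv --space-out space.csv
cctte randomize --config cfg.yaml --covariates cov.csv --out space.csv
cctte analyze   --data trial.csv --method cox_robust -S 4
cctte permtest  --data trial.csv --space space.csv -S 4 --constrained
cctte scenario  --config grid.yaml --out results.csv
cctte fixtures  --kind tiny --out fixtures/
```

Configurations are YAML (validated, unknown keys rejected); datasets and
allocation spaces are plain CSV with bit-exact float round trips.

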