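# Methods

`cctte` simulates, randomizes, and analyzes two-arm cluster-randomized
trials (CRTs) with right-censored time-to-event outcomes, and reproduces a
Monte-Carlo study of type-I error and power for three analysis methods
under simple versus covariate-constrained randomization.

## Data-generating model

A trial has `g` clusters per arm and `n` subjects per cluster.  Subject
`j` of cluster `i` has an exponential latent event time with rate

    lambda_ij = lambda0 * gamma_i * exp(x_i' beta + T_i * log(delta)),

where `x_i` holds four binary cluster-level covariates drawn independently
Bernoulli(0.3), `T_i` is the cluster's treatment indicator, `delta` is the
treatment hazard ratio, and `gamma_i` is a cluster frailty drawn from a
mean-one gamma distribution, Gamma(shape = 1/sigma^2, scale = sigma^2)
(`sigma^2 = 0` means `gamma_i = 1` exactly).  All subjects alive at
`tau = 2` years are administratively censored there.  The baseline hazard
is not a free parameter: `lambda0 = -log(1 - pi0)/tau` is calibrated so a
reference subject (`x = 0`, `T = 0`, `gamma = 1`) has cumulative event
probability `pi0` (default 25%) by `tau`.

Latent times are drawn by inverse transform from per-subject uniforms, so
two scenario variants sharing a replicate seed see identical data whenever
their subject rates coincide (e.g., different constraint percentiles under
`delta = 1`).  Latent (pre-censoring) times are retained on the dataset so
the empirical intraclass correlation

    ICC = sigma2_b / (sigma2_b + sigma2_w)

can be measured before censoring; both components use (n-1) sample
variances (`sigma2_b` over cluster means, `sigma2_w` averaged across
clusters).  Under the gamma frailty alone this ICC converges to
`sigma^2` itself (via E[1/gamma] = 1/(1-sigma^2) and
E[1/gamma^2] = 1/((1-sigma^2)(1-2*sigma^2))) — a useful closed-form test
anchor.  Note the study conditions fix the frailty variances at
{0.087, 0.143, 0.268}; we make no claim that these correspond to any other
ICC labels, since ICC definitions for censored survival data are not
settled and alternative estimators give different values.

Two scenario families are used: *prognostic* (`beta > 0` on all four
covariates, `sigma^2 = 0`) and *non-prognostic* (`beta = 0`,
`sigma^2 > 0`).  Combining `beta > 0` with `sigma^2 > 0` is rejected by
the scenario grid: the covariate effect already induces between-cluster
variance, and stacking a frailty on top would make the prognostic versus
non-prognostic comparison uninterpretable.

## Randomization

Candidate allocations assign `g` of the `2g` clusters to each arm.  The
engine draws 20,000 schemes uniformly with replacement and removes
duplicates (`enumerate_allocation_space` provides the exact C(2g, g) space
for small designs and for tests; the sampled-then-deduplicated space is
the study's procedure and is what all simulation runs use).  Each scheme
is scored with the inverse-variance-weighted imbalance score

    B = sum_k w_k (xbar_Ak - xbar_Bk)^2,    w_k = 1 / var_k,

where `var_k` is the (2g-1)-denominator sample variance of covariate `k`
over all clusters.  Constrained randomization keeps schemes with `B` at or
below the empirical `q`-quantile (the `ceil(q*M)`-th smallest score,
inclusive, so ties at the cutoff are all retained and the set is never
empty); `q = 1` is simple randomization.  The final allocation is drawn
uniformly from the retained set and a fair coin picks the treatment arm.
Mirror allocations are kept as distinct members so the permutation null
distribution stays symmetric under arm relabeling.

An alternative, mutually exclusive constraint mimics ratio-based balance
rules used in practice: per-covariate arm-mean ratios must lie strictly
inside (1/1.1, 1.1), optionally with per-category cluster counts balanced
within +/-1.  A validity check reports pairwise co-assignment proportions
over the retained set and flags pairs outside (0.25, 0.75), i.e. clusters
the constraint has nearly hard-wired together or apart.

Degenerate covariates: a Bernoulli(0.3) draw over 16 clusters is constant
for at least one covariate in roughly 1.3% of replicates, making `1/var_k`
undefined.  `imbalance_score` raises; the engine's scoring path instead
assigns such covariates a zero contribution (their limiting value — a
constant covariate is exactly balanced under every allocation), and model
fits drop zero-variance design columns, mirroring how R's `coxph` returns
`NA` for them while fitting the rest.

## Analysis methods

All three tests target H0: `delta = 1` at the two-sided 5% level.

**Cox with cluster-robust variance.**  The Breslow partial likelihood is
maximized by Newton iteration with step-halving (relative log-likelihood
change < 1e-9 or gradient max-norm < 1e-6, at most 50 iterations).
Monotone likelihoods (separation) are capped at |beta| = 15 and flagged
non-converged rather than aborting a simulation run.  The Huber sandwich
A^-1 (sum_i U_i U_i') A^-1 aggregates subject score residuals within
clusters; with one subject per cluster it reduces to the Lin-Wei
estimator.  No small-sample correction is applied, matching the default
behavior of `survival::coxph` (verified to 5 decimals against both R and
lifelines).  Rejection: the Wald 95% CI `exp(beta_T +/- 1.96 SE_robust)`
excludes 1.

**Mixed-effects Cox.**  Gaussian cluster intercepts `b_i` enter the log
hazard; for fixed variance `theta` the penalized Breslow partial
likelihood `l(beta, b) - b'b/(2 theta)` is maximized jointly, and `theta`
maximizes the Laplace-approximate integrated likelihood
`l_p - 0.5 log det(I + theta H_bb)` over [1e-8, 10] on a log grid refined
by golden section (boundary estimates report `theta = 0` and collapse
exactly to the plain Cox fit).  Because covariates and intercepts are
cluster-constant, the risk-set sums are computed from per-cluster at-risk
counts at each event time — an exact collapsed representation that makes
each fit cheap enough for thousands of Monte-Carlo fits.  The treatment SE
comes from the inverse penalized information.  The data carry a *gamma*
frailty while the model assumes a *Gaussian* random effect; this mismatch
is deliberate (the model is a comparator, not the generator).

**Deviance-residual permutation test.**  A Cox model is fitted under the
null (no treatment term; the S balancing covariates optionally adjusted
for).  Cox-Snell residuals `r_C = exp(x'beta_hat) * H0_hat(y)` use the
right-continuous Breslow baseline cumulative hazard; deviance residuals

    r_D = sign(d - r_C) * sqrt(-2 [d - r_C + d log r_C])

(censored subjects with `r_C = 0` map to 0 by continuity) are averaged
within clusters, and the statistic `S = g^-1 sum_i (2 T_i - 1) rbar_i` is
referred to its permutation distribution over the randomization space the
design actually used: the full deduplicated space under simple
randomization, the constrained subset under constrained randomization.
Because the null fit ignores treatment, residuals are computed once per
dataset.  The two-sided p-value counts allocations with
|S*| >= |S_obs| (observed included, so p > 0 always); rejection at
p <= 0.05.  The Breslow tie convention is used throughout because the
Cox-Snell construction relies on the Breslow baseline; simulated times are
continuous, so divergence from Efron-based fits is negligible.

## Monte-Carlo engine

One replicate: draw covariates and frailties → sample and score the
allocation space from the same covariate matrix → constrain → select the
trial allocation → simulate outcomes → run each requested method at each
adjustment level S in {0,...,4}.  Replicate `i` always consumes the random
substream derived from `(master seed, i)` with independent child streams
for covariates, frailties, latent-time uniforms, space sampling, and
selection, so results are identical under any parallel scheduling.
Rejection rates are reported with the Monte-Carlo standard error
`sqrt(p(1-p)/n_sim)`.  Non-converged fits are excluded from that method's
denominator and counted separately; silently counting them as rejections
or acceptances would bias rates invisibly.

### Problem sizes

The full study grid (1,000 replicates per cell) is available through the
scenario-grid configuration.  The package's own reproduction runs
(`scripts/acceptance.py`, `tests/test_acceptance.py`) use 500 replicates
for type-I-error cells and 300 for power cells, with 3x(pooled) MCSE
tolerances — enough resolution to separate nominal 0.05 behavior from the
documented model-based inflation while keeping a desk-scale runtime.
Reference-calibration checks use 100,000 independent subjects.

## Known limitations and reproduction caveats

* The exponential/proportional-hazards generator with administrative
  censoring does not exercise non-proportional hazards, informative
  censoring, individual-level covariates, or nested (household-in-cluster)
  structure; conclusions from the synthetic study do not automatically
  transfer to data with those features.
* Under the study's frailty calibration (sigma^2 in {0.087, 0.143,
  0.268}), the measured pre-censoring ICC equals sigma^2 (closed form
  above).  Published power figures for comparable designs that assume
  materially smaller between-cluster variance will therefore not be
  matched by these conditions; the package reports what the stated
  generator actually produces, and an independent R (`survival::coxph`)
  replication of the same conditions agrees with it.
* The cluster-robust sandwich at 16 clusters with five cluster-level model
  terms is strongly downward-biased; its over-rejection (~0.16-0.20 here)
  exceeds some published figures for similar settings (~0.11), again
  consistent with the R cross-check.  The qualitative conclusion — robust
  Cox over-rejects at small g while the permutation test holds its size —
  is robust.
* With continuous simulated times, ties never occur; for user-supplied
  data with heavy ties the Breslow convention may diverge from
  Efron-based software in late digits.
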