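# Methods

## Generative model

A balanced two-arm CRT has k clusters per arm of nominal size m. The
individual-level baseline covariate is X_ijl = α_ij + u_ijl with
α_ij ~ N(μx, σα²) and u_ijl ~ N(0, σu²), so Var(X) = σx² = σα² + σu² and
the covariate ICC is ρx = σα²/σx². Outcomes are Bernoulli with

    g(π_ijl) = β0 + β1·i + β2(i)·X_ijl + δ_ij,   δ_ij ~ N(0, σb²),

g logit by default. Missingness is covariate-dependent:
logit P(R_ijl = 0) = ψ_i + ϕ_i X_ijl, independent across individuals;
covariates are never missing. The scenario presets share
μx = 0, σu² = 3.37, σα² = 0.18, σb² = 0.20, β0 = 0, β1 = 1.36, ϕ = 1,
m = 50, which puts the marginal success rates at 0.50 (control) and 0.70
(intervention), the covariate ICC at ≈0.05 and the outcome ICCs at ≈0.037
and ≈0.032 — values typical of primary-care CRTs, where outcome ICCs below
0.05 are the norm. The presets differ in whether β2 and ψ match between
arms (S1: both match; S2: ψ differs, 30% vs 60% missing; S3: β2 differs,
0.588 vs 1; S4: both differ).

The ψ intercepts −1.34 and 0.65 are stored as published constants;
`calibrate_psi` root-finds ψ for any missingness target and recovers
−1.337/0.645 for 30%/60%, i.e. the constants are the 2-dp roundings of the
calibrated values.

**Log link support.** The log link is used analytically (the RR validity
conditions), not in the shipped scenarios. Because exp can exceed 1, X is
truncated at μx ± 4σx, δ at ±4σb, and a configuration is rejected unless
the largest linear predictor over that box is negative. Truncation at 4 SD
changes the covariate law negligibly (mass 6e-5) but makes π < 1 a hard
guarantee.

**Quadrature oracles.** Marginal success rates and expected missingness
integrate the inverse link over the normal laws of (X, δ) with a 64-node
(tensor, for two dimensions) Gauss–Hermite rule; with an expit/exp
integrand and these variances the rule is accurate well past 1e-8.
The outcome ICC ρ_i = Var(π_ij)/(π_i(1−π_i)) has no convenient closed form
and is estimated from a very large simulated dataset (default 2000 clusters
of 500 per arm), averaging the *true* individual probabilities within
cluster; at that size the relative MC error of Var(π_ij) is about 3%.

## Estimators

**Cluster-level.** Stage one reduces clusters to summaries; stage two is a
pooled two-sample t with df equal to the number of contributing clusters
minus 2. For the adjusted analyses the stage-one model is a covariate-only
logistic regression fitted to pooled observed records, ignoring arm and
clustering (this is deliberate: adjusting out the covariate before
comparing arms). Difference residuals are divided by m on full data and by
the cluster's observed count under complete records — the full-data choice
preserves the exact identity RD_adj = RD_unadj + (1/(mk))Σ(N̂0j − N̂1j),
which the tests verify to 1e-12. Ratio residuals are N/N̂; the log-RR
variance uses the delta-method form s²ε/(k ε̄²) summed over arms, with the
realised per-arm cluster counts substituted for k when complete-records
analysis empties a cluster (the formulas are stated for balanced k; using
realised counts is our choice and only matters when whole clusters lose
every outcome). Empty clusters are dropped because a cluster proportion is
undefined on zero observed outcomes.

Separation of the stage-one fit (constant outcome, or perfect prediction)
raises an error instead of returning huge coefficients; the simulation
harness records such replicates as failed for the affected cell.

**RELR.** The marginal likelihood of the random-intercept logistic model
is evaluated by adaptive Gauss–Hermite quadrature: per cluster, a 1-D
Newton iteration finds the posterior mode of the random effect and the
curvature there, and 15 nodes are re-centred and scaled accordingly;
log-sum-exp keeps the node sum stable. L-BFGS-B maximises over
(β, log σb) (bounds keep log σb in [log 1e-4, log 50], so σb = 0 is
approached smoothly rather than hit as a boundary); standard errors come
from the numerically differentiated Hessian at the optimum, with a
fall-back to the β-block Hessian when the σb direction is flat. Warm
starts: the cluster modes persist between likelihood evaluations, so the
inner Newton converges in 2–3 steps during optimisation. The
implementation agrees with R's lme4 `glmer(nAGQ=15)` to ~2e-4 on a test
fixture. Intervals use t(2k−2), the convention of comparing 2k clusters.

**GEE.** statsmodels' GEE (binomial, exchangeable) supplies the estimating
equations and sandwich variance; we multiply the variance by k/(k−1)
(k per arm — the correction is conventionally stated for the variance,
though "SE multiplied by k/(k−1)" is sometimes written; the alternative is
exposed as `correction="se"`) and use t(2k−2−q) quantiles, q counting only
cluster-level covariate parameters (the arm indicator is not counted).
If the exchangeable fit fails to converge the model is refitted with an
independence working correlation — the sandwich variance remains valid —
and only a failure of both is an error.

**Interactions.** When the covariate effect may differ by arm, the design
is (1, arm, X*, arm·X*) with X* = X − X̄ centred at the all-individuals
mean (missing outcomes included, since X is always observed), so the arm
coefficient targets the effect at the covariate mean. No variance
correction is made for estimating X̄; coverage in the harness confirms this
is benign at the simulated sizes.

## Multilevel multiple imputation

The imputation model is a random-intercept *probit* regression fitted by
Gibbs sampling with latent-variable data augmentation: observed outcomes
truncate their latent normals to (0,∞) or (−∞,0) (sampled by inverse CDF
through ndtr/ndtri, which is safe far into the tails), missing outcomes
contribute untruncated draws, coefficients and cluster effects have normal
full conditionals, and τ² an inverse-gamma one. Priors: flat on
coefficients, inverse-gamma(0.001, 0.001) on τ² — weakly informative; at
the simulated sizes (≥5 clusters/arm, m = 50) the likelihood dominates.
Probit rather than logit keeps every full conditional conjugate; for
success probabilities away from the extremes the two links give near
identical imputations, and the mild uncongeniality with the logit analysis
models is accepted (coverage confirms it is not harmful here). Defaults:
Q = 15 imputations, 100 burn-in iterations, thinning 25.

A cluster with no observed outcomes still receives a random effect (its
full conditional given its latent draws), so its missing outcomes are
imputed from the fixed effects plus a prior-consistent cluster effect.

Pooling follows Rubin's rules with T = W + (1+1/Q)B. Because the
complete-data df in a CRT is the small ν_com = 2k−2, the classical MI df
υ = (Q−1)(1 + QW/((Q+1)B))² can absurdly exceed it; intervals therefore
use the Barnard–Rubin ν_adj = (1/υ + 1/ν̂_obs)⁻¹ with
ν̂_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1 + (1+1/Q)B/W)⁻¹, which satisfies
ν_adj ≤ ν_com. B = 0 (all imputations identical) gives υ = ∞ and
ν_adj = ν̂_obs; W = 0 with B > 0 is an error. Ratio effects (RR, OR) are
pooled on the log scale, the standard choice for approximately normal
pooling.

A failed estimator on any single completed dataset fails that replicate's
MMI analysis outright — quietly pooling fewer than Q results would bias B.

## Simulation harness

Replications are seeded by (root seed, k, replication index) through
SeedSequence spawning, with separate substreams for covariates/outcomes,
missingness and the imputation chain — results are independent of any
parallel execution order, and the same full dataset underlies full-data,
CRA and MMI handling within a replicate. One imputation run per replicate
is shared by all pooled estimators. Truth values: RD and log RR from the
quadrature success rates; conditional log OR = β1; the marginal
(population-averaged) log OR has no closed form under a logit
random-intercept model (non-collapsibility) and is estimated as the mean
full-data GEE coefficient over replications. Per-cell outputs are the mean
estimate, its MC error (SD/√n), mean estimated SE, coverage of nominal 95%
t intervals, and failure counts; cells losing >10% of replicates are
flagged.

The validity-condition oracle draws (X, δ, R) and compares E[g_i|R=1]
(difference form) or E[h_i|R=1] (ratio form) between arms, with delta-method
MC errors for the ratio; a condition is declared satisfied when the
statistic is within 3 MC SEs of its null value. A discretised-grid oracle
in the tests confirms the MC implementation.

## Problem sizes and tolerances

The replicated experiments in the tests and the acceptance script use 300
replications of the S1, k = 50, m = 50 design (and 300 replications at
k = 5 for the small-sample MMI coverage check). At 300 replications the MC
SE of a mean log-OR estimate is ≈0.007 and of a coverage percentage ≈1.3
points, so bias assertions use 3 MC SE bands (±0.02–0.03 on the log-OR
scale) and coverage assertions ±4 points. The ICC estimator runs at 2000
clusters × 500 individuals per arm. Quadrature tolerances are effectively
exact at 64 nodes. The stage-one logistic convergence tolerance is 1e-10
on the IRLS deviance with a 1e-6 score-norm check; RELR optimisation uses
ftol 1e-12 / gtol 1e-8.

## What the generator does and does not emulate

The generator produces balanced designs, a single normally decomposed
continuous covariate, normal random intercepts on the link scale, and
individually independent CDM missingness. Real CRTs add unequal cluster
sizes, multiple and categorical covariates, covariate measurement error,
non-normal cluster effects, and missingness that may depend on outcomes
(MNAR) or cluster-level shocks. Passing tests therefore demonstrate the
estimators' behaviour under the stated mechanism — they do not certify
robustness to MNAR or model misspecification, which is precisely the
distinction the validity conditions formalise.

## Known limitations

- RD/RR from RELR/GEE by integrating over effects is not implemented
  (out of scope); cluster-level analyses are the RD/RR route.
- One individual-level covariate in the estimators (the schema reserves
  room for more).
- The GEE engine has no external oracle in the tests (R geepack is not
  available in the pinned environment); it is validated through its
  degenerate equivalence to ordinary logistic regression and through the
  replicated-simulation benchmarks.
- MMI assumes the covariate fully observed; missing covariates need a
  joint imputation model this package does not provide.
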