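# crtmiss

Missing binary outcomes are routine in cluster randomised trials (CRTs):
outcomes are collected on individuals, but randomisation — and therefore
inference — operates at the level of clusters (practices, schools,
communities). When the probability that an outcome is missing depends on a
fully observed baseline covariate (covariate-dependent missingness, CDM — a
special case of MAR), the familiar analysis choices behave very differently:
complete-records analysis (CRA) can be badly biased for some estimands and
valid for others, while multilevel multiple imputation (MMI) restores
validity at the cost of extra machinery.

`crtmiss` is a simulator + estimator suite for studying exactly this. It is
aimed at trial statisticians and methodologists who want to check, for a
design like theirs, which estimator/missing-data-handling combination is
trustworthy.

## What is in the box

**Data generation** (`crtmiss.dgm`). Outcomes follow a random-intercept
model with logit (or log) link,

    g(π_ijl) = β0 + β1·i + β2(i)·X_ijl + δ_ij,     δ_ij ~ N(0, σb²),

for individual *l* in cluster *j* of arm *i*, with a covariate
X_ijl = α_ij + u_ijl split into cluster (α ~ N(μx, σα²)) and individual
(u ~ N(0, σu²)) components. Missingness is imposed per individual with
logit P(R=0) = ψ_i + ϕ_i·X_ijl. Four scenario presets (S1–S4) cross
same/different covariate effects with same/different missingness mechanisms
between arms; quadrature oracles give the exact marginal success rates,
expected missingness and outcome ICCs implied by any configuration.

**Estimators.**

* Cluster-level, unadjusted (CL_U): RD = p̄₁ − p̄₀ and RR = p̄₁/p̄₀ from
  cluster proportions, two-sample *t* inference with 2k − 2 df.
* Cluster-level, covariate-adjusted (CL_A): a covariate-only logistic
  regression (no arm term, clustering ignored) predicts each cluster's
  successes; difference residuals (N − N̂)/m give RD, ratio residuals N/N̂
  give RR.
* RELR: random-intercept logistic regression (conditional log OR), maximum
  likelihood via adaptive Gauss–Hermite quadrature (15 nodes), *t*(2k−2)
  intervals.
* GEE: logistic estimating equations with exchangeable working correlation
  (marginal log OR), sandwich variance inflated by k/(k−1), *t*(2k−2−q)
  intervals.

**Missing-data handling.** Every estimator runs on full data, complete
records, or MMI: a Bayesian random-intercept *probit* imputation model
fitted by Gibbs sampling with latent-variable data augmentation (Q = 15
imputations, 100 burn-in, thinning 25 by default), pooled by Rubin's rules
with the Barnard–Rubin adjusted degrees of freedom (ν_adj ≤ 2k − 2).

**Evaluation** (`crtmiss.evaluation`). A replicated-simulation harness
(bias, average SE, coverage per scenario × k × method × handling) and a
Monte-Carlo oracle for the analytic validity conditions of complete-records
cluster-level analysis: writing π_ijl = π_i + g_i(X, δ) or
π_ijl = π_i·h_i(X, δ), CRA is unbiased for RD iff
E[g₁|R=1] = E[g₀|R=1] and consistent for RR iff E[h₁|R=1]/E[h₀|R=1] = 1.

## Worked example

```python
import numpy as np
from crtmiss import dgm, cluster_level as cl, individual_level as il, mmi

cfg, mcfg = dgm.scenario_preset("S1", k=20, m=50)   # 20 clusters/arm, size 50
full = dgm.simulate_full_data(cfg, seed=7)
obs  = dgm.impose_cdm_missingness(full, mcfg, seed=8)
print(round(obs.n_missing / obs.n_records, 3))

rd_cra = cl.estimate_rd_unadjusted(cl.cluster_summaries(obs, "complete_records"))
print(round(rd_cra.estimate, 3), (round(rd_cra.ci_low, 3), round(rd_cra.ci_high, 3)))

relr = il.fit_relr(obs, il.build_design(obs), "complete_records")
print(round(relr.effect.estimate, 3), round(relr.effect.se, 3))

pooled = mmi.analyze_with_mmi(obs, "cl_u_rd", mmi.ImputationConfig(seed=9))
print(round(pooled.estimate, 3), round(pooled.nu_adj, 1))
```

prints

```
0.275
0.279 (0.194, 0.364)
1.607 0.252
0.273 34.3
```

Under S1 the true risk difference is 0.200 (quadrature: success rates 0.50
and 0.70) and the true conditional log OR is 1.36; about 30% of outcomes go
missing. These are single-replicate numbers, so all three estimates sit
within sampling noise of their targets (RELR: 1.607 with SE 0.252), and the
MMI-pooled RD comes with a Barnard–Rubin df of 34.3 (< 2k − 2 = 38). The
systematic story — complete-records cluster-level RD biased upward because
CDM removes high-covariate individuals and the RD validity condition fails
under a logit-link truth, RELR/GEE on complete records unbiased because the
covariate driving missingness is in the model, MMI restoring unbiasedness
of the cluster-level estimators — emerges over replications, which is what
`crtmiss.evaluation.run_study` and the test suite quantify.

The same analyses are available from the shell:

```
crtmiss simulate --scenario S1 --k 20 --m 50 --seed 7 --out data.csv
crtmiss analyze data.csv --method relr --handle cra
crtmiss study --scenario S1 --reps 1000 --k 5,10,20,50 --seed 2017 --out results.csv
```

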