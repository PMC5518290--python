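"""Individual-level analysis of binary CRT outcomes.

Two regression approaches are provided:

* **RELR** — random-effects (random-intercept) logistic regression,
  estimating the cluster-specific (conditional) log odds ratio.  The
  marginal likelihood integrates the cluster random effect out of the
  logistic likelihood; we maximise it with adaptive Gauss-Hermite
  quadrature (default 15 nodes), re-centring the nodes at each cluster's
  posterior mode.
* **GEE** — generalised estimating equations with an exchangeable working
  correlation, estimating the population-averaged (marginal) log odds
  ratio.  With few clusters the sandwich variance is biased downwards, so
  it is inflated by k/(k-1) (k clusters per arm) and confidence intervals
  use t quantiles with 2k - 2 degrees of freedom (2k - 2 - q when q
  cluster-level covariate parameters are in the model).

When the covariate effect may differ between arms, the design includes
the empirically centred covariate X* = X - Xbar and its interaction with
the arm indicator, so the arm coefficient is the effect at the covariate
mean.  Xbar is computed over *all* individuals, including those whose
outcome is missing, since the covariate is always observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .datamodel import EffectEstimate, TrialDataset, complete_records
from .cluster_level import EstimationError

__all__ = [
    "DesignSpec",
    "FitResult",
    "build_design",
    "fit_relr",
    "fit_gee",
    "empirical_marginal_logor",
]

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class DesignSpec:
    """Fixed-effects design for the individual-level models.

    Columns are (intercept, arm, X) without interaction, or
    (intercept, arm, X*, arm*X*) with it, X* being the covariate centred
    at the all-individuals mean ``xbar``.
    """

    include_interaction: bool
    x_centered: bool
    xbar: float

    @property
    def column_names(self) -> list[str]:
        if self.include_interaction:
            return ["intercept", "arm", "x_c", "arm:x_c"]
        return ["intercept", "arm", "x"]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        arm = df["arm"].to_numpy(dtype=float)
        x = df["x"].to_numpy(dtype=float)
        if self.x_centered:
            x = x - self.xbar
        cols = [np.ones_like(arm), arm, x]
        if self.include_interaction:
            cols.append(arm * x)
        return np.column_stack(cols)


def build_design(data: TrialDataset, interaction: bool = False) -> DesignSpec:
    """Design for RELR/GEE; with ``interaction`` the covariate is centred
    so that the arm coefficient targets the effect at the covariate mean."""
    xbar = float(data.df["x"].mean())  # all individuals, missing outcomes included
    return DesignSpec(include_interaction=interaction, x_centered=interaction, xbar=xbar)


@dataclass
class FitResult:
    """A fitted individual-level model.

    ``effect`` holds the arm coefficient with its t-based interval;
    ``params``/``cov`` are the full coefficient vector and its variance
    matrix (after any small-sample correction).  ``sigma_b`` is the
    random-intercept SD for RELR; ``working_corr`` the estimated
    exchangeable correlation for GEE.
    """

    effect: EffectEstimate
    params: np.ndarray
    cov: np.ndarray
    column_names: list[str]
    converged: bool
    n_iterations: int
    method: str
    sigma_b: float | None = None
    working_corr: float | None = None
    se_uncorrected: float | None = None


def _analysis_frame(data: TrialDataset, use: str) -> pd.DataFrame:
    if use == "complete_records":
        return complete_records(data).df
    if use == "full":
        if data.n_missing:
            raise EstimationError("full-data analysis requested on an incomplete dataset")
        return data.df
    raise ValueError(f"use must be 'full' or 'complete_records', got {use!r}")


def _cluster_codes(df: pd.DataFrame) -> tuple[np.ndarray, int, tuple[int, int]]:
    key = df["arm"].to_numpy() * (df["cluster"].to_numpy().max() + 1) + df["cluster"].to_numpy()
    codes, uniques = pd.factorize(key, sort=True)
    k0 = df.loc[df["arm"] == 0, "cluster"].nunique()
    k1 = df.loc[df["arm"] == 1, "cluster"].nunique()
    return codes.astype(np.intp), len(uniques), (int(k0), int(k1))


# ---------------------------------------------------------------------------
# RELR: random-intercept logistic regression by adaptive Gauss-Hermite ML
# ---------------------------------------------------------------------------

class _RELRLikelihood:
    """Negative marginal log-likelihood of the random-intercept logistic
    model, evaluated by adaptive Gauss-Hermite quadrature.

    Parameter vector: (beta, log sigma_b).  The per-cluster posterior
    modes of the random effect are cached between calls so the inner
    Newton iteration warm-starts during optimisation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 n_clusters: int, n_nodes: int = 15):
        self.y = y
        self.X = X
        self.codes = codes
        self.n_clusters = n_clusters
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = z
        self.logw = np.log(w) + z ** 2  # for the exp(z^2)-rescaled AGQ weights
        self._mode = np.zeros(n_clusters)

    def _cluster_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.codes, weights=values, minlength=self.n_clusters)

    def __call__(self, params: np.ndarray) -> float:
        beta = params[:-1]
        sigma = math.exp(params[-1])
        sigma2 = sigma * sigma
        eta = self.X @ beta

        # posterior mode of each cluster's random effect (1-D Newton)
        b = self._mode.copy()
        for _ in range(50):
            mu = special.expit(eta + b[self.codes])
            g1 = self._cluster_sum(self.y - mu) - b / sigma2
            g2 = -self._cluster_sum(mu * (1.0 - mu)) - 1.0 / sigma2
            step = g1 / g2
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._mode = b
        mu = special.expit(eta + b[self.codes])
        curv = self._cluster_sum(mu * (1.0 - mu)) + 1.0 / sigma2  # -g''(bhat)
        tau = 1.0 / np.sqrt(curv)

        # nodes b_q = bhat + sqrt(2) tau z_q, log integrand per cluster/node
        bq = b[None, :] + _SQRT2 * tau[None, :] * self.z[:, None]  # (Q, J)
        eta_q = eta[None, :] + bq[:, self.codes]
        ll_obs = self.y[None, :] * eta_q - np.logaddexp(0.0, eta_q)
        ll_clust = np.vstack([self._cluster_sum(ll_obs[q]) for q in range(len(self.z))])
        log_prior = -0.5 * (bq / sigma) ** 2 - math.log(sigma) - _LOG_SQRT_2PI
        log_terms = (self.logw[:, None] + np.log(_SQRT2 * tau)[None, :]
                     + ll_clust + log_prior)
        ll = special.logsumexp(log_terms, axis=0).sum()
        return -float(ll)


def fit_relr(data: TrialDataset, design: DesignSpec, use: str = "full",
             n_nodes: int = 15, maxiter: int = 200) -> FitResult:
    """Maximum-likelihood random-intercept logistic regression.

    The optimiser is L-BFGS-B on (beta, log sigma_b); standard errors
    come from the inverse of a numerically differentiated Hessian at the
    optimum.  The arm-coefficient confidence interval uses t quantiles
    with 2k - 2 degrees of freedom.  sigma_b is allowed to shrink to
    (numerically) zero, in which case the model collapses to ordinary
    logistic regression.
    """
    df = _analysis_frame(data, use)
    y = df["y"].to_numpy(dtype=float)
    X = design.matrix(df)
    codes, n_clusters, (k0, k1) = _cluster_codes(df)
    if k0 < 2 or k1 < 2:
        raise EstimationError("need at least 2 clusters per arm")

    # starting values: ordinary logistic fit, modest random-effect SD
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50).params
    x0 = np.append(start_beta, math.log(0.3))

    nll = _RELRLikelihood(y, X, codes, n_clusters, n_nodes=n_nodes)
    bounds = [(None, None)] * X.shape[1] + [(math.log(1e-4), math.log(50.0))]
    opt = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})

    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(opt.x, nll)
    p = X.shape[1]
    try:
        cov_full = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(hess)
    cov = cov_full[:p, :p]
    if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov) <= 0):
        # sigma_b at the boundary can make the joint Hessian near-singular;
        # fall back to the beta-block Hessian with log sigma held fixed
        hb = approx_hess1(opt.x[:p], lambda b: nll(np.append(b, opt.x[-1])))
        cov = np.linalg.pinv(hb)

    params = opt.x[:p]
    sigma_b = math.exp(opt.x[-1])
    arm_idx = design.column_names.index("arm")
    df_t = k0 + k1 - 2
    effect = EffectEstimate.from_t("logOR_conditional", params[arm_idx],
                                   math.sqrt(cov[arm_idx, arm_idx]), df_t, (k0, k1))
    return FitResult(effect=effect, params=params, cov=cov,
                     column_names=design.column_names, converged=bool(opt.success),
                     n_iterations=int(opt.nit), method="relr", sigma_b=sigma_b)


# ---------------------------------------------------------------------------
# GEE with exchangeable working correlation and small-sample correction
# ---------------------------------------------------------------------------

def fit_gee(data: TrialDataset, design: DesignSpec, use: str = "full",
            n_cluster_level_covariates: int = 0,
            correction: str = "variance") -> FitResult:
    """Logistic GEE with exchangeable working correlation.

    The robust (sandwich) variance is multiplied by k/(k-1), k being the
    number of clusters per arm, to offset its small-sample downward bias
    (``correction="se"`` applies the factor to the SE instead, an
    alternative reading of the same correction).  Confidence intervals use
    t quantiles with 2k - 2 - q degrees of freedom, q counting
    cluster-level covariate parameters only.  If the exchangeable fit
    fails to converge the model is refitted with an independence working
    correlation.
    """
    df = _analysis_frame(data, use)
    y = df["y"].to_numpy(dtype=float)
    X = design.matrix(df)
    codes, _, (k0, k1) = _cluster_codes(df)
    if k0 < 2 or k1 < 2:
        raise EstimationError("need at least 2 clusters per arm")

    res = None
    working = None
    for cov_struct in (sm.cov_struct.Exchangeable(), sm.cov_struct.Independence()):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(y, X, groups=codes, family=sm.families.Binomial(),
                               cov_struct=cov_struct)
                cand = model.fit(maxiter=100)
            if np.all(np.isfinite(cand.params)) and np.all(np.isfinite(cand.bse)):
                res = cand
                working = cov_struct
                break
        except Exception:
            continue
    if res is None:
        raise EstimationError("GEE failed to converge with exchangeable and "
                              "independence working correlation")

    k_per_arm = 0.5 * (k0 + k1)
    factor = k_per_arm / (k_per_arm - 1.0)
    cov = np.asarray(res.cov_params())
    arm_idx = design.column_names.index("arm")
    se_raw = math.sqrt(cov[arm_idx, arm_idx])
    if correction == "variance":
        cov = cov * factor
    elif correction == "se":
        cov = cov * factor ** 2
    else:
        raise ValueError("correction must be 'variance' or 'se'")

    df_t = k0 + k1 - 2 - n_cluster_level_covariates
    effect = EffectEstimate.from_t("logOR_marginal", float(res.params[arm_idx]),
                                   math.sqrt(cov[arm_idx, arm_idx]), df_t, (k0, k1))
    alpha = None
    if isinstance(working, sm.cov_struct.Exchangeable):
        alpha = float(working.dep_params)
    return FitResult(effect=effect, params=np.asarray(res.params), cov=cov,
                     column_names=design.column_names, converged=True,
                     n_iterations=0, method="gee", working_corr=alpha,
                     se_uncorrected=se_raw)


def empirical_marginal_logor(cfg, reps: int, k: int, m: int, seed,
                             interaction: bool = False) -> tuple[float, float]:
    """Empirical population-averaged log OR: mean full-data GEE arm
    coefficient over simulated replications, with its Monte-Carlo SE.

    Because the odds ratio is non-collapsible this marginal target is
    smaller in magnitude than the conditional coefficient beta1 used to
    generate the data; it has no closed form and is estimated by
    simulation, as done when benchmarking GEE.
    """
    from dataclasses import replace

    from . import dgm

    ss = np.random.SeedSequence(seed)
    cfg = replace(cfg, k=k, m=m)
    estimates = []
    for child in ss.spawn(reps):
        data = dgm.simulate_full_data(cfg, np.random.default_rng(child))
        design = build_design(data, interaction=interaction)
        fit = fit_gee(data, design, use="full")
        estimates.append(fit.effect.estimate)
    est = np.asarray(estimates)
    return float(est.mean()), float(est.std(ddof=1) / math.sqrt(reps))
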