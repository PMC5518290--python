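"""Multilevel multiple imputation (MMI) of missing binary outcomes.

The imputation model is a Bayesian random-intercept probit regression

    P(Y_ijl = 1 | b_ij) = Phi(w_ijl' gamma + b_ij),   b_ij ~ N(0, tau^2),

fitted by Gibbs sampling with latent-variable data augmentation: each
binary outcome corresponds to a latent normal z = w'gamma + b + e,
e ~ N(0, 1), observed outcomes truncating z to (0, inf) or (-inf, 0).
Missing outcomes contribute untruncated latent draws, so the sampler
targets the joint posterior given the observed data only.  Priors are an
improper flat prior on gamma and inverse-gamma(0.001, 0.001) on tau^2.

Q completed datasets are taken from the chain every ``thin`` iterations
after ``burn_in``, each missing outcome drawn as Bernoulli(Phi(w'gamma +
b)) at the retained iteration.  Completed-data analyses are combined with
Rubin's rules; because the complete-data degrees of freedom in a CRT is
the small 2k - 2 rather than infinity, intervals use the Barnard-Rubin
adjusted degrees of freedom, which never exceeds 2k - 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import PooledEstimate, TrialDataset

__all__ = [
    "ImputationConfig",
    "ImputedSet",
    "GibbsState",
    "gibbs_probit_fit",
    "impute",
    "rubin_pool",
    "analyze_with_mmi",
    "MMIError",
]


class MMIError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    """Sampler settings.  Defaults: Q = 15 imputations, 100 burn-in
    iterations, thinning 25 between retained draws."""

    Q: int = 15
    burn_in: int = 100
    thin: int = 25
    include_interaction: bool = False
    prior_a: float = 0.001  # inverse-gamma shape for tau^2
    prior_b: float = 0.001  # inverse-gamma scale for tau^2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.Q < 2:
            raise ValueError("Q must be >= 2")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")


@dataclass
class GibbsState:
    """One retained state of the probit Gibbs sampler."""

    gamma: np.ndarray
    b: np.ndarray          # cluster effects, one per cluster (both arms)
    tau2: float
    iteration: int


@dataclass
class ImputedSet:
    """Q completed datasets plus chain diagnostics (coefficient and
    variance traces at the retained iterations)."""

    datasets: list
    states: list
    column_names: list[str]

    @property
    def Q(self) -> int:
        return len(self.datasets)


def _imputation_design(data: TrialDataset, include_interaction: bool):
    import pandas as pd

    df = data.df
    arm = df["arm"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    if include_interaction:
        xc = x - x.mean()  # centred over all individuals
        W = np.column_stack([np.ones_like(arm), arm, xc, arm * xc])
        names = ["intercept", "arm", "x_c", "arm:x_c"]
    else:
        W = np.column_stack([np.ones_like(arm), arm, x])
        names = ["intercept", "arm", "x"]
    key = df["arm"].to_numpy() * (df["cluster"].to_numpy().max() + 1) + df["cluster"].to_numpy()
    codes, _ = pd.factorize(key, sort=True)
    return W, names, codes.astype(np.intp)


def _truncnorm_draw(mu: np.ndarray, lower: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw z ~ N(mu, 1) truncated to z > 0 where lower, z < 0 where not,
    by inverse-CDF sampling (numerically safe via the ndtr/ndtri pair)."""
    from scipy.special import ndtr, ndtri

    u = rng.random(mu.shape)
    # P(Z <= -mu) = ndtr(-mu); positive-truncated draw uses the upper tail
    p_neg = ndtr(-mu)
    q = np.where(lower, p_neg + u * (1.0 - p_neg), u * p_neg)
    q = np.clip(q, 1e-15, 1.0 - 1e-15)
    return mu + ndtri(q)


def gibbs_probit_fit(data: TrialDataset, cfg: ImputationConfig):
    """Run the data-augmentation Gibbs sampler; yields a
    :class:`GibbsState` at every retained iteration (after burn-in, every
    ``thin`` steps, Q states in total).

    Clusters with no observed outcomes still receive a random effect
    (their full conditional reduces to the N(0, tau^2) prior given their
    latent draws), so imputation in such clusters borrows strength from
    the fitted fixed effects plus a prior-draw cluster effect.
    """
    from scipy.special import ndtr

    rng = np.random.default_rng(cfg.seed)
    W, names, codes = _imputation_design(data, cfg.include_interaction)
    y = data.df["y"].to_numpy(dtype=float)
    observed = data.df["r"].to_numpy() == 1
    y_pos = observed & (y == 1.0)
    n_clusters = int(codes.max()) + 1
    n, p = W.shape

    arm = data.df["arm"].to_numpy()
    for i in (0, 1):
        if not observed[arm == i].any():
            raise MMIError(f"arm {i} has no observed outcomes")

    WtW = W.T @ W
    WtW_inv = np.linalg.inv(WtW)
    chol = np.linalg.cholesky(WtW_inv)
    cluster_sizes = np.bincount(codes, minlength=n_clusters).astype(float)

    # initial values: gamma from a crude least-squares on +/-1 scores,
    # cluster effects zero, tau^2 moderate
    score = np.where(y_pos, 1.0, -1.0) * observed
    gamma = WtW_inv @ (W.T @ score)
    b = np.zeros(n_clusters)
    tau2 = 0.1
    z = np.zeros(n)

    n_iter = cfg.burn_in + cfg.thin * cfg.Q
    retained = 0
    for it in range(1, n_iter + 1):
        mu = W @ gamma + b[codes]
        # (i)/(v) latent normals: truncated at observed outcomes, free at missing
        z_trunc = _truncnorm_draw(mu[observed], y_pos[observed], rng)
        z[observed] = z_trunc
        z[~observed] = mu[~observed] + rng.standard_normal((~observed).sum())
        # (ii) coefficients
        resid = z - b[codes]
        mean_gamma = WtW_inv @ (W.T @ resid)
        gamma = mean_gamma + chol @ rng.standard_normal(p)
        # (iii) cluster effects
        s = np.bincount(codes, weights=z - W @ gamma, minlength=n_clusters)
        prec = cluster_sizes + 1.0 / tau2
        b = s / prec + rng.standard_normal(n_clusters) / np.sqrt(prec)
        # (iv) random-effect variance
        shape = cfg.prior_a + 0.5 * n_clusters
        scale = cfg.prior_b + 0.5 * float(b @ b)
        tau2 = scale / rng.gamma(shape)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            retained += 1
            yield GibbsState(gamma=gamma.copy(), b=b.copy(), tau2=float(tau2),
                             iteration=it)
            if retained == cfg.Q:
                return


def impute(data: TrialDataset, cfg: ImputationConfig) -> ImputedSet:
    """Produce Q completed datasets.

    Observed outcomes are carried through unchanged; each missing outcome
    is drawn as Bernoulli(Phi(w'gamma + b_cluster)) at the retained Gibbs
    iterations.  With nothing missing this returns Q identical copies.
    """
    from scipy.special import ndtr

    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    W, names, codes = _imputation_design(data, cfg.include_interaction)
    missing = data.df["r"].to_numpy() == 0
    datasets, states = [], []
    for state in gibbs_probit_fit(data, cfg):
        states.append(state)
        completed = data.df.copy()
        if missing.any():
            mu = W[missing] @ state.gamma + state.b[codes[missing]]
            draw = (rng.random(missing.sum()) < ndtr(mu)).astype(float)
            completed.loc[missing, "y"] = draw
        completed["r"] = 1
        datasets.append(TrialDataset(completed, k=data.k, m=data.m))
    return ImputedSet(datasets=datasets, states=states, column_names=names)


def rubin_pool(estimates, variances, nu_com: float, scale: str = "RD",
               alpha: float = 0.05) -> PooledEstimate:
    """Combine Q completed-data analyses with Rubin's rules.

    total variance  T = W + (1 + 1/Q) B
    classical df    upsilon = (Q-1) (1 + Q W / ((Q+1) B))^2
    Barnard-Rubin   nu_adj = (1/upsilon + 1/nu_obs)^{-1}  with
    nu_obs = ((nu_com+1)/(nu_com+3)) nu_com (1 + (1+1/Q) B / W)^{-1},
    so that nu_adj <= nu_com always.  B = 0 gives upsilon = +inf and
    nu_adj = nu_obs.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    Q = len(est)
    if Q < 2 or len(var) != Q:
        raise ValueError("need Q >= 2 estimates with matching variances")
    qbar = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    if W == 0.0 and B > 0.0:
        raise MMIError("degenerate pooling: zero within-imputation variance "
                       "with positive between-imputation variance")
    total = W + (1.0 + 1.0 / Q) * B
    if B > 0.0:
        try:
            upsilon = (Q - 1.0) * (1.0 + Q * W / ((Q + 1.0) * B)) ** 2
        except OverflowError:  # B negligible relative to W: effectively B = 0
            upsilon = math.inf
        nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com / (1.0 + ((Q + 1.0) / Q) * B / W)
        nu_adj = 1.0 / (1.0 / upsilon + 1.0 / nu_obs)
    else:
        upsilon = math.inf
        nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com
        nu_adj = nu_obs
    se = math.sqrt(total)
    tq = stats.t.ppf(1.0 - alpha / 2.0, nu_adj)
    return PooledEstimate(scale=scale, estimate=qbar, W=W, B=B, Q=Q,
                          total_var=total, upsilon=upsilon, nu_com=float(nu_com),
                          nu_adj=float(nu_adj), ci_low=qbar - tq * se,
                          ci_high=qbar + tq * se)


# estimator registry: name -> callable(TrialDataset) -> (estimate, variance, scale)
def _run_estimator(name: str, data: TrialDataset, interaction: bool):
    from . import cluster_level as cl
    from . import individual_level as il

    if name == "cl_u_rd":
        e = cl.estimate_rd_unadjusted(cl.cluster_summaries(data, "full"))
    elif name == "cl_u_rr":
        e = cl.estimate_rr_unadjusted(cl.cluster_summaries(data, "full"))
    elif name == "cl_a_rd":
        e = cl.estimate_rd_adjusted(data, "full")
    elif name == "cl_a_rr":
        e = cl.estimate_rr_adjusted(data, "full")
    elif name == "relr":
        e = il.fit_relr(data, il.build_design(data, interaction), "full").effect
    elif name == "gee":
        e = il.fit_gee(data, il.build_design(data, interaction), "full").effect
    else:
        raise ValueError(f"unknown estimator {name!r}")
    return e.estimate, e.se ** 2, e.scale


def pool_over_imputed(imputed: ImputedSet, analysis: str, nu_com: float,
                      interaction: bool = False) -> PooledEstimate:
    """Run one estimator on each completed dataset of an existing
    :class:`ImputedSet` and pool with Rubin's rules.

    Ratio effects are pooled on the log scale.  A failure of the
    estimator on any completed dataset fails the whole analysis (silently
    dropping imputations would bias the between-imputation variance).
    """
    estimates, variances, scale = [], [], None
    for d in imputed.datasets:
        est, var, scale = _run_estimator(analysis, d, interaction)
        estimates.append(est)
        variances.append(var)
    return rubin_pool(estimates, variances, nu_com=nu_com, scale=scale)


def analyze_with_mmi(data: TrialDataset, analysis: str, cfg: ImputationConfig,
                     interaction: bool = False) -> PooledEstimate:
    """Impute Q times, run one estimator on each completed dataset and
    pool with nu_com = 2k - 2."""
    imputed = impute(data, cfg)
    return pool_over_imputed(imputed, analysis, nu_com=2 * data.k - 2,
                             interaction=interaction)
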