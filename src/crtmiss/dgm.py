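"""Data-generating mechanisms for two-arm CRTs with covariate-dependent
missingness (CDM).

Outcome model.  For individual l in cluster j of arm i the success
probability is

    g(pi_ijl) = beta0 + beta1 * i + beta2_i * X_ijl + delta_ij

with link g either logit or log, cluster effect delta_ij ~ N(0, sigma_b2)
and a continuous baseline covariate decomposed into a cluster effect and
an individual deviation,

    X_ijl = alpha_ij + u_ijl,   alpha_ij ~ N(mu_x, sigma_alpha2),
                                u_ijl   ~ N(0, sigma_u2),

so Var(X) = sigma_alpha2 + sigma_u2 and the covariate intraclass
correlation is rho_x = sigma_alpha2 / (sigma_alpha2 + sigma_u2).

Missingness model.  Outcomes go missing independently with probability

    P(R_ijl = 0 | X_ijl) = expit(psi_i + phi_i * X_ijl),

i.e. missingness depends on the baseline covariate only (a special case
of MAR since X is fully observed).

Scenario presets S1-S4 cross two factors: whether the covariate effect
beta2 and the missingness intercept psi are the same in the two arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special

from .datamodel import TrialDataset

__all__ = [
    "DGMConfig",
    "MissingnessConfig",
    "ConfigError",
    "simulate_full_data",
    "impose_cdm_missingness",
    "scenario_preset",
    "marginal_success_probability",
    "expected_missing_proportion",
    "estimate_outcome_icc",
    "calibrate_psi",
    "SCENARIOS",
]

_X_TRUNC_SD = 4.0  # log-link guard: X truncated at mu_x +/- 4 sd(X)
_GH_NODES = 64


class ConfigError(ValueError):
    """Invalid generative configuration."""


@dataclass(frozen=True)
class DGMConfig:
    """Generative parameters of the outcome and covariate models.

    ``beta2`` is a per-arm pair (control, intervention) so the covariate
    effect may differ between arms; ``link`` is ``"logit"`` or ``"log"``.
    """

    beta0: float
    beta1: float
    beta2: tuple[float, float]
    sigma_b2: float
    mu_x: float
    sigma_alpha2: float
    sigma_u2: float
    k: int
    m: int
    link: str = "logit"

    @property
    def sigma_x2(self) -> float:
        return self.sigma_alpha2 + self.sigma_u2

    @property
    def rho_x(self) -> float:
        return self.sigma_alpha2 / self.sigma_x2

    def __post_init__(self) -> None:
        if self.link not in ("logit", "log"):
            raise ConfigError(f"unknown link {self.link!r}")
        if self.sigma_u2 <= 0 or self.sigma_alpha2 < 0 or self.sigma_b2 < 0:
            raise ConfigError("variance components must be non-negative (sigma_u2 > 0)")
        if self.link == "log":
            # With X truncated at +/- 4 sd and delta at +/- 4 sd_b the
            # largest linear predictor must stay negative so pi < 1.
            sx = math.sqrt(self.sigma_x2)
            sb = math.sqrt(self.sigma_b2)
            for i in (0, 1):
                b2 = self.beta2[i]
                lp_max = (self.beta0 + self.beta1 * i
                          + max(b2 * (self.mu_x - _X_TRUNC_SD * sx),
                                b2 * (self.mu_x + _X_TRUNC_SD * sx))
                          + _X_TRUNC_SD * sb)
                if lp_max >= 0:
                    raise ConfigError(
                        f"log link: max linear predictor {lp_max:.3f} >= 0 in arm {i}; "
                        "success probabilities would exceed 1"
                    )


@dataclass(frozen=True)
class MissingnessConfig:
    """Per-arm intercepts ``psi`` and covariate slopes ``phi`` of the
    CDM logistic model for P(R = 0)."""

    psi: tuple[float, float]
    phi: tuple[float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.psi)) or not all(np.isfinite(self.phi)):
            raise ConfigError("psi and phi must be finite")


# Common core of the published simulation scenarios: logit link,
# mu_x = 0, sigma_u2 = 3.37, sigma_alpha2 = 0.18 (so sigma_x2 = 3.55,
# rho_x ~ 0.05), sigma_b2 = 0.20, beta0 = 0, beta1 = 1.36, phi = 1, m = 50.
def _core(beta2: tuple[float, float], k: int, m: int) -> DGMConfig:
    return DGMConfig(beta0=0.0, beta1=1.36, beta2=beta2, sigma_b2=0.20,
                     mu_x=0.0, sigma_alpha2=0.18, sigma_u2=3.37,
                     k=k, m=m, link="logit")


SCENARIOS = {
    # name -> (beta2 pair, psi pair); phi = (1, 1) throughout
    "S1": ((1.0, 1.0), (-1.34, -1.34)),
    "S2": ((1.0, 1.0), (-1.34, 0.65)),
    "S3": ((0.588, 1.0), (-1.34, -1.34)),
    "S4": ((0.588, 1.0), (-1.34, 0.65)),
}


def scenario_preset(name: str, k: int = 50, m: int = 50) -> tuple[DGMConfig, MissingnessConfig]:
    """Return the published parameterisation of scenario S1, S2, S3 or S4.

    S1/S2 share the covariate effect between arms (beta2 = 1 in both);
    S3/S4 use beta2 = (0.588, 1).  S1/S3 share the missingness mechanism
    (psi = -1.34, ~30% missing in both arms); S2/S4 raise the
    intervention-arm intercept to psi1 = 0.65 (~60% missing).
    """
    try:
        beta2, psi = SCENARIOS[name]
    except KeyError:
        raise ConfigError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")
    return _core(beta2, k, m), MissingnessConfig(psi=psi, phi=(1.0, 1.0))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _linear_predictor(cfg: DGMConfig, arm: int, x: np.ndarray, delta: np.ndarray) -> np.ndarray:
    return cfg.beta0 + cfg.beta1 * arm + cfg.beta2[arm] * x + delta


def _success_prob(cfg: DGMConfig, arm: int, x: np.ndarray, delta: np.ndarray) -> np.ndarray:
    lp = _linear_predictor(cfg, arm, x, delta)
    if cfg.link == "logit":
        return special.expit(lp)
    pi = np.exp(lp)
    if np.any(pi >= 1.0):
        raise ConfigError("log link produced a success probability >= 1")
    return pi


def _draw_covariates(cfg: DGMConfig, rng: np.random.Generator, n_clusters: int,
                     m: int) -> tuple[np.ndarray, np.ndarray]:
    """Cluster effects alpha (n_clusters,) and covariates X (n_clusters, m)."""
    alpha = rng.normal(cfg.mu_x, math.sqrt(cfg.sigma_alpha2), size=n_clusters)
    u = rng.normal(0.0, math.sqrt(cfg.sigma_u2), size=(n_clusters, m))
    x = alpha[:, None] + u
    if cfg.link == "log":
        sx = math.sqrt(cfg.sigma_x2)
        x = np.clip(x, cfg.mu_x - _X_TRUNC_SD * sx, cfg.mu_x + _X_TRUNC_SD * sx)
    return alpha, x


def simulate_full_data(cfg: DGMConfig, seed) -> TrialDataset:
    """Simulate one complete trial (all outcomes observed).

    Deterministic given ``seed`` (an int, SeedSequence or Generator).
    """
    import pandas as pd

    rng = _rng(seed)
    frames = []
    sb = math.sqrt(cfg.sigma_b2)
    for arm in (0, 1):
        _, x = _draw_covariates(cfg, rng, cfg.k, cfg.m)
        delta = rng.normal(0.0, sb, size=cfg.k)
        if cfg.link == "log":
            delta = np.clip(delta, -_X_TRUNC_SD * sb, _X_TRUNC_SD * sb)
        pi = _success_prob(cfg, arm, x, delta[:, None])
        y = (rng.random(size=(cfg.k, cfg.m)) < pi).astype(np.float64)
        frames.append(pd.DataFrame({
            "arm": arm,
            "cluster": np.repeat(np.arange(1, cfg.k + 1), cfg.m),
            "individual": np.tile(np.arange(1, cfg.m + 1), cfg.k),
            "x": x.ravel(),
            "y": y.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    df["r"] = 1
    df = df.astype({"arm": np.int64, "cluster": np.int64, "individual": np.int64,
                    "r": np.int64})
    return TrialDataset(df, k=cfg.k, m=cfg.m)


def impose_cdm_missingness(data: TrialDataset, mcfg: MissingnessConfig, seed) -> TrialDataset:
    """Blank outcomes according to the CDM logistic model.

    Each individual's outcome is set missing independently with
    probability ``expit(psi_i + phi_i * x)``; the covariate is never
    removed.  Returns a new dataset, leaving the input untouched.
    """
    rng = _rng(seed)
    df = data.df.copy()
    arm = df["arm"].to_numpy()
    x = df["x"].to_numpy()
    psi = np.where(arm == 1, mcfg.psi[1], mcfg.psi[0])
    phi = np.where(arm == 1, mcfg.phi[1], mcfg.phi[0])
    p_miss = special.expit(psi + phi * x)
    miss = rng.random(len(df)) < p_miss
    df.loc[miss, "y"] = np.nan
    df["r"] = (~df["y"].isna()).astype(np.int64)
    return TrialDataset(df, k=data.k, m=data.m)


# ---------------------------------------------------------------------------
# generative-truth oracles (quadrature)
# ---------------------------------------------------------------------------

def _gauss_hermite(n: int = _GH_NODES) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite_e.hermegauss(n)
    return nodes, weights / math.sqrt(2.0 * math.pi)  # weights of standard normal


def marginal_success_probability(cfg: DGMConfig, arm: int, n_nodes: int = _GH_NODES) -> float:
    """Population success rate pi_i = E[pi_ijl] in one arm.

    Integrates the inverse link over the Normal laws of X and of the
    cluster effect delta with a tensor Gauss-Hermite rule.
    """
    if not np.isfinite([cfg.beta0, cfg.beta1, *cfg.beta2]).all():
        raise ConfigError("non-finite outcome coefficients")
    z, w = _gauss_hermite(n_nodes)
    x = cfg.mu_x + math.sqrt(cfg.sigma_x2) * z
    if cfg.sigma_b2 > 0:
        d = math.sqrt(cfg.sigma_b2) * z
        lp = (cfg.beta0 + cfg.beta1 * arm + cfg.beta2[arm] * x[:, None] + d[None, :])
        pi = special.expit(lp) if cfg.link == "logit" else np.exp(lp)
        return float(w @ pi @ w)
    lp = cfg.beta0 + cfg.beta1 * arm + cfg.beta2[arm] * x
    pi = special.expit(lp) if cfg.link == "logit" else np.exp(lp)
    return float(w @ pi)


def expected_missing_proportion(cfg: DGMConfig, mcfg: MissingnessConfig, arm: int,
                                n_nodes: int = _GH_NODES) -> float:
    """E[P(R = 0)] in one arm: expit(psi + phi X) integrated over X."""
    psi, phi = mcfg.psi[arm], mcfg.phi[arm]
    if not (np.isfinite(psi) and np.isfinite(phi)):
        raise ConfigError("non-finite missingness parameters")
    if phi == 0:
        return float(special.expit(psi))
    z, w = _gauss_hermite(n_nodes)
    x = cfg.mu_x + math.sqrt(cfg.sigma_x2) * z
    return float(w @ special.expit(psi + phi * x))


def calibrate_psi(cfg: DGMConfig, target_missing: float, phi: float, arm: int) -> float:
    """Root-find the intercept psi giving a desired expected missingness."""
    if not 0.0 < target_missing < 1.0:
        raise ConfigError("target_missing must lie in (0, 1)")

    def f(psi: float) -> float:
        m = MissingnessConfig(psi=(psi, psi), phi=(phi, phi))
        return expected_missing_proportion(cfg, m, arm) - target_missing

    lo, hi = -50.0, 50.0
    if f(lo) * f(hi) > 0:
        raise ConfigError("no root for psi in [-50, 50]")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


def estimate_outcome_icc(cfg: DGMConfig, n_clusters: int, m_big: int, seed) -> tuple[float, float]:
    """Estimate the per-arm outcome ICC from a very large simulated dataset.

    For binary outcomes the ICC of arm i is Var(pi_ij) / (pi_i (1 - pi_i))
    where pi_ij is the true cluster-level success probability.  We draw
    ``n_clusters`` clusters of ``m_big`` covariates per arm, average the
    true individual probabilities within cluster and take the sample
    variance across clusters.
    """
    rng = _rng(seed)
    out = []
    sb = math.sqrt(cfg.sigma_b2)
    big = replace(cfg, k=n_clusters, m=m_big)
    for arm in (0, 1):
        _, x = _draw_covariates(big, rng, n_clusters, m_big)
        delta = rng.normal(0.0, sb, size=n_clusters)
        pi_ij = _success_prob(cfg, arm, x, delta[:, None]).mean(axis=1)
        pi_i = pi_ij.mean()
        if pi_i <= 0.0 or pi_i >= 1.0:
            raise ConfigError(f"arm {arm}: success rate {pi_i} gives an undefined ICC")
        out.append(float(np.var(pi_ij, ddof=1) / (pi_i * (1.0 - pi_i))))
    return out[0], out[1]
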