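"""Cluster-level analysis of binary CRT outcomes: unadjusted (CL_U) and
baseline-covariate-adjusted (CL_A) estimation of the risk difference and
risk ratio with t-based inference.

Both analyses are two-stage.  Stage one reduces each cluster to a
summary: the observed proportion of success p_ij for CL_U, or a residual
comparing observed to predicted successes for CL_A, where predictions
come from an individual-level logistic regression of the outcome on the
baseline covariate alone (no arm term, clustering ignored).  Stage two
compares the per-arm means of the summaries with a two-sample t statistic
on 2k - 2 degrees of freedom, clusters being independent.

Residuals: difference residual eps_d = (N - Nhat) / m for the risk
difference, ratio residual eps_r = N / Nhat for the risk ratio, with N
and Nhat the observed and predicted number of successes in a cluster.
Under complete-records analysis the difference residual is divided by
the cluster's observed count rather than the nominal size m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special

from .datamodel import EffectEstimate, TrialDataset, complete_records

__all__ = [
    "ClusterSummary",
    "Stage1Model",
    "SeparationError",
    "EstimationError",
    "cluster_summaries",
    "estimate_rd_unadjusted",
    "estimate_rr_unadjusted",
    "fit_stage1_logistic",
    "predicted_successes",
    "estimate_rd_adjusted",
    "estimate_rr_adjusted",
]


class EstimationError(RuntimeError):
    """An estimator could not be computed on this dataset."""


class SeparationError(EstimationError):
    """Stage-1 logistic regression is separated (ML estimate at infinity)."""


@dataclass
class Stage1Model:
    """Covariate-only logistic fit: logit pi = lambda1 + lambda2 * x."""

    lambda1: float
    lambda2: float
    converged: bool
    x_constant: bool = False  # lambda2 dropped because x carried no information

    def predict(self, x: np.ndarray) -> np.ndarray:
        return special.expit(self.lambda1 + self.lambda2 * np.asarray(x, dtype=float))


def _working_frame(data: TrialDataset, use: str) -> pd.DataFrame:
    if use == "complete_records":
        return complete_records(data).df
    if use == "full":
        if data.n_missing:
            raise EstimationError("full-data analysis requested on an incomplete dataset")
        return data.df
    raise ValueError(f"use must be 'full' or 'complete_records', got {use!r}")


def cluster_summaries(data: TrialDataset, use: str = "full") -> pd.DataFrame:
    """Per-cluster observed counts and success proportions.

    Returns a frame with one row per retained cluster and columns
    ``arm, cluster, n_obs, successes, p``.
    """
    df = _working_frame(data, use)
    g = df.groupby(["arm", "cluster"], sort=True)
    out = g["y"].agg(n_obs="size", successes="sum").reset_index()
    out["successes"] = out["successes"].astype(float)
    out["p"] = out["successes"] / out["n_obs"]
    return out


def _arm_values(summaries: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    v0 = summaries.loc[summaries["arm"] == 0, col].to_numpy(dtype=float)
    v1 = summaries.loc[summaries["arm"] == 1, col].to_numpy(dtype=float)
    for i, v in enumerate((v0, v1)):
        if len(v) < 2:
            raise EstimationError(f"arm {i} has {len(v)} cluster(s); need at least 2")
    return v0, v1


def _two_sample_t(v0: np.ndarray, v1: np.ndarray, scale: str) -> EffectEstimate:
    """Pooled-variance two-sample t comparison of cluster summaries."""
    k0, k1 = len(v0), len(v1)
    est = v1.mean() - v0.mean()
    sp2 = ((k0 - 1) * v0.var(ddof=1) + (k1 - 1) * v1.var(ddof=1)) / (k0 + k1 - 2)
    se = math.sqrt(sp2 * (1.0 / k0 + 1.0 / k1))
    return EffectEstimate.from_t(scale, est, se, df=k0 + k1 - 2, n_clusters_used=(k0, k1))


def estimate_rd_unadjusted(summaries: pd.DataFrame) -> EffectEstimate:
    """Unadjusted risk difference: difference of per-arm mean cluster
    proportions, with the standard two-sample t test on 2k - 2 df."""
    p0, p1 = _arm_values(summaries, "p")
    return _two_sample_t(p0, p1, "RD")


def _log_ratio_estimate(v0: np.ndarray, v1: np.ndarray, scale: str) -> EffectEstimate:
    """log of a ratio of per-arm summary means, with the delta-method
    variance s0^2/(k0 vbar0^2) + s1^2/(k1 vbar1^2)."""
    k0, k1 = len(v0), len(v1)
    m0, m1 = v0.mean(), v1.mean()
    if m0 <= 0 or m1 <= 0:
        raise EstimationError("ratio estimate undefined: a per-arm summary mean is <= 0")
    var = v0.var(ddof=1) / (k0 * m0 ** 2) + v1.var(ddof=1) / (k1 * m1 ** 2)
    return EffectEstimate.from_t(scale, math.log(m1 / m0), math.sqrt(var),
                                 df=k0 + k1 - 2, n_clusters_used=(k0, k1))


def estimate_rr_unadjusted(summaries: pd.DataFrame) -> EffectEstimate:
    """Unadjusted risk ratio on the log scale: log(pbar1 / pbar0)."""
    p0, p1 = _arm_values(summaries, "p")
    return _log_ratio_estimate(p0, p1, "logRR")


# ---------------------------------------------------------------------------
# adjusted analysis
# ---------------------------------------------------------------------------

def fit_stage1_logistic(data: TrialDataset, use: str = "full", tol: float = 1e-10,
                        maxiter: int = 100) -> Stage1Model:
    """ML logistic regression of y on x, pooling both arms and ignoring
    clustering and the arm indicator.

    Raises :class:`SeparationError` when the outcome is constant or the
    fit is perfectly separated (infinite ML estimate).
    """
    df = _working_frame(data, use)
    y = df["y"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is constant; intercept ML estimate is infinite")
    if np.ptp(x) == 0.0:
        # covariate carries no information: intercept-only ML in closed form
        p = y.mean()
        return Stage1Model(lambda1=float(special.logit(p)), lambda2=0.0,
                           converged=True, x_constant=True)
    X = sm.add_constant(x)
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=tol, maxiter=maxiter)
    except Exception as exc:  # separation surfaces as a warning-turned-error
        raise SeparationError(f"stage-1 logistic fit failed: {exc}") from exc
    lam1, lam2 = (float(v) for v in res.params)
    if not np.isfinite([lam1, lam2]).all() or max(abs(lam1), abs(lam2)) > 1e3:
        raise SeparationError("stage-1 logistic estimates diverged (separation)")
    mu = res.fittedvalues
    score = X.T @ (y - mu)
    converged = bool(res.converged) and float(np.max(np.abs(score))) < 1e-6
    return Stage1Model(lambda1=lam1, lambda2=lam2, converged=converged)


def predicted_successes(data: TrialDataset, model: Stage1Model,
                        use: str = "full") -> pd.DataFrame:
    """Cluster summaries augmented with the predicted number of successes
    Nhat_ij = sum over contributing records of expit(lambda1 + lambda2 x)."""
    df = _working_frame(data, use)
    df = df.assign(_fit=model.predict(df["x"].to_numpy()))
    g = df.groupby(["arm", "cluster"], sort=True)
    out = g.agg(n_obs=("y", "size"), successes=("y", "sum"),
                predicted=("_fit", "sum")).reset_index()
    out["successes"] = out["successes"].astype(float)
    out["p"] = out["successes"] / out["n_obs"]
    return out


def _residual_summaries(data: TrialDataset, use: str) -> pd.DataFrame:
    model = fit_stage1_logistic(data, use)
    out = predicted_successes(data, model, use)
    divisor = float(data.m) if use == "full" else out["n_obs"].astype(float)
    out["resid_diff"] = (out["successes"] - out["predicted"]) / divisor
    out["resid_ratio"] = out["successes"] / out["predicted"]
    return out


def estimate_rd_adjusted(data: TrialDataset, use: str = "full") -> EffectEstimate:
    """Covariate-adjusted risk difference: difference of per-arm mean
    difference residuals, compared with a two-sample t on 2k - 2 df.

    On full data this reproduces the identity
    RD_adj = RD_unadj + (1/(m k)) * sum_j (Nhat_0j - Nhat_1j)
    to machine precision.
    """
    out = _residual_summaries(data, use)
    e0, e1 = _arm_values(out, "resid_diff")
    return _two_sample_t(e0, e1, "RD")


def estimate_rr_adjusted(data: TrialDataset, use: str = "full") -> EffectEstimate:
    """Covariate-adjusted risk ratio on the log scale: log of the ratio of
    per-arm mean ratio residuals, with the delta-method t interval."""
    out = _residual_summaries(data, use)
    if (out["predicted"] <= 0.0).any():
        raise EstimationError("ratio residual undefined: a cluster has predicted "
                              "successes equal to 0")
    e0, e1 = _arm_values(out, "resid_ratio")
    return _log_ratio_estimate(e0, e1, "logRR")
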