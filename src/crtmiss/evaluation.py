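"""Simulation harness and validity oracles.

``run_study`` reproduces the factorial simulation design: for each
number of clusters per arm k, simulate replicated trials under a chosen
scenario, impose covariate-dependent missingness, analyse each replicate
with the requested estimators under full data, complete-records analysis
(CRA) and multilevel multiple imputation (MMI), and aggregate average
estimates, average estimated standard errors, and coverage of nominal
95% t intervals against the generative truth.

``check_condition`` is a Monte-Carlo oracle for the analytic validity
conditions of the complete-records cluster-level analyses.  Writing the
individual success probability as pi_ijl = pi_i + g_i(X, delta)
(difference form) or pi_ijl = pi_i * h_i(X, delta) (ratio form), the
complete-records unadjusted risk difference is unbiased iff

    E[g_1 | R = 1] = E[g_0 | R = 1]

and the unadjusted risk ratio is consistent iff

    E[h_1 | R = 1] / E[h_0 | R = 1] = 1.

Both expectations are over the covariate and cluster-effect laws
conditioned on the outcome being observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cluster_level as cl
from . import dgm
from . import individual_level as il
from . import mmi as mmi_mod
from .datamodel import TrialDataset

__all__ = [
    "SimulationConfig",
    "ConditionReport",
    "run_replication",
    "run_study",
    "check_condition",
    "report_table",
    "ALL_METHODS",
]

ALL_METHODS = ("cl_u_rd", "cl_a_rd", "cl_u_rr", "cl_a_rr", "relr", "gee")
_INTERACTION_SCENARIOS = {"S3", "S4"}  # arms differ in covariate effect


@dataclass
class SimulationConfig:
    """Study design for a batch of simulations.

    ``scenario`` may be one of the presets S1-S4 or ``"custom"`` with an
    explicit (DGMConfig, MissingnessConfig) pair.  ``interaction``
    defaults to scenarios whose two arms have different covariate
    effects, where the analysis and imputation models include an
    arm-by-centred-covariate interaction.
    """

    scenario: str = "S1"
    dgm_config: dgm.DGMConfig | None = None
    missingness: dgm.MissingnessConfig | None = None
    k_grid: tuple[int, ...] = (5, 10, 20, 50)
    m: int = 50
    n_reps: int = 1000
    methods: tuple[str, ...] = ALL_METHODS
    handling: tuple[str, ...] = ("full", "cra", "mmi")
    seed: int = 0
    mmi_config: mmi_mod.ImputationConfig = field(default_factory=mmi_mod.ImputationConfig)
    interaction: bool | None = None
    gee_truth: float | None = None  # empirical marginal log OR, if precomputed

    def __post_init__(self) -> None:
        if self.n_reps < 2 or any(k <= 0 for k in self.k_grid):
            raise ValueError("need n_reps >= 2 and positive k_grid")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    def configs(self, k: int) -> tuple[dgm.DGMConfig, dgm.MissingnessConfig]:
        if self.scenario == "custom":
            if self.dgm_config is None or self.missingness is None:
                raise ValueError("custom scenario requires dgm_config and missingness")
            return replace(self.dgm_config, k=k, m=self.m), self.missingness
        cfg, mcfg = dgm.scenario_preset(self.scenario, k=k, m=self.m)
        return cfg, mcfg

    @property
    def use_interaction(self) -> bool:
        if self.interaction is not None:
            return self.interaction
        return self.scenario in _INTERACTION_SCENARIOS


def _rep_seed(root_seed: int, k: int, rep_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(k, rep_index))


def _analyze_one(method: str, data: TrialDataset, use: str, interaction: bool):
    if method == "cl_u_rd":
        return cl.estimate_rd_unadjusted(cl.cluster_summaries(data, use))
    if method == "cl_u_rr":
        return cl.estimate_rr_unadjusted(cl.cluster_summaries(data, use))
    if method == "cl_a_rd":
        return cl.estimate_rd_adjusted(data, use)
    if method == "cl_a_rr":
        return cl.estimate_rr_adjusted(data, use)
    design_source = data  # Xbar over all individuals, including missing outcomes
    if method == "relr":
        return il.fit_relr(data, il.build_design(design_source, interaction), use).effect
    if method == "gee":
        return il.fit_gee(data, il.build_design(design_source, interaction), use).effect
    raise ValueError(f"unknown method {method!r}")


def run_replication(cfg: SimulationConfig, k: int, rep_index: int) -> dict:
    """Simulate one trial and analyse it with every requested
    method x handling combination.

    Returns a dict keyed by ``(method, handling)`` whose values are
    :class:`EffectEstimate` / :class:`PooledEstimate` objects, or an
    exception instance when that analysis failed.  Deterministic given
    (seed, k, rep_index); the covariate/outcome draw, the missingness
    draw and the imputation chain use independent substreams so the same
    full dataset underlies every handling.
    """
    ss = _rep_seed(cfg.seed, k, rep_index)
    s_data, s_miss, s_mmi = ss.spawn(3)
    dcfg, mcfg = cfg.configs(k)
    interaction = cfg.use_interaction

    full = dgm.simulate_full_data(dcfg, np.random.default_rng(s_data))
    incomplete = None
    if {"cra", "mmi"} & set(cfg.handling):
        incomplete = dgm.impose_cdm_missingness(full, mcfg, np.random.default_rng(s_miss))

    imputed = None
    if "mmi" in cfg.handling:
        # one imputation run per replicate, shared by every estimator
        icfg = replace(cfg.mmi_config, include_interaction=interaction,
                       seed=int(s_mmi.generate_state(1)[0] >> 1))
        try:
            imputed = mmi_mod.impute(incomplete, icfg)
        except Exception as exc:
            imputed = exc

    out: dict = {}
    for method in cfg.methods:
        for handling in cfg.handling:
            try:
                if handling == "full":
                    out[(method, "full")] = _analyze_one(method, full, "full", interaction)
                elif handling == "cra":
                    out[(method, "cra")] = _analyze_one(method, incomplete,
                                                        "complete_records", interaction)
                elif handling == "mmi":
                    if isinstance(imputed, Exception):
                        raise imputed
                    out[(method, "mmi")] = mmi_mod.pool_over_imputed(
                        imputed, method, nu_com=2 * k - 2, interaction=interaction)
                else:
                    raise ValueError(f"unknown handling {handling!r}")
            except Exception as exc:  # recorded, not raised: a failed fit skips one cell
                out[(method, handling)] = exc
    return out


_SCALE_OF = {"cl_u_rd": "RD", "cl_a_rd": "RD", "cl_u_rr": "logRR", "cl_a_rr": "logRR",
             "relr": "logOR_conditional", "gee": "logOR_marginal"}


def true_values(cfg: SimulationConfig, k: int) -> dict[str, float]:
    """Generative truths per effect scale: RD and log RR from quadrature,
    conditional log OR = beta1, marginal log OR estimated empirically
    from full data unless supplied."""
    dcfg, _ = cfg.configs(k)
    pi0 = dgm.marginal_success_probability(dcfg, 0)
    pi1 = dgm.marginal_success_probability(dcfg, 1)
    truths = {"RD": pi1 - pi0, "logRR": math.log(pi1 / pi0),
              "logOR_conditional": dcfg.beta1}
    if "gee" in cfg.methods:
        if cfg.gee_truth is not None:
            truths["logOR_marginal"] = cfg.gee_truth
        else:
            truth_seed = int(np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(99991,)).generate_state(1)[0] >> 1)
            est, _ = il.empirical_marginal_logor(
                dcfg, reps=200, k=max(cfg.k_grid), m=cfg.m,
                seed=truth_seed, interaction=cfg.use_interaction)
            truths["logOR_marginal"] = est
    return truths


def run_study(cfg: SimulationConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial study and aggregate a results table.

    One row per (scenario, k, method, handling): the average estimate and
    its Monte-Carlo error, the average estimated SE, coverage of nominal
    95% intervals against the generative truth, and the number of failed
    replicates.  Cells losing more than 10% of replicates are flagged.
    """
    rows = []
    for k in cfg.k_grid:
        truths = true_values(cfg, k)
        results: dict = {key: [] for key in
                         ((m, h) for m in cfg.methods for h in cfg.handling)}
        for rep in range(cfg.n_reps):
            rep_out = run_replication(cfg, k, rep)
            for key, value in rep_out.items():
                results[key].append(value)
            if progress and (rep + 1) % 50 == 0:
                print(f"  k={k}: {rep + 1}/{cfg.n_reps} replicates")
        for (method, handling), values in results.items():
            ok = [v for v in values if not isinstance(v, Exception)]
            n_failed = len(values) - len(ok)
            scale = _SCALE_OF[method]
            truth = truths[scale]
            if not ok:
                rows.append(dict(scenario=cfg.scenario, k=k, method=method,
                                 handling=handling, scale=scale, mean_estimate=np.nan,
                                 mc_error_estimate=np.nan, mean_se=np.nan,
                                 mc_error_se=np.nan, coverage_pct=np.nan,
                                 n_failed_reps=n_failed, n_used=0, true_value=truth,
                                 flagged=True))
                continue
            est = np.array([v.estimate for v in ok])
            ses = np.array([v.se for v in ok])
            cov = np.array([v.covers(truth) for v in ok])
            n = len(ok)
            rows.append(dict(
                scenario=cfg.scenario, k=k, method=method, handling=handling,
                scale=scale,
                mean_estimate=float(est.mean()),
                mc_error_estimate=float(est.std(ddof=1) / math.sqrt(n)),
                mean_se=float(ses.mean()),
                mc_error_se=float(ses.std(ddof=1) / math.sqrt(n)),
                coverage_pct=float(100.0 * cov.mean()),
                n_failed_reps=n_failed, n_used=n, true_value=truth,
                flagged=n_failed > 0.1 * cfg.n_reps))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validity-condition oracle
# ---------------------------------------------------------------------------

@dataclass
class ConditionReport:
    """Monte-Carlo check of a complete-records validity condition.

    For the risk difference the statistic is the between-arm difference
    of E[g_i | R = 1]; for the risk ratio it is the ratio of
    E[h_i | R = 1].  ``satisfied`` holds when the statistic is within
    3 Monte-Carlo SEs of its null value (0 for differences, 1 for
    ratios).
    """

    kind: str
    lhs: float
    rhs: float
    statistic: float
    mc_se: float
    n_mc: int

    @property
    def satisfied(self) -> bool:
        null = 0.0 if self.kind == "rd_condition" else 1.0
        return abs(self.statistic - null) <= 3.0 * self.mc_se


def _conditional_mean_given_observed(dcfg: dgm.DGMConfig, mcfg: dgm.MissingnessConfig,
                                     arm: int, kind: str, n_mc: int,
                                     rng: np.random.Generator) -> tuple[float, float]:
    """E[g_arm | R = 1] or E[h_arm | R = 1] with its MC standard error."""
    from scipy import special as sp

    pi_i = dgm.marginal_success_probability(dcfg, arm)
    if kind == "rr_condition" and pi_i <= 0.0:
        raise dgm.ConfigError("group success rate is 0; ratio form h_i undefined")
    sx = math.sqrt(dcfg.sigma_x2)
    x = rng.normal(dcfg.mu_x, sx, size=n_mc)
    if dcfg.link == "log":
        x = np.clip(x, dcfg.mu_x - 4 * sx, dcfg.mu_x + 4 * sx)
    delta = rng.normal(0.0, math.sqrt(dcfg.sigma_b2), size=n_mc)
    lp = dcfg.beta0 + dcfg.beta1 * arm + dcfg.beta2[arm] * x + delta
    pi = sp.expit(lp) if dcfg.link == "logit" else np.exp(lp)
    observed = rng.random(n_mc) >= sp.expit(mcfg.psi[arm] + mcfg.phi[arm] * x)
    if not observed.any():
        raise dgm.ConfigError("no observed draws; missingness too extreme for MC check")
    vals = (pi - pi_i) if kind == "rd_condition" else (pi / pi_i)
    sel = vals[observed]
    return float(sel.mean()), float(sel.std(ddof=1) / math.sqrt(len(sel)))


def check_condition(dcfg: dgm.DGMConfig, mcfg: dgm.MissingnessConfig, kind: str,
                    n_mc: int = 200_000, seed=0) -> ConditionReport:
    """Monte-Carlo evaluation of the complete-records validity condition.

    ``kind="rd"`` checks E[g_1|R=1] - E[g_0|R=1] = 0 (unbiasedness of the
    unadjusted complete-records risk difference); ``kind="rr"`` checks
    E[h_1|R=1] / E[h_0|R=1] = 1 (consistency of the unadjusted
    complete-records risk ratio).
    """
    kind = {"rd": "rd_condition", "rr": "rr_condition"}.get(kind, kind)
    if kind not in ("rd_condition", "rr_condition"):
        raise ValueError("kind must be 'rd' or 'rr'")
    rng = np.random.default_rng(seed)
    m0, se0 = _conditional_mean_given_observed(dcfg, mcfg, 0, kind, n_mc, rng)
    m1, se1 = _conditional_mean_given_observed(dcfg, mcfg, 1, kind, n_mc, rng)
    if kind == "rd_condition":
        stat = m1 - m0
        se = math.hypot(se0, se1)
    else:
        stat = m1 / m0
        # delta method for the ratio of independent means
        se = abs(stat) * math.hypot(se1 / m1, se0 / m0)
    return ConditionReport(kind=kind, lhs=m1, rhs=m0, statistic=stat,
                           mc_se=se, n_mc=n_mc)


_COLUMN_ORDER = ["scenario", "k", "method", "handling", "scale", "true_value",
                 "mean_estimate", "mc_error_estimate", "mean_se", "mc_error_se",
                 "coverage_pct", "n_used", "n_failed_reps", "flagged"]


def report_table(results: pd.DataFrame, path) -> None:
    """Write the results table as CSV plus a formatted text companion
    laid out in scenario blocks with one row per k and column groups per
    handling (full / CRA / MMI)."""
    import pathlib

    path = pathlib.Path(path)
    cols = [c for c in _COLUMN_ORDER if c in results.columns]
    results[cols].to_csv(path, index=False)
    txt = path.with_suffix(".txt")
    lines = []
    if len(results):
        for (scen, method), block in results.groupby(["scenario", "method"], sort=True):
            lines.append(f"scenario {scen} | method {method}")
            pivot = block.pivot_table(index="k", columns="handling",
                                      values=["mean_estimate", "mean_se", "coverage_pct"])
            lines.append(pivot.round(3).to_string())
            lines.append("")
    txt.write_text("\n".join(lines) or "(empty results table)\n")
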