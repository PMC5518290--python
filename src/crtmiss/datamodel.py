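"""Core data structures for two-arm cluster randomised trials (CRTs).

A trial is stored in long format: one row per individual with columns
``arm`` (0 control, 1 intervention), ``cluster`` (arm-local id 1..k),
``individual`` (1..m within cluster), ``x`` (continuous baseline
covariate) and ``y`` (binary outcome, NaN when missing).  A derived
indicator ``r`` records whether the outcome was observed (r = 1) or is
missing (r = 0).  The design is balanced: both arms are randomised to
``k`` clusters of nominal size ``m``; missingness may later thin the
observed outcomes but never removes rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "EffectEstimate",
    "PooledEstimate",
    "ValidationError",
    "load_trial_csv",
    "write_trial_csv",
    "complete_records",
]

CSV_COLUMNS = ("arm", "cluster", "individual", "x", "y")


class ValidationError(ValueError):
    """Raised when a dataset violates the trial-design invariants."""


@dataclass
class TrialDataset:
    """Long-format CRT data.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``arm, cluster, individual, x, y, r``.  ``y`` is float
        with NaN marking a missing outcome; ``r`` is the 0/1 observed
        indicator and must satisfy ``r == 0  iff  y is NaN``.
    k : int
        Clusters randomised per arm.
    m : int
        Nominal cluster size before any missingness.
    """

    df: pd.DataFrame
    k: int
    m: int

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_missing(self) -> int:
        return int((self.df["r"] == 0).sum())

    def clusters_per_arm(self) -> tuple[int, int]:
        """Number of distinct clusters present in each arm."""
        g = self.df.groupby("arm")["cluster"].nunique()
        return int(g.get(0, 0)), int(g.get(1, 0))

    def arm(self, i: int) -> pd.DataFrame:
        return self.df[self.df["arm"] == i]

    def observed(self) -> pd.DataFrame:
        return self.df[self.df["r"] == 1]

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), self.k, self.m)


def _as_trial_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "arm": df["arm"].astype(np.int64),
            "cluster": df["cluster"].astype(np.int64),
            "individual": df["individual"].astype(np.int64),
            "x": df["x"].astype(np.float64),
            "y": df["y"].astype(np.float64),
        }
    )
    out["r"] = (~out["y"].isna()).astype(np.int64)
    return out


def validate_trial(data: TrialDataset, *, balanced: bool = True) -> None:
    """Check the trial-design invariants, raising :class:`ValidationError`.

    With ``balanced=True`` (datasets as randomised) both arms must carry
    exactly ``k`` clusters of ``m`` rows each.  Complete-records subsets
    are validated with ``balanced=False`` since dropping unobserved rows
    may unbalance the design.
    """
    df = data.df
    bad_arm = ~df["arm"].isin((0, 1))
    if bad_arm.any():
        i = int(np.flatnonzero(bad_arm.to_numpy())[0])
        raise ValidationError(f"arm must be 0 or 1 (row {i}: arm={df['arm'].iloc[i]})")
    obs_y = df.loc[df["r"] == 1, "y"]
    if not obs_y.isin((0.0, 1.0)).all():
        bad = obs_y[~obs_y.isin((0.0, 1.0))]
        raise ValidationError(f"observed y must be 0 or 1, found {bad.iloc[0]!r}")
    mism = (df["r"] == 1) != df["y"].notna()
    if mism.any():
        raise ValidationError("r = 1 must coincide exactly with y being present")
    dup = df.duplicated(subset=["arm", "cluster", "individual"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (arm, cluster, individual) = "
            f"({row['arm']}, {row['cluster']}, {row['individual']})"
        )
    if balanced:
        k0, k1 = data.clusters_per_arm()
        if k0 != data.k or k1 != data.k:
            raise ValidationError(
                f"unbalanced design: {k0} control / {k1} intervention clusters, "
                f"expected k={data.k} in each arm"
            )
        sizes = df.groupby(["arm", "cluster"]).size()
        if (sizes != data.m).any():
            arm_i, clus = sizes[sizes != data.m].index[0]
            raise ValidationError(
                f"cluster ({arm_i}, {clus}) has {sizes[(arm_i, clus)]} records, "
                f"expected m={data.m}"
            )


def load_trial_csv(path) -> TrialDataset:
    """Read a trial from CSV (columns ``arm,cluster,individual,x,y``).

    An empty ``y`` field denotes a missing outcome and sets r = 0.
    """
    try:
        raw = pd.read_csv(path, dtype={"arm": "Int64", "cluster": "Int64",
                                       "individual": "Int64", "x": float, "y": float})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    missing_cols = set(CSV_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    for col in ("arm", "cluster", "individual", "x"):
        if raw[col].isna().any():
            # +2: one for the header line, one for 0-based indexing
            line = int(np.flatnonzero(raw[col].isna().to_numpy())[0]) + 2
            raise ValidationError(f"{path} line {line}: empty {col} field")
    df = _as_trial_frame(raw)
    k = int(df.groupby("arm")["cluster"].nunique().max())
    m = int(df.groupby(["arm", "cluster"]).size().max())
    data = TrialDataset(df, k=k, m=m)
    validate_trial(data, balanced=True)
    return data


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a trial to CSV; missing y becomes an empty field.

    ``load_trial_csv(write_trial_csv(d))`` reproduces ``d`` exactly,
    including the float covariate to full precision.
    """
    out = data.df[list(CSV_COLUMNS)].copy()
    y = out["y"]
    out["y"] = y.map(lambda v: "" if (isinstance(v, float) and math.isnan(v)) else str(int(v)))
    out["x"] = out["x"].map(repr)
    out.to_csv(path, index=False)


def complete_records(data: TrialDataset) -> TrialDataset:
    """Restrict to individuals with observed outcomes (r = 1).

    Clusters left with no observed outcomes disappear from the subset;
    downstream analyses use the realised per-arm cluster counts.  The
    operation is idempotent.
    """
    sub = data.df[data.df["r"] == 1]
    for i in (0, 1):
        if (sub["arm"] == i).sum() == 0:
            raise ValidationError(f"arm {i} has no observed outcomes")
    return TrialDataset(sub.copy(), k=data.k, m=data.m)


@dataclass
class EffectEstimate:
    """One analysis result on its natural scale.

    ``scale`` is one of ``"RD"``, ``"logRR"``, ``"logOR_conditional"``
    (cluster-specific effect from a random-effects fit) or
    ``"logOR_marginal"`` (population-averaged effect from GEE).  The
    confidence interval is ``estimate ± t_{df,0.975} · se`` and the
    p-value is from the same t reference distribution.
    """

    scale: str
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    n_clusters_used: tuple[int, int]

    @classmethod
    def from_t(cls, scale: str, estimate: float, se: float, df: float,
               n_clusters_used: tuple[int, int], alpha: float = 0.05) -> "EffectEstimate":
        from scipy import stats

        tq = stats.t.ppf(1 - alpha / 2, df)
        if se > 0:
            p = 2 * stats.t.sf(abs(estimate / se), df)
        else:
            p = 0.0 if estimate != 0 else 1.0
        return cls(scale=scale, estimate=float(estimate), se=float(se), df=float(df),
                   ci_low=float(estimate - tq * se), ci_high=float(estimate + tq * se),
                   p_value=float(p), n_clusters_used=n_clusters_used)

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


@dataclass
class PooledEstimate:
    """Rubin-combined multiple-imputation result.

    W is the average within-imputation variance, B the between-imputation
    variance over the Q completed-data analyses; ``total_var = W +
    (1 + 1/Q) B``.  ``upsilon`` is the classical MI degrees of freedom and
    ``nu_adj`` the Barnard–Rubin small-sample adjustment, which never
    exceeds the complete-data degrees of freedom ``nu_com``.
    """

    scale: str
    estimate: float
    W: float
    B: float
    Q: int
    total_var: float
    upsilon: float
    nu_com: float
    nu_adj: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high
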