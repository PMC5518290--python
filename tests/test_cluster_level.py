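"""Cluster-level RD/RR estimators, stage-1 logistic fit and residuals."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from crtmiss import cluster_level as cl
from crtmiss import dgm
from crtmiss.cluster_level import SeparationError
from crtmiss.datamodel import complete_records

from conftest import make_dataset


def _props_dataset(p0, p1, m=10):
    """A trial whose cluster proportions are exactly p0 (arm 0) / p1 (arm 1)."""
    arm, cluster, individual, y = [], [], [], []
    for i, props in enumerate((p0, p1)):
        for j, p in enumerate(props, start=1):
            succ = round(p * m)
            for l in range(1, m + 1):
                arm.append(i), cluster.append(j), individual.append(l)
                y.append(1.0 if l <= succ else 0.0)
    x = np.zeros(len(y))
    return make_dataset(arm, cluster, individual, x, y, k=len(p0), m=m)


class TestClusterSummaries:
    def test_simple_proportion(self):
        d = make_dataset([0] * 4 + [1] * 4, [1] * 8, [1, 2, 3, 4] * 2,
                         np.arange(8) * 0.1, [1, 1, 0, 0, 1, 0, 1, 1], 1, 4)
        s = cl.cluster_summaries(d, "full")
        assert s.loc[s.arm == 0, "p"].item() == 0.5
        assert s.loc[s.arm == 1, "p"].item() == 0.75

    def test_complete_records_proportion(self):
        y = [1, float("nan"), float("nan"), 0, 1, 0, 1, 1]
        d = make_dataset([0] * 4 + [1] * 4, [1] * 8, [1, 2, 3, 4] * 2,
                         np.arange(8) * 0.1, y, 1, 4)
        s = cl.cluster_summaries(d, "complete_records")
        row = s[s.arm == 0].iloc[0]
        assert row["n_obs"] == 2 and row["p"] == 0.5

    def test_success_conservation(self, s1_small):
        s = cl.cluster_summaries(s1_small, "full")
        assert s["successes"].sum() == s1_small.df["y"].sum()


class TestUnadjustedEstimators:
    def test_rd_hand_arithmetic(self):
        d = _props_dataset([0.4, 0.5, 0.6], [0.6, 0.7, 0.8])
        e = cl.estimate_rd_unadjusted(cl.cluster_summaries(d))
        assert e.estimate == pytest.approx(0.2)
        # pooled two-sample t: s^2 = 0.01 in each arm, se = 0.1 sqrt(2/3)
        assert e.se == pytest.approx(0.1 * math.sqrt(2 / 3), abs=1e-10)
        assert e.df == 4
        assert e.ci_low < 0.2 < e.ci_high

    def test_rr_hand_arithmetic(self):
        d = _props_dataset([0.4, 0.5, 0.6], [0.6, 0.7, 0.8])
        e = cl.estimate_rr_unadjusted(cl.cluster_summaries(d))
        assert e.estimate == pytest.approx(math.log(0.7 / 0.5))
        # printed variance formula: 0.01/(3*0.25) + 0.01/(3*0.49)
        assert e.se == pytest.approx(math.sqrt(0.01 / 0.75 + 0.01 / 1.47), abs=1e-12)
        assert e.df == 4

    def test_symmetric_arms_null(self):
        d = _props_dataset([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        rd = cl.estimate_rd_unadjusted(cl.cluster_summaries(d))
        rr = cl.estimate_rr_unadjusted(cl.cluster_summaries(d))
        assert rd.estimate == 0 and rd.p_value == pytest.approx(1.0)
        assert rr.estimate == 0

    def test_single_cluster_arm_rejected(self):
        d = _props_dataset([0.4], [0.5])
        with pytest.raises(cl.EstimationError, match="at least 2"):
            cl.estimate_rd_unadjusted(cl.cluster_summaries(d))


def _irls_logistic(y, x, iters=60):
    """Minimal IRLS oracle for logit(p) = a + b x (test-only)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        mu = expit(X @ beta)
        w = mu * (1 - mu)
        z = X @ beta + (y - mu) / w
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
    return beta


class TestStage1Logistic:
    def test_matches_irls_oracle(self, s1_small):
        model = cl.fit_stage1_logistic(s1_small, "full")
        df = s1_small.df
        a, b = _irls_logistic(df["y"].to_numpy(), df["x"].to_numpy())
        assert model.lambda1 == pytest.approx(a, abs=1e-6)
        assert model.lambda2 == pytest.approx(b, abs=1e-6)
        assert model.converged

    def test_complete_records_fit_uses_observed_only(self, s1_small_incomplete):
        model = cl.fit_stage1_logistic(s1_small_incomplete, "complete_records")
        obs = s1_small_incomplete.df.query("r == 1")
        a, b = _irls_logistic(obs["y"].to_numpy(), obs["x"].to_numpy())
        assert model.lambda1 == pytest.approx(a, abs=1e-6)
        assert model.lambda2 == pytest.approx(b, abs=1e-6)

    def test_constant_covariate_intercept_only(self):
        d = make_dataset([0, 0, 1, 1], [1, 1, 1, 1], [1, 2, 1, 2],
                         [2.0] * 4, [1, 0, 1, 1], 1, 2)
        model = cl.fit_stage1_logistic(d, "full")
        assert model.x_constant and model.lambda2 == 0.0
        assert model.lambda1 == pytest.approx(logit(0.75))

    def test_constant_outcome_raises_separation(self):
        d = make_dataset([0, 0, 1, 1], [1, 1, 1, 1], [1, 2, 1, 2],
                         [0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1], 1, 2)
        with pytest.raises(SeparationError):
            cl.fit_stage1_logistic(d, "full")

    def test_perfect_separation_raises(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0] * 2)
        y = (x > 0).astype(float)
        d = make_dataset([0] * 6 + [1] * 6, [1] * 12, list(range(1, 7)) * 2,
                         x, y, 1, 6)
        with pytest.raises(SeparationError):
            cl.fit_stage1_logistic(d, "full")


class TestPredictedSuccesses:
    def test_null_model_predicts_half(self, s1_small):
        model = cl.Stage1Model(lambda1=0.0, lambda2=0.0, converged=True)
        out = cl.predicted_successes(s1_small, model, "full")
        assert np.allclose(out["predicted"], out["n_obs"] / 2)

    def test_ml_score_identity(self, s1_small):
        # at the logistic ML solution total predicted = total observed successes
        model = cl.fit_stage1_logistic(s1_small, "full")
        out = cl.predicted_successes(s1_small, model, "full")
        assert out["predicted"].sum() == pytest.approx(out["successes"].sum(), abs=1e-6)

    def test_per_cluster_brute_force(self, s1_small):
        model = cl.fit_stage1_logistic(s1_small, "full")
        out = cl.predicted_successes(s1_small, model, "full")
        df = s1_small.df
        for _, row in out.head(4).iterrows():
            sub = df[(df["arm"] == row["arm"]) & (df["cluster"] == row["cluster"])]
            nhat = expit(model.lambda1 + model.lambda2 * sub["x"]).sum()
            assert row["predicted"] == pytest.approx(nhat, abs=1e-12)


class TestAdjustedEstimators:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_full_data_identity_with_unadjusted(self, seed):
        # RD_adj = RD_unadj + (1/(m k)) sum_j (Nhat_0j - Nhat_1j), machine precision
        cfg, _ = dgm.scenario_preset("S1", k=6, m=15)
        data = dgm.simulate_full_data(cfg, seed)
        rd_u = cl.estimate_rd_unadjusted(cl.cluster_summaries(data)).estimate
        model = cl.fit_stage1_logistic(data, "full")
        pred = cl.predicted_successes(data, model, "full")
        shift = (pred.loc[pred.arm == 0, "predicted"].sum()
                 - pred.loc[pred.arm == 1, "predicted"].sum()) / (cfg.m * cfg.k)
        rd_a = cl.estimate_rd_adjusted(data, "full").estimate
        assert rd_a == pytest.approx(rd_u + shift, abs=1e-12)

    def test_adjusted_rr_recomputed_from_residuals(self, s1_small):
        e = cl.estimate_rr_adjusted(s1_small, "full")
        model = cl.fit_stage1_logistic(s1_small, "full")
        pred = cl.predicted_successes(s1_small, model, "full")
        ratio = pred["successes"] / pred["predicted"]
        r0 = ratio[pred["arm"] == 0].to_numpy()
        r1 = ratio[pred["arm"] == 1].to_numpy()
        assert e.estimate == pytest.approx(math.log(r1.mean() / r0.mean()), abs=1e-12)
        var = (r0.var(ddof=1) / (len(r0) * r0.mean() ** 2)
               + r1.var(ddof=1) / (len(r1) * r1.mean() ** 2))
        assert e.se == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_cra_difference_residual_divides_by_observed_count(self, s1_small_incomplete):
        e = cl.estimate_rd_adjusted(s1_small_incomplete, "complete_records")
        obs = complete_records(s1_small_incomplete)
        model = cl.fit_stage1_logistic(s1_small_incomplete, "complete_records")
        pred = cl.predicted_successes(s1_small_incomplete, model, "complete_records")
        resid = (pred["successes"] - pred["predicted"]) / pred["n_obs"]
        diff = (resid[pred["arm"] == 1].mean() - resid[pred["arm"] == 0].mean())
        assert e.estimate == pytest.approx(diff, abs=1e-12)

    def test_adjusted_null_when_arms_identical(self):
        d = _props_dataset([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        # constant x: predictions equal the pooled mean in every cluster
        rd = cl.estimate_rd_adjusted(d, "full")
        assert rd.estimate == pytest.approx(0.0, abs=1e-12)
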