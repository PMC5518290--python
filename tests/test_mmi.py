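"""Multilevel imputation: Gibbs sampler, imputation invariants, pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from crtmiss import dgm, mmi
from crtmiss.datamodel import TrialDataset



def _probit_trial(k, m, gamma, tau, seed, x_sd=1.5):
    """Synthetic trial generated from the imputation model itself."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm in (0, 1):
        b = rng.normal(0.0, tau, size=k)
        for j in range(1, k + 1):
            x = rng.normal(0.0, x_sd, size=m)
            mu = gamma[0] + gamma[1] * arm + gamma[2] * x + b[j - 1]
            y = (rng.random(m) < ndtr(mu)).astype(float)
            rows.append(pd.DataFrame({"arm": arm, "cluster": j,
                                      "individual": np.arange(1, m + 1),
                                      "x": x, "y": y}))
    df = pd.concat(rows, ignore_index=True)
    df["r"] = 1
    return TrialDataset(df, k=k, m=m)


class TestRubinPool:
    def test_hand_arithmetic(self):
        # Q=3, W=1, B=0.5: T = 1 + (4/3)*0.5 = 5/3,
        # upsilon = 2 (1 + 3/(4*0.5))^2 = 12.5,
        # nu_obs = (9/11)*8/(1 + (4/3)*0.5) = 216/55, nu_adj ~ 2.9884
        est = [0.0, 0.5 * math.sqrt(2), -0.5 * math.sqrt(2)]  # sample var 0.5
        pooled = mmi.rubin_pool(est, [1.0, 1.0, 1.0], nu_com=8.0)
        assert pooled.W == pytest.approx(1.0)
        assert pooled.B == pytest.approx(0.5)
        assert pooled.total_var == pytest.approx(5.0 / 3.0)
        assert pooled.upsilon == pytest.approx(12.5)
        assert pooled.nu_adj == pytest.approx(1.0 / (1.0 / 12.5 + 55.0 / 216.0))
        assert pooled.nu_adj <= pooled.nu_com

    def test_b_zero_limit(self):
        pooled = mmi.rubin_pool([0.3, 0.3, 0.3], [0.04, 0.04, 0.04], nu_com=18.0)
        assert pooled.B == 0.0
        assert pooled.total_var == pytest.approx(0.04)
        assert math.isinf(pooled.upsilon)
        assert pooled.nu_adj == pytest.approx((19.0 / 21.0) * 18.0)
        assert pooled.nu_adj <= 18.0

    def test_degenerate_variances_rejected(self):
        with pytest.raises(mmi.MMIError):
            mmi.rubin_pool([0.1, 0.4], [0.0, 0.0], nu_com=8.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=10),
           st.floats(0.01, 5.0), st.floats(4.0, 100.0))
    def test_pooling_invariants(self, estimates, w, nu_com):
        pooled = mmi.rubin_pool(estimates, [w] * len(estimates), nu_com=nu_com)
        assert pooled.total_var >= pooled.W
        assert pooled.nu_adj <= pooled.nu_com + 1e-9
        assert pooled.ci_low <= pooled.estimate <= pooled.ci_high


class TestImpute:
    def test_no_missingness_returns_identical_copies(self, s1_small):
        cfg = mmi.ImputationConfig(Q=3, burn_in=10, thin=2, seed=1)
        imputed = mmi.impute(s1_small, cfg)
        assert imputed.Q == 3
        for d in imputed.datasets:
            pd.testing.assert_series_equal(d.df["y"], s1_small.df["y"])

    def test_observed_outcomes_never_altered(self, s1_small_incomplete):
        cfg = mmi.ImputationConfig(Q=4, burn_in=20, thin=5, seed=2)
        imputed = mmi.impute(s1_small_incomplete, cfg)
        obs = s1_small_incomplete.df["r"] == 1
        for d in imputed.datasets:
            assert d.df["r"].eq(1).all()
            assert d.df["y"].notna().all()
            np.testing.assert_array_equal(d.df.loc[obs, "y"],
                                          s1_small_incomplete.df.loc[obs, "y"])

    def test_only_missing_positions_vary(self, s1_small_incomplete):
        cfg = mmi.ImputationConfig(Q=6, burn_in=20, thin=5, seed=3)
        imputed = mmi.impute(s1_small_incomplete, cfg)
        miss = s1_small_incomplete.df["r"] == 0
        stacked = np.vstack([d.df.loc[miss, "y"].to_numpy() for d in imputed.datasets])
        assert (stacked.std(axis=0) > 0).any()  # imputations genuinely vary

    def test_deterministic_given_seed(self, s1_small_incomplete):
        cfg = mmi.ImputationConfig(Q=3, burn_in=15, thin=3, seed=9)
        a = mmi.impute(s1_small_incomplete, cfg)
        b = mmi.impute(s1_small_incomplete, cfg)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.df, db.df)


class TestGibbsSampler:
    def test_parameter_recovery(self):
        gamma = np.array([-0.3, 0.8, 0.4])
        tau = 0.45
        data = _probit_trial(150, 50, gamma, tau, seed=12)
        cfg = mmi.ImputationConfig(Q=30, burn_in=100, thin=10, seed=3)
        states = list(mmi.gibbs_probit_fit(data, cfg))
        draws = np.array([s.gamma for s in states])
        post_mean, post_sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
        assert np.all(np.abs(post_mean - gamma) < 3 * post_sd)
        tau2 = np.array([s.tau2 for s in states])
        assert abs(tau2.mean() - tau ** 2) < 3 * tau2.std(ddof=1)

    def test_two_chains_agree(self):
        data = _probit_trial(60, 30, np.array([0.0, 0.5, 0.3]), 0.4, seed=5)
        means, ses = [], []
        for seed in (101, 202):
            cfg = mmi.ImputationConfig(Q=40, burn_in=80, thin=5, seed=seed)
            draws = np.array([s.gamma[1] for s in mmi.gibbs_probit_fit(data, cfg)])
            means.append(draws.mean())
            ses.append(draws.std(ddof=1) / math.sqrt(len(draws)))
        # thinned draws remain autocorrelated; allow a generous factor
        combined = 3 * math.hypot(*ses) + 0.02
        assert abs(means[0] - means[1]) < combined

    def test_cluster_without_observed_outcomes_still_imputed(self):
        cfg_d, _ = dgm.scenario_preset("S1", k=4, m=6)
        data = dgm.simulate_full_data(cfg_d, 8)
        df = data.df.copy()
        df.loc[(df["arm"] == 0) & (df["cluster"] == 1), "y"] = np.nan
        df["r"] = (~df["y"].isna()).astype(np.int64)
        incomplete = TrialDataset(df, k=4, m=6)
        cfg = mmi.ImputationConfig(Q=3, burn_in=20, thin=3, seed=4)
        imputed = mmi.impute(incomplete, cfg)
        for d in imputed.datasets:
            assert d.df["y"].notna().all()

    def test_imputed_rate_matches_quadrature_oracle(self):
        # Among records the mechanism removed, the success rate should match
        # E[pi | R=0] computed by integrating the generative model over the
        # missingness-weighted covariate law.
        from scipy.special import expit

        cfg_d, mcfg = dgm.scenario_preset("S1", k=100, m=50)
        data = dgm.impose_cdm_missingness(dgm.simulate_full_data(cfg_d, 30), mcfg, 31)
        z, w = np.polynomial.hermite_e.hermegauss(64)
        w = w / w.sum()
        x = math.sqrt(cfg_d.sigma_x2) * z
        d = math.sqrt(cfg_d.sigma_b2) * z
        pi = expit(cfg_d.beta1 + x[:, None] + d[None, :])  # arm 1, beta2 = 1
        p_miss = expit(mcfg.psi[1] + x)
        truth = float((w @ (pi * p_miss[:, None]) @ w) / (w @ p_miss))
        cfg = mmi.ImputationConfig(Q=15, seed=6)
        imputed = mmi.impute(data, cfg)
        miss1 = (data.df["r"] == 0) & (data.df["arm"] == 1)
        rates = [d_.df.loc[miss1, "y"].mean() for d_ in imputed.datasets]
        assert np.mean(rates) == pytest.approx(truth, abs=0.025)


class TestAnalyzeWithMMI:
    def test_complete_data_reduces_to_single_analysis(self, s1_small):
        from crtmiss import cluster_level as cl

        cfg = mmi.ImputationConfig(Q=3, burn_in=10, thin=2, seed=7)
        pooled = mmi.analyze_with_mmi(s1_small, "cl_u_rd", cfg)
        single = cl.estimate_rd_unadjusted(cl.cluster_summaries(s1_small, "full"))
        assert pooled.B == 0.0
        assert pooled.estimate == pytest.approx(single.estimate)
        assert pooled.W == pytest.approx(single.se ** 2)

    def test_pooled_result_structure(self, s1_small_incomplete):
        cfg = mmi.ImputationConfig(Q=5, burn_in=30, thin=5, seed=8)
        pooled = mmi.analyze_with_mmi(s1_small_incomplete, "cl_u_rd", cfg)
        assert pooled.Q == 5
        assert pooled.nu_com == 2 * 8 - 2
        assert pooled.nu_adj <= pooled.nu_com
        assert pooled.total_var == pytest.approx(
            pooled.W + (1 + 1 / 5) * pooled.B)

    def test_log_scale_pooling_for_ratio(self, s1_small_incomplete):
        cfg = mmi.ImputationConfig(Q=4, burn_in=20, thin=4, seed=9)
        pooled = mmi.analyze_with_mmi(s1_small_incomplete, "cl_u_rr", cfg)
        assert pooled.scale == "logRR"
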