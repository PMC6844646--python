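"""Random-intercept ML fitting, likelihood-ratio testing and the
coefficient bundles, cross-checked against closed forms, a brute-force
multivariate-normal likelihood and statsmodels MixedLM."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from cfmap.mixedlm import ConvergenceWarning, RandomInterceptModel, analysis_bundles, fit_lmm, ks_test
from cfmap.mixedlm import test_fixed_effect as lrt_pvalue  # alias: avoid pytest collection


def simulate_lmm(rng, beta=(1.0, 0.5), sigma_b=0.1, sigma_e=0.2, g=12, m=100):
    groups = np.repeat(np.arange(g), m)
    x = rng.normal(size=g * m)
    y = beta[0] + beta[1] * x + rng.normal(0, sigma_b, g)[groups] + rng.normal(0, sigma_e, g * m)
    return y, x[:, None], groups


class TestFit:
    def test_single_group_collapses_to_ols(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = 2.0 + 0.3 * x + rng.normal(0, 0.5, n)
        res = fit_lmm(y, x[:, None], np.zeros(n))
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)[0]
        np.testing.assert_allclose(res.params, ols, atol=1e-10)
        assert res.sigma2_b == 0.0

    def test_matches_bruteforce_multivariate_normal_ml(self, rng):
        """Tiny balanced design: direct numeric ML over the full N×N
        covariance agrees with the profiled fit to high precision."""
        g, m = 4, 6
        y, X, groups = simulate_lmm(rng, g=g, m=m, sigma_b=0.3, sigma_e=0.4)
        res = fit_lmm(y, X, groups)
        Xd = np.column_stack([np.ones(g * m), X])
        Z = np.zeros((g * m, g))
        Z[np.arange(g * m), groups] = 1.0

        def negll(theta):
            b0, b1, log_sb, log_se = theta
            V = np.exp(2 * log_sb) * Z @ Z.T + np.exp(2 * log_se) * np.eye(g * m)
            resid = y - Xd @ [b0, b1]
            sign, logdet = np.linalg.slogdet(V)
            return 0.5 * (logdet + resid @ np.linalg.solve(V, resid) + g * m * np.log(2 * np.pi))

        start = np.array([res.params[0], res.params[1], -1.0, -1.0])
        brute = optimize.minimize(negll, start, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert res.llf == pytest.approx(-brute.fun, abs=1e-6)
        np.testing.assert_allclose(res.params, brute.x[:2], atol=1e-5)

    def test_agrees_with_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        y, X, groups = simulate_lmm(rng, g=8, m=30, sigma_b=0.3, sigma_e=0.5)
        res = fit_lmm(y, X, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_res = sm.MixedLM(y, np.column_stack([np.ones_like(y), X[:, 0]]), groups).fit(
                reml=False
            )
        np.testing.assert_allclose(res.params, np.asarray(sm_res.params)[:2], atol=1e-5)
        assert res.llf == pytest.approx(sm_res.llf, abs=1e-5)
        assert res.sigma2_e == pytest.approx(sm_res.scale, rel=1e-4)
        assert res.sigma2_b == pytest.approx(float(np.asarray(sm_res.cov_re)[0, 0]), rel=1e-3, abs=1e-6)

    def test_parameter_recovery_coverage(self):
        rng = np.random.default_rng(42)
        cover = 0
        for _ in range(40):
            y, X, groups = simulate_lmm(rng)
            res = fit_lmm(y, X, groups)
            cover += abs(res.params[1] - 0.5) <= 2 * res.bse[1]
        assert cover >= 34  # ~95% nominal coverage

    def test_invariance_to_group_relabelling_and_row_order(self, rng):
        y, X, groups = simulate_lmm(rng, g=6, m=20)
        res = fit_lmm(y, X, groups)
        perm = rng.permutation(len(y))
        relabel = np.array([f"mouse_{g}" for g in groups])
        res2 = fit_lmm(y[perm], X[perm], relabel[perm])
        np.testing.assert_allclose(res.params, res2.params, atol=1e-9)
        assert res.llf == pytest.approx(res2.llf, abs=1e-9)

    def test_profile_likelihood_is_maximal_at_the_fit(self, rng):
        y, X, groups = simulate_lmm(rng, g=10, m=30)
        model = RandomInterceptModel(y, X, groups)
        res = model.fit()
        grid = [model._profile(p)[0] for p in np.geomspace(1e-8, 1e4, 400)]
        assert res.llf >= max(grid) - 1e-5

    def test_collinear_design_raises(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(rng.normal(size=30), X, np.zeros(30))

    def test_summary_mentions_fit_quantities(self, rng):
        y, X, groups = simulate_lmm(rng, g=4, m=10)
        text = fit_lmm(y, X, groups, exog_names=["slope"]).summary()
        assert "log-likelihood" in text and "slope" in text


class TestLikelihoodRatio:
    def test_equal_likelihoods_give_p_one(self, rng):
        import dataclasses

        y, X, groups = simulate_lmm(rng, g=5, m=20, beta=(1.0, 0.0))
        full = fit_lmm(y, X, groups)
        reduced = dataclasses.replace(full, params=full.params[:-1], bse=full.bse[:-1])
        assert lrt_pvalue(full, reduced) == pytest.approx(1.0)

    def test_strong_effect_is_highly_significant(self, rng):
        y, X, groups = simulate_lmm(rng, beta=(1.0, 0.5), sigma_e=0.2)
        full = fit_lmm(y, X, groups)
        reduced = fit_lmm(y, np.empty((len(y), 0)), groups)
        assert lrt_pvalue(full, reduced) < 1e-3

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n = 200
        for _ in range(n):
            y, X, groups = simulate_lmm(rng, beta=(1.0, 0.0), g=12, m=50)
            full = fit_lmm(y, X, groups)
            reduced = fit_lmm(y, np.empty((len(y), 0)), groups)
            rejections += lrt_pvalue(full, reduced) < 0.05
        assert 0.01 <= rejections / n <= 0.10

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(9)
        power = []
        for beta1 in (0.0, 0.01, 0.05):
            hits = 0
            for _ in range(40):
                y, X, groups = simulate_lmm(rng, beta=(1.0, beta1), g=8, m=40)
                full = fit_lmm(y, X, groups)
                reduced = fit_lmm(y, np.empty((len(y), 0)), groups)
                hits += lrt_pvalue(full, reduced) < 0.05
            power.append(hits)
        assert power[0] <= power[2]
        assert power[2] >= 35

    def test_mismatched_data_raises(self, rng):
        y, X, groups = simulate_lmm(rng, g=4, m=10)
        full = fit_lmm(y, X, groups)
        reduced = fit_lmm(y[:-1], np.empty((len(y) - 1, 0)), groups[:-1])
        with pytest.raises(ValueError):
            lrt_pvalue(full, reduced)


class TestKsTest:
    def test_identical_samples_have_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0])
        d, p = ks_test(a, a)
        assert d == 0.0

    def test_disjoint_supports_have_unit_statistic(self):
        d, p = ks_test(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert d == 1.0

    def test_statistic_matches_ecdf_sweep_oracle(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=55)
        d, _ = ks_test(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= x).mean() for x in grid])
        ecdf_b = np.array([(b <= x).mean() for x in grid])
        assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_test(np.empty(0), np.array([1.0]))


class TestAnalysisBundles:
    @staticmethod
    def _toy_table(rng, n_mice=4, n_trials=60, reward_beta=-0.3):
        rows = []
        for mouse in range(n_mice):
            b = rng.normal(0, 0.05)
            for t in range(n_trials):
                lick = rng.uniform() < 0.6
                go = rng.uniform() < 0.5
                reward = lick and go
                latency = rng.uniform(0.1, 0.9) if lick else np.nan
                rate = rng.uniform(4, 8) if lick else np.nan
                noise = lambda: rng.normal(0, 0.05)
                rows.append(
                    {
                        "mouse": f"m{mouse}",
                        "compartment": "6-",
                        "kind": "trial",
                        "outcome": "hit" if reward else ("fa" if lick else ("miss" if go else "cr")),
                        "lick": int(lick),
                        "cue_go": int(go),
                        "reward": int(reward),
                        "latency_s": latency,
                        "bout_rate_hz": rate,
                        "precue_eligible": True,
                        "m_pre_cue": b + 0.1 * lick + noise(),
                        "m_early": b + 0.2 * go + noise(),
                        "m_secondary": b + noise(),
                        "m_late": (b + reward_beta * reward + noise()) if lick else np.nan,
                        "m_pre_trial": noise(),
                        "m_pre_lick": np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def test_recovers_planted_coefficient_signs(self, rng):
        table = self._toy_table(rng)
        out = analysis_bundles(table)
        reward = out[(out.window == "late") & (out.predictor == "reward")].iloc[0]
        assert reward.beta < 0 and reward.p < 0.05
        cue = out[(out.window == "early") & (out.predictor == "cue_go")].iloc[0]
        assert cue.beta > 0 and cue.p < 0.05

    def test_null_predictor_is_not_flagged(self, rng):
        table = self._toy_table(rng)
        out = analysis_bundles(table)
        rate = out[(out.window == "secondary") & (out.predictor == "bout_rate_hz")].iloc[0]
        assert rate.p > 0.001  # no planted secondary effect

    def test_single_mouse_warns_and_reports_zero_variance(self, rng):
        table = self._toy_table(rng, n_mice=1, n_trials=80)
        with pytest.warns(ConvergenceWarning):
            out = analysis_bundles(table)
        assert (out.sigma2_b == 0).all()
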