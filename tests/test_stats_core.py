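"""Mixed-model, beta-regression, LRT and Tukey-adjustment machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvaphen.stats_core import (
    build_condition_design,
    fit_betareg,
    fit_condition_lmm,
    fit_condition_time_lmm,
    fit_lmm,
    lrt,
    smithson_verkuilen,
    tukey_contrasts,
)


def _balanced_data(rng, n_subj=10, n_bins=8, subj_sd=0.0, effect=0.0):
    rows = []
    for cond, shift in [("control", 0.0), ("treated", effect)]:
        for i in range(n_subj):
            u = rng.normal(0, subj_sd)
            for b in range(n_bins):
                rows.append(
                    {
                        "subject_id": f"{cond}{i}",
                        "condition": cond,
                        "t": float(b),
                        "distance_mm": 5.0 + shift + u + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestLMM:
    def test_zero_between_subject_variance_matches_ols(self, rng):
        data = _balanced_data(rng, subj_sd=0.0, effect=1.0)
        res = fit_condition_lmm(data)
        X, names, _ = build_condition_design(data)
        beta = np.linalg.lstsq(X, data["distance_mm"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-6)

    def test_balanced_oneway_condition_means_exact(self, rng):
        data = _balanced_data(rng, effect=2.0)
        res = fit_condition_lmm(data)
        gm = data.groupby("condition")["distance_mm"].mean()
        # balanced design: fixed effects reproduce the group averages
        assert res.params["Intercept"] == pytest.approx(gm["control"], abs=1e-6)
        assert res.params["Intercept"] + res.params["cond[treated]"] == pytest.approx(
            gm["treated"], abs=1e-6
        )

    def test_random_intercept_sd_recovered(self):
        # 20 replicate fits; subject SD 0.3
        ests = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            data = _balanced_data(r, n_subj=30, n_bins=10, subj_sd=0.3)
            res = fit_condition_lmm(data)
            ests.append(np.sqrt(res.random_effect_var))
        m, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(20)
        assert abs(m - 0.3) < 2 * se + 0.02

    def test_single_condition_rejected(self, rng):
        data = _balanced_data(rng)
        data = data[data.condition == "control"]
        with pytest.raises(ValueError):
            fit_condition_lmm(data)

    def test_rank_deficiency_names_term(self, rng):
        data = _balanced_data(rng)
        data["t"] = 1.0  # constant covariate aliases the intercept
        with pytest.raises(ValueError, match="aliased"):
            build_condition_design(data, covariate="t", interaction=False)

    def test_interaction_slopes_recovered(self):
        # control slope 0.5, treated slope 0.2 -> interaction -0.3
        r = np.random.default_rng(7)
        rows = []
        for cond, slope in [("control", 0.5), ("treated", 0.2)]:
            for i in range(20):
                u = r.normal(0, 0.5)
                for b in range(10):
                    rows.append({"subject_id": f"{cond}{i}", "condition": cond,
                                 "t": float(b),
                                 "distance_mm": 3 + u + slope * b + r.normal(0, 0.5)})
        res = fit_condition_time_lmm(pd.DataFrame(rows))
        est, se = res.slopes["control"]
        assert est == pytest.approx(0.5, abs=3 * se)
        est_t, se_t = res.slopes["treated"]
        assert est_t == pytest.approx(0.2, abs=3 * se_t)
        assert res.contrasts[0].estimate == pytest.approx(-0.3, abs=0.1)

    def test_noise_free_input_degrades_to_ols(self):
        rows = []
        for i in range(4):
            for b in range(5):
                rows.append({"subject_id": f"s{i}", "condition": "control",
                             "t": float(b), "distance_mm": 1.0 + 2.0 * b})
        df = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(df)), df["t"]])
        res = fit_lmm(df, "distance_mm", X, ["Intercept", "t"], "subject_id")
        assert res.singular
        assert res.params["t"] == pytest.approx(2.0, abs=1e-9)


class TestBetaReg:
    def test_intercept_only_at_half_is_zero_logit(self):
        y = np.full(40, 0.5)
        res = fit_betareg(y, np.ones((40, 1)), ["Intercept"])
        assert res.params["Intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_boundary_response_rejected(self):
        y = np.array([0.2, 1.0, 0.4])
        with pytest.raises(ValueError):
            fit_betareg(y, np.ones((3, 1)), ["Intercept"])

    def test_logit_linear_slope_recovered(self):
        ests, ses = [], []
        for seed in range(20):
            r = np.random.default_rng(500 + seed)
            x = np.tile(np.arange(10, dtype=float), 5)
            mu = 1.0 / (1.0 + np.exp(-(-1.0 + 0.25 * x)))
            phi = 60.0
            y = r.beta(mu * phi, (1 - mu) * phi)
            X = np.column_stack([np.ones_like(x), x])
            res = fit_betareg(y, X, ["Intercept", "x"])
            ests.append(res.params["x"])
            ses.append(res.bse["x"])
        assert np.mean(ests) == pytest.approx(0.25, abs=2 * np.std(ests, ddof=1) / np.sqrt(20))

    def test_smithson_verkuilen_pulls_off_boundary(self):
        y = smithson_verkuilen(np.array([0.0, 1.0, 0.5]), 48)
        assert 0 < y.min() and y.max() < 1
        assert y[2] == pytest.approx(0.5, abs=1e-12)


class TestLRT:
    def test_identical_models_stat_zero_p_one(self):
        assert lrt((-10.0, 3), (-10.0, 3)) == (0.0, 0.0, 1.0)

    def test_one_extra_parameter_df_one(self):
        stat, df, p = lrt((-12.0, 3), (-10.0, 4))
        assert df == 1.0
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt((-10.0, 4), (-9.0, 3))


class TestTukey:
    def _vectors(self, k):
        # group-mean parameterization: one coefficient per level
        return {f"g{j}": np.eye(k)[j] for j in range(k)}

    def test_two_levels_adjusted_equals_unadjusted(self):
        params = pd.Series([0.0, 1.0], index=["g0", "g1"])
        cov = pd.DataFrame(np.eye(2) * 0.1, index=params.index, columns=params.index)
        (c,) = tukey_contrasts(self._vectors(2), params, cov)
        assert c.p_adjusted == pytest.approx(c.p_unadjusted)

    def test_adjusted_dominates_unadjusted(self, rng):
        for _ in range(10):
            k = 4
            est = rng.normal(0, 1, k)
            params = pd.Series(est, index=[f"g{j}" for j in range(k)])
            cov = pd.DataFrame(np.eye(k) * 0.2, index=params.index, columns=params.index)
            for c in tukey_contrasts(self._vectors(k), params, cov):
                assert c.p_adjusted >= c.p_unadjusted - 1e-12

    def test_familywise_error_controlled_under_null(self):
        # 4 balanced groups under the null: any adjusted p < .05 counts as a
        # familywise error; rate must stay near/below the nominal level
        k, reps, hits = 4, 500, 0
        cov = pd.DataFrame(np.eye(k) / 25.0,
                           index=[f"g{j}" for j in range(k)],
                           columns=[f"g{j}" for j in range(k)])
        r = np.random.default_rng(99)
        for _ in range(reps):
            params = pd.Series(r.normal(0, 0.2, k), index=cov.index)
            cons = tukey_contrasts(self._vectors(k), params, cov, n_draws=40_000)
            hits += any(c.p_adjusted < 0.05 for c in cons)
        # binomial 97.5% bound for p=0.05, n=500
        assert hits <= stats.binom.ppf(0.975, reps, 0.05)
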