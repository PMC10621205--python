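"""Mixed-model stage: VIF, Laplace GLMM estimation, Wald tests, family
selection and conditional R-squared.

Two independent cross-checks pin the estimation engine: the gaussian
family against statsmodels MixedLM (same crossed random-intercept
structure, run live), and the binomial family against coefficients from
R glmmTMB computed on a dataset this suite regenerates bit-identically
from its seed (values frozen below).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kratkit import mixed, synth
from kratkit.mixed import MixedGLM, MixedGLMResults


def _gaussian_dataset(seed, n_id=14, n_night=20, beta=0.8, sd_id=0.5, sd_night=0.5, sd_e=0.5):
    rng = np.random.default_rng(seed)
    u_i = rng.normal(0, sd_id, n_id)
    u_n = rng.normal(0, sd_night, n_night)
    x = rng.normal(size=n_night)
    rows = []
    for i in range(n_id):
        for j in range(n_night):
            rows.append(
                {
                    "individual": f"i{i:02d}",
                    "night": f"n{j:02d}",
                    "x": x[j],
                    "y": 1.0 + beta * x[j] + u_i[i] + u_n[j] + rng.normal(0, sd_e),
                }
            )
    return pd.DataFrame(rows)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        # orthogonalize b against a exactly
        b = b - a * (a @ b) / (a @ a)
        rep = mixed.compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert np.allclose(rep["vif"], 1.0, atol=1e-9)

    def test_correlation_point_eight_closed_form(self):
        # r = 0.8 exactly -> VIF = 1/(1-0.64) = 2.778
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        e = rng.normal(size=500)
        a = (a - a.mean()) / a.std()
        e = e - a * (a @ e) / (a @ a)
        e = (e - e.mean()) / e.std()
        b = 0.8 * a + 0.6 * e
        rep = mixed.compute_vif(pd.DataFrame({"a": a, "b": b})).set_index("predictor")
        assert rep.loc["a", "vif"] == pytest.approx(1.0 / (1.0 - 0.64), abs=1e-3)
        assert rep.loc["b", "vif"] == pytest.approx(2.778, abs=1e-3)

    def test_duplicated_column_reported_infinite(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=100)
        rep = mixed.compute_vif(pd.DataFrame({"a": a, "a2": a.copy()}))
        assert np.isinf(rep["vif"]).all()

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        rep = mixed.compute_vif(X)
        assert (rep["vif"] >= 1.0 - 1e-12).all()


class TestEngineCrossChecks:
    def test_gaussian_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _gaussian_dataset(11, n_id=10, n_night=15)
        fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
        md = smf.mixedlm(
            "y ~ x",
            df,
            groups=np.ones(len(df)),
            vc_formula={"individual": "0 + C(individual)", "night": "0 + C(night)"},
        ).fit(reml=False)
        assert fit.params["x"] == pytest.approx(md.params["x"], abs=1e-5)
        assert fit.params["Intercept"] == pytest.approx(md.params["Intercept"], abs=1e-5)
        assert fit.llf == pytest.approx(md.llf, abs=1e-5)
        assert fit.scale == pytest.approx(md.scale, rel=1e-4)

    def test_binomial_matches_frozen_glmmtmb_fit(self):
        # Reference values from glmmTMB 1.1.9:
        #   glmmTMB(cbind(n_windows, n_total - n_windows) ~ humidity_z +
        #           (1|individual) + (1|night), family = binomial)
        # on the dataset regenerated below (bit-identical from the seed).
        data, _ = synth.simulate_budget_dataset(14, 20, beta_humidity=0.0, seed=20007)
        fit = mixed.fit_mixed(
            "proportion ~ humidity_z", data, family="binomial", weights="n_total"
        )
        assert fit.params["Intercept"] == pytest.approx(-1.2566980, abs=5e-3)
        assert fit.params["humidity_z"] == pytest.approx(-0.1686323, abs=2e-3)
        assert fit.bse["Intercept"] == pytest.approx(0.1934053, abs=2e-3)
        assert fit.bse["humidity_z"] == pytest.approx(0.0929062, abs=2e-3)
        assert fit.llf == pytest.approx(-775.5001, abs=1e-2)
        assert np.sqrt(fit.vc["individual"]) == pytest.approx(0.63427, abs=5e-3)
        assert np.sqrt(fit.vc["night"]) == pytest.approx(0.40676, abs=5e-3)


class TestFitMixed:
    def test_gaussian_recovery_of_known_slope(self):
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            df = _gaussian_dataset(1000 + s)
            fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
            if abs(fit.params["x"] - 0.8) <= 0.25:
                hits += 1
        assert hits >= 0.90 * n_rep

    def test_zero_variance_random_effect_estimated_at_boundary(self):
        df = _gaussian_dataset(5, sd_id=0.0, sd_night=0.0, sd_e=0.3)
        fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
        assert np.sqrt(fit.vc["individual"]) <= 0.1
        assert np.sqrt(fit.vc["night"]) <= 0.1

    def test_refit_is_deterministic(self):
        data, _ = synth.simulate_budget_dataset(8, 10, beta_humidity=0.4, seed=77)
        f1 = mixed.fit_mixed("proportion ~ humidity_z", data, family="binomial", weights="n_total")
        f2 = mixed.fit_mixed("proportion ~ humidity_z", data, family="binomial", weights="n_total")
        assert np.allclose(f1.params, f2.params, atol=1e-8)
        assert f1.llf == pytest.approx(f2.llf, abs=1e-8)

    def test_single_level_random_factor_rejected(self):
        df = _gaussian_dataset(6, n_id=1, n_night=10)
        with pytest.raises(ValueError, match="at least 2 levels"):
            mixed.fit_mixed("y ~ x", df, family="gaussian")

    def test_rank_deficient_design_rejected(self):
        df = _gaussian_dataset(7, n_id=4, n_night=6)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="rank-deficient"):
            mixed.fit_mixed("y ~ x + x2", df, family="gaussian")

    def test_summary_mentions_family_and_terms(self):
        df = _gaussian_dataset(8, n_id=5, n_night=8)
        fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
        text = fit.summary()
        assert "gaussian" in text and "x" in text and "AIC" in text


class TestWald:
    def _results_with(self, beta, se):
        # hand-built results object: Wald pieces only need params + cov
        df = _gaussian_dataset(9, n_id=4, n_night=5)
        model = MixedGLM.from_formula("y ~ x", df, family="gaussian")
        fit = model.fit()
        fit.params[:] = [0.0, beta]
        cov = fit.cov_params.to_numpy()
        cov[1, 1] = se**2
        return fit

    def test_single_coefficient_chi_square_closed_form(self):
        fit = self._results_with(0.2, 0.1)  # b/se = 2 -> chi2 = 4
        row = fit.wald_test_terms(["x"]).iloc[0]
        assert row["chi2"] == pytest.approx(4.0)
        assert row["df"] == 1
        assert row["p"] == pytest.approx(0.0455, abs=1e-3)

    def test_zero_coefficient_gives_p_one(self):
        fit = self._results_with(0.0, 0.1)
        row = fit.wald_test_terms(["x"]).iloc[0]
        assert row["chi2"] == 0.0
        assert row["p"] == 1.0

    def test_null_p_values_are_uniform(self):
        # binomial nulls; the Wald test is asymptotic, so calibration is
        # checked at a design with enough random-effect levels for the
        # chi-square reference to hold.  KS test against U(0,1).
        ps = []
        for s in range(200):
            data, _ = synth.simulate_budget_dataset(
                25, 50, beta_humidity=0.0, sd_individual=0.3, sd_night=0.3,
                trials_mean=40, seed=60000 + s,
            )
            fit = mixed.fit_mixed(
                "proportion ~ humidity_z", data, family="binomial", weights="n_total"
            )
            ps.append(fit.wald_test_terms(["humidity_z"]).iloc[0]["p"])
        stat = stats.kstest(ps, "uniform")
        assert stat.pvalue > 0.01


class TestFamilySelection:
    def test_binomial_generated_data_selects_binomial(self):
        wins = 0
        n_rep = 50
        for s in range(n_rep):
            data, _ = synth.simulate_budget_dataset(
                10, 20, beta_humidity=0.4, seed=40000 + s
            )
            sel = mixed.select_family(
                "proportion ~ humidity_z", data, weights="n_total"
            )
            wins += sel.best.family == "binomial"
        assert wins >= 0.90 * n_rep

    def test_single_feasible_candidate_returned(self):
        data, _ = synth.simulate_budget_dataset(6, 8, seed=1)
        sel = mixed.select_family(
            "proportion ~ humidity_z", data, candidates=("gaussian",), weights="n_total"
        )
        assert sel.best.family == "gaussian"

    def test_aic_table_sorted_and_best_is_first(self):
        data, _ = synth.simulate_budget_dataset(8, 12, seed=2)
        sel = mixed.select_family("proportion ~ humidity_z", data, weights="n_total")
        aics = sel.aic_table["aic"].to_numpy()
        assert np.all(np.diff(aics) >= 0)
        assert sel.aic_table.iloc[0]["family"] == sel.best.family

    def test_infeasible_candidates_are_skipped_with_reason(self):
        data, _ = synth.simulate_budget_dataset(6, 8, seed=3)
        data.loc[0, "proportion"] = 0.0  # a zero makes gamma infeasible
        sel = mixed.select_family("proportion ~ humidity_z", data, weights="n_total")
        assert "gamma" in sel.skipped
        assert "poisson" in sel.skipped


class TestConditionalR2:
    def test_known_variance_components_give_half(self):
        # var_f = 1 (beta=1, x~N(0,1)), var_r = 1, var_e = 2 -> R2c = 0.5
        rng = np.random.default_rng(123)
        n_id, n_night = 50, 20
        u_i = rng.normal(0, np.sqrt(0.5), n_id)
        u_n = rng.normal(0, np.sqrt(0.5), n_night)
        rows = []
        for i in range(n_id):
            for j in range(n_night):
                x = rng.normal()
                rows.append(
                    {
                        "individual": i,
                        "night": j,
                        "x": x,
                        "y": x + u_i[i] + u_n[j] + rng.normal(0, np.sqrt(2.0)),
                    }
                )
        df = pd.DataFrame(rows)
        fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
        assert fit.conditional_r2() == pytest.approx(0.5, abs=0.05)

    def test_null_model_r2_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "individual": np.repeat(np.arange(10), 10),
                "night": np.tile(np.arange(10), 10),
                "x": rng.normal(size=100) * 1e-8,
                "y": rng.normal(size=100),
            }
        )
        fit = mixed.fit_mixed("y ~ x", df, family="gaussian")
        assert fit.conditional_r2() <= 0.15

    def test_r2_bounded_on_random_fits(self):
        for s in range(10):
            data, _ = synth.simulate_budget_dataset(6, 8, beta_humidity=0.3, seed=500 + s)
            fit = mixed.fit_mixed(
                "proportion ~ humidity_z", data, family="binomial", weights="n_total"
            )
            assert 0.0 <= fit.conditional_r2() <= 1.0
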