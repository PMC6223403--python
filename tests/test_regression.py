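"""Covariate coding, logistic fitting, marginals, and the sensitivity suite."""

import numpy as np
import pandas as pd
import pytest

from hypoburden import regression as rg
from hypoburden.errors import DataError, SeparationError
from hypoburden.synthetic import (recovery_design_spec,
                                  simulate_regression_replicate)

from _oracles import irls_logistic


class TestCovariateCoding:
    @pytest.mark.parametrize("age,cat", [(40, "<65"), (65, "65-74"), (70, "65-74"),
                                         (75, "75-84"), (85, ">=85")])
    def test_age_bands(self, age, cat):
        assert rg.age_category(age) == cat

    @pytest.mark.parametrize("sofa,cat", [(2, "<=4"), (4, "<=4"), (5, ">4 to <=6"),
                                          (8, ">6 to <=8"), (11, ">10")])
    def test_sofa_bands(self, sofa, cat):
        assert rg.sofa_category(sofa) == cat

    def test_lab_missingness_is_a_category(self):
        assert rg.lactate_category(np.nan) == "missing"
        assert rg.lactate_category(2.0) == ">=2.0"
        assert rg.albumin_category(2.4) == "<2.5"
        assert rg.creatinine_category(1.9) == "<2.0"

    def test_reference_record_encodes_to_intercept_only(self):
        spec = recovery_design_spec()
        cov = pd.DataFrame({"duration": ["never below"], "sex": ["male"],
                            "ventilated": ["no"], "lactate": ["<2.0"]})
        X = spec.encode(cov)
        assert X.iloc[0]["const"] == 1.0
        assert X.iloc[0].drop("const").sum() == 0.0

    def test_unseen_category_names_the_field(self):
        spec = recovery_design_spec()
        cov = pd.DataFrame({"duration": ["sometimes"], "sex": ["male"],
                            "ventilated": ["no"], "lactate": ["<2.0"]})
        with pytest.raises(DataError, match="duration"):
            spec.encode(cov)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = pd.DataFrame({"const": np.ones(100)})
        fit = rg.fit_logistic(X, y)
        assert fit.params["const"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_matches_independent_irls_to_1e8(self, rng):
        n = 400
        X = pd.DataFrame({
            "const": np.ones(n),
            "a": rng.normal(size=n),
            "b": (rng.random(n) < 0.4).astype(float),
            "c": rng.normal(size=n),
        })
        lp = -0.5 + 0.8 * X["a"] - 1.1 * X["b"] + 0.3 * X["c"]
        y = rng.random(n) < 1 / (1 + np.exp(-lp))
        fit = rg.fit_logistic(X, y)
        beta, se = irls_logistic(X.to_numpy(), y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert np.allclose(fit.table["se"].to_numpy(), se, atol=1e-8)

    def test_wald_columns_consistent(self, rng):
        n = 300
        X = pd.DataFrame({"const": np.ones(n), "a": rng.normal(size=n)})
        y = rng.random(n) < 0.3
        t = rg.fit_logistic(X, y).table
        assert np.allclose(t["odds_ratio"], np.exp(t["estimate"]))
        assert np.allclose(t["wald_chi2"], (t["estimate"] / t["se"]) ** 2)

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        X = pd.DataFrame({"const": np.ones(40), "x": x})
        with pytest.raises(SeparationError):
            rg.fit_logistic(X, x.astype(bool))

    def test_degenerate_outcome_detected(self):
        X = pd.DataFrame({"const": np.ones(30)})
        with pytest.raises(SeparationError):
            rg.fit_logistic(X, np.zeros(30))

    def test_rank_deficiency_names_collinear_terms(self, rng):
        n = 100
        a = rng.normal(size=n)
        X = pd.DataFrame({"const": np.ones(n), "a": a, "twice_a": 2 * a})
        with pytest.raises(DataError, match="twice_a"):
            rg.fit_logistic(X, rng.random(n) < 0.5)

    def test_record_order_invariance(self, rng):
        cov, y, _ = simulate_regression_replicate(2000, rng)
        spec = recovery_design_spec()
        fit1 = rg.fit_logistic(spec.encode(cov), y, spec=spec)
        perm = rng.permutation(len(y))
        fit2 = rg.fit_logistic(spec.encode(cov.iloc[perm].reset_index(drop=True)),
                               y[perm], spec=spec)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-12)


class TestMarginalMortality:
    def test_constant_model_gives_constant_marginals(self, rng):
        cov, y, _ = simulate_regression_replicate(500, rng)
        spec = recovery_design_spec()
        fit = rg.fit_logistic(spec.encode(cov), y, spec=spec)
        fit.params[:] = 0.0
        fit.params["const"] = np.log(0.3 / 0.7)
        marg = rg.marginal_mortality(fit, cov, "duration")
        assert np.allclose(marg.to_numpy(), 0.3, atol=1e-12)

    def test_matches_per_record_average_oracle(self, rng):
        cov, y, _ = simulate_regression_replicate(1500, rng)
        spec = recovery_design_spec()
        fit = rg.fit_logistic(spec.encode(cov), y, spec=spec)
        marg = rg.marginal_mortality(fit, cov, "lactate")
        for cat in ("<2.0", ">=2.0"):
            cf = cov.copy()
            cf["lactate"] = cat
            X = spec.encode(cf)[fit.params.index].to_numpy()
            p = 1 / (1 + np.exp(-(X @ fit.params.to_numpy())))
            assert marg[cat] == pytest.approx(p.mean(), abs=1e-12)

    def test_monotone_coefficients_give_monotone_marginals(self, rng):
        cov, y, _ = simulate_regression_replicate(4000, rng)
        spec = recovery_design_spec()
        fit = rg.fit_logistic(spec.encode(cov), y, spec=spec)
        # force a clean monotone ladder, then check the standardised marginals
        for i, lab in enumerate(spec.terms["duration"][0][1:]):
            fit.params[f"duration[{lab}]"] = 0.2 * (i + 1)
        marg = rg.marginal_mortality(fit, cov, "duration")
        assert (np.diff(marg.to_numpy()) > 0).all()

    def test_unknown_term_rejected(self, rng):
        cov, y, _ = simulate_regression_replicate(500, rng)
        spec = recovery_design_spec()
        fit = rg.fit_logistic(spec.encode(cov), y, spec=spec)
        with pytest.raises(DataError):
            rg.marginal_mortality(fit, cov, "potassium")


@pytest.fixture(scope="module")
def pipeline_frames():
    """Cohort-level frames (baselines, exposures, outcomes, stays) at n=2500."""
    from hypoburden.cohort import select_cohort
    from hypoburden.pipeline import attribute_outcomes, compute_exposures
    from hypoburden.synthetic import SimConfig, simulate_cohort
    tables, truth = simulate_cohort(SimConfig(n_stays=2500, seed=5))
    cohort, _, support = select_cohort(tables["stays"], tables["infusions"],
                                       tables["map_readings"], tables["transfusions"],
                                       tables["codes"])
    exposures = compute_exposures(cohort, tables["map_readings"], tables["infusions"],
                                  tables["baselines"], support)
    outcomes = attribute_outcomes(cohort, tables["deaths"])
    return tables["baselines"], exposures, outcomes, cohort, truth


class TestEndToEndModel:
    def test_primary_fit_recovers_positive_duration_gradient(self, pipeline_frames):
        baselines, exposures, outcomes, cohort, truth = pipeline_frames
        cov = rg.encode_covariates(baselines, exposures)
        y = outcomes.set_index("stay_id")["icu_death"].loc[cov.index].to_numpy(bool)
        fit = rg.fit_primary_model(cov, y)
        durs = fit.table[fit.table.index.str.startswith("duration[")]
        # the planted ladder is positive everywhere; the fitted short-vs-long
        # contrast must point the same way
        assert durs["estimate"].iloc[-1] > durs["estimate"].iloc[0]
        assert (durs["estimate"] > 0).mean() > 0.7

    def test_threshold_sweep_matches_primary_at_65(self, pipeline_frames):
        baselines, exposures, outcomes, _, _ = pipeline_frames
        cov = rg.encode_covariates(baselines, exposures)
        y = outcomes.set_index("stay_id")["icu_death"].loc[cov.index].to_numpy(bool)
        fits = rg.threshold_sweep(baselines, exposures, y, thresholds=(65.0,))
        primary = rg.fit_primary_model(cov, y)
        assert np.allclose(fits[65.0].params.to_numpy(), primary.params.to_numpy(),
                           atol=1e-10)

    def test_sensitivity_suite_layout(self, pipeline_frames):
        baselines, exposures, outcomes, cohort, _ = pipeline_frames
        res = rg.sensitivity_suite(baselines, exposures, outcomes, cohort)
        assert set(res) == {"primary", "exclude_first_24h_deaths", "day28_mortality",
                            "six_hour_bins", "post2008_only"}
        tab = rg.sensitivity_table(res)
        assert "primary" in tab.columns
        if res["six_hour_bins"] is not None:
            assert any(lab in tab.index for lab in (">0 to <6", ">=6 to <12"))

    def test_28day_variant_changes_only_outcome(self, pipeline_frames):
        baselines, exposures, outcomes, cohort, _ = pipeline_frames
        res = rg.sensitivity_suite(baselines, exposures, outcomes, cohort)
        cov = rg.encode_covariates(baselines, exposures)
        y28 = outcomes.set_index("stay_id")["day28_death"].loc[cov.index].to_numpy(bool)
        if res["day28_mortality"] is None:
            # the suite's report must agree with a direct fit attempt
            with pytest.raises(SeparationError):
                rg.fit_primary_model(cov, y28)
        else:
            assert res["day28_mortality"].n == res["primary"].n
            direct = rg.fit_primary_model(cov, y28)
            assert np.allclose(direct.params.to_numpy(),
                               res["day28_mortality"].params.to_numpy(), atol=1e-10)
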