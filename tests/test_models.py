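"""Model fitting and scoring, cross-checked against statsmodels."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from iohdef import pipeline
from iohdef.design import ModelMatrix, build_model_matrix
from iohdef.metrics import IOHDefinition, default_registry
from iohdef.models import brier_score, fit_model, hosmer_lemeshow, mse


def simple_matrix(X_cols: dict, y, outcome="mortality"):
    X = pd.DataFrame(X_cols)
    return ModelMatrix(
        outcome=outcome,
        y=np.asarray(y, float),
        X=X,
        groups={"all": list(X.columns)},
        patient_ids=np.arange(len(y)),
        meta={"definition": {"name": "x", "kind": "sustained_min_map"}},
    )


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        mm = simple_matrix({"intercept": np.ones(100)}, y)
        fit = fit_model(mm)
        assert fit.params["intercept"] == pytest.approx(logit(0.1), abs=1e-6)
        assert fit.converged

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.random(500) < expit(-1 + 0.8 * x)
        mm = simple_matrix({"intercept": np.ones(500), "x": x}, y.astype(float))
        fit = fit_model(mm)
        ref = sm.GLM(y.astype(float), sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.params["intercept"] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.params["x"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-5)
        assert np.allclose(fit.cov.to_numpy(), ref.cov_params(), atol=1e-6)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-2 + 0.8 * x)).astype(float)
        fit = fit_model(simple_matrix({"intercept": np.ones(n), "x": x}, y))
        se = np.sqrt(fit.cov.loc["x", "x"])
        assert abs(fit.params["x"] - 0.8) < 3 * se

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()  # perfectly separated
        fit = fit_model(simple_matrix({"intercept": np.ones(40), "x": x}, y))
        assert fit.separation_flag

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_model(
                simple_matrix({"intercept": np.ones(200), "x": x, "x2": 2 * x}, y)
            )
        assert len(fit.dropped_columns) == 1


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 1, 50)
        mm = simple_matrix({"intercept": np.ones(50), "x": x}, 2 * x, outcome="hlos")
        fit = fit_model(mm)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.scale == pytest.approx(0.0, abs=1e-18)

    def test_loglik_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = 1 + 0.5 * x + rng.normal(0, 0.7, 300)
        fit = fit_model(simple_matrix({"intercept": np.ones(300), "x": x}, y, "hlos"))
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-8)
        # AIC counts the residual variance as an estimated parameter
        assert fit.aic == pytest.approx(ref.aic + 2, abs=1e-5)

    def test_aic_identity(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        fit = fit_model(simple_matrix({"intercept": np.ones(100), "x": x}, y, "hlos"))
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)


class TestScores:
    def test_brier_closed_forms(self):
        assert brier_score(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0
        assert brier_score(np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)]) == 0.25
        assert brier_score(np.array([0.8, 0.2]), np.array([1.0, 0.0])) == pytest.approx(0.04)

    def test_brier_domain_checks(self):
        with pytest.raises(ValueError):
            brier_score(np.array([1.2]), np.array([1.0]))
        with pytest.raises(ValueError):
            brier_score(np.array([0.5, 0.5]), np.array([1.0]))

    def test_mse_closed_forms(self):
        assert mse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert mse(np.array([1.0, -1.0]), np.zeros(2)) == 1.0
        assert mse(np.array([0.3, 0.4]), np.zeros(2)) == pytest.approx(0.125)

    def test_brier_bounded(self):
        rng = np.random.default_rng(21)
        p = rng.random(100)
        y = (rng.random(100) < 0.5).astype(float)
        assert 0.0 <= brier_score(p, y) <= 1.0


class TestHosmerLemeshow:
    def test_perfect_calibration_zero_statistic(self):
        # ten groups whose observed rate equals the predicted rate exactly
        probs = np.repeat(np.linspace(0.05, 0.5, 10), 20)
        y = np.concatenate([
            np.r_[np.ones(round(20 * p)), np.zeros(20 - round(20 * p))]
            for p in np.linspace(0.05, 0.5, 10)
        ])
        stat, pval = hosmer_lemeshow(probs, y)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert pval == pytest.approx(1.0)

    def test_df_rule(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p).astype(float)
        stat, pval = hosmer_lemeshow(p, y, groups=10)
        from scipy.stats import chi2

        assert pval == pytest.approx(chi2.sf(stat, 8))

    def test_few_distinct_predictions_reduce_groups(self):
        p = np.repeat([0.1, 0.2, 0.3, 0.4], 25)
        y = (np.random.default_rng(3).random(100) < p).astype(float)
        with pytest.warns(UserWarning, match="distinct"):
            hosmer_lemeshow(p, y, groups=10)

    def test_well_specified_model_not_rejected_typically(self):
        # p-values from a well-specified model should not pile up near 0
        rng = np.random.default_rng(29)
        pvals = []
        for _ in range(40):
            x = rng.normal(size=2000)
            y = (rng.random(2000) < expit(-1.5 + 0.7 * x)).astype(float)
            fit = fit_model(simple_matrix({"intercept": np.ones(2000), "x": x}, y))
            p = expit(np.column_stack([np.ones(2000), x]) @ fit.params.to_numpy())
            pvals.append(hosmer_lemeshow(p, y)[1])
        assert np.mean(np.array(pvals) < 0.01) < 0.2


class TestOnCohortDesign:
    def test_full_design_fit_matches_statsmodels(self, small_cohort):
        feats, _, _ = pipeline.compute_features(
            small_cohort.public_vitals(), default_registry()
        )
        cohort = small_cohort.cohort_table.merge(feats, on="patient_id")
        mm = build_model_matrix(cohort, IOHDefinition("sustained_min_map", 1), "hlos")
        fit = fit_model(mm)
        ref = sm.OLS(mm.y, mm.X.to_numpy()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
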