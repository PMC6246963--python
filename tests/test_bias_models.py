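"""Mixed-effects bias models, checked against statsmodels and OLS oracles."""

import numpy as np
import pandas as pd
import pytest

from crowdcal.bias_models import (
    REGISTERED_MODELS,
    density_bias_curve,
    density_mass_correlation,
    fit_bias_model,
    fit_crossed_lmm,
)
from crowdcal.error_metrics import compute_metrics
from crowdcal.qc_filters import apply_qc
from crowdcal.quiz_model import FoodItem, FoodType, QuizSpec
from crowdcal.synthetic_cohort import SimulationConfig, simulate_cohort


def _quiz_from(pairs):
    return QuizSpec(
        foods=tuple(
            FoodItem(f"f{i}", f"f{i}", FoodType.FRUIT, e, m, False)
            for i, (e, m) in enumerate(pairs)
        )
    )


class TestDensityMassCorrelation:
    def test_packaged_quiz_matches_published_value(self, quiz):
        assert round(density_mass_correlation(quiz), 2) == -0.70

    def test_constant_density_is_missing(self):
        q = _quiz_from([(100, 100), (200, 200), (300, 300)])
        assert np.isnan(density_mass_correlation(q))

    def test_two_foods_give_plus_minus_one(self):
        q = _quiz_from([(100, 50), (100, 200)])  # density falls as mass rises
        assert density_mass_correlation(q) == pytest.approx(-1.0)
        q2 = _quiz_from([(100, 50), (800, 200)])  # density rises with mass
        assert density_mass_correlation(q2) == pytest.approx(1.0)

    def test_single_food_rejected(self):
        with pytest.raises(ValueError):
            density_mass_correlation(_quiz_from([(100, 50)]))


def _fitted_cohort(quiz, **overrides):
    base = dict(
        n_participants=80, n_experts=0, seed=21, sigma_noise=0.25,
        p_invalid_bmi=0.0, p_missing_gender=0.0,
    )
    base.update(overrides)
    participants, responses = simulate_cohort(quiz, SimulationConfig(**base))
    metrics = compute_metrics(responses, quiz)
    return participants, metrics


class TestCrossedReml:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM with both intercepts as
        variance components must reproduce our REML fixed effects and SEs."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(10)
        n_p, n_f = 40, 12
        x_food = rng.normal(0, 1, n_f)
        u = rng.normal(0, 0.4, n_p)
        v = rng.normal(0, 0.3, n_f)
        pc = np.repeat(np.arange(n_p), n_f)
        fc = np.tile(np.arange(n_f), n_p)
        y = 1.5 + 0.8 * x_food[fc] + u[pc] + v[fc] + rng.normal(0, 0.5, n_p * n_f)
        X = np.column_stack([np.ones_like(y), x_food[fc]])

        ours = fit_crossed_lmm(y, X, pc, fc)

        df = pd.DataFrame({"y": y, "x": x_food[fc], "pid": pc, "fid": fc})
        sm_fit = smf.mixedlm(
            "y ~ x", df, groups=np.ones(len(df)),
            vc_formula={"pid": "0 + C(pid)", "fid": "0 + C(fid)"},
        ).fit(reml=True)
        assert ours.beta[1] == pytest.approx(sm_fit.fe_params["x"], rel=1e-4)
        assert ours.beta[0] == pytest.approx(sm_fit.fe_params["Intercept"], rel=1e-3)
        assert ours.se[1] == pytest.approx(sm_fit.bse_fe["x"], rel=1e-3)
        assert ours.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_zero_variance_components_reduce_to_ols(self):
        rng = np.random.default_rng(3)
        n_p, n_f = 60, 10
        x = rng.normal(0, 1, n_f)
        pc = np.repeat(np.arange(n_p), n_f)
        fc = np.tile(np.arange(n_f), n_p)
        y = 2.0 - 0.5 * x[fc] + rng.normal(0, 0.3, n_p * n_f)
        X = np.column_stack([np.ones_like(y), x[fc]])
        fit = fit_crossed_lmm(y, X, pc, fc)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, rtol=0.01)


class TestRegisteredModels:
    def test_density_bias_recovers_injected_positive_slope(self, quiz):
        participants, metrics = _fitted_cohort(
            quiz, n_participants=200, beta_density=0.3, sigma_noise=0.2, sd_food=0.1
        )
        fit = fit_bias_model(metrics, participants, quiz, "density_bias")
        coef = fit.coefficients["centered_log_density"]
        assert fit.converged
        assert coef["estimate"] > 0
        assert coef["p_value"] < 0.05
        assert fit.outcome == "e"

    def test_bmi_density_interaction_recovery(self, quiz):
        participants, metrics = _fitted_cohort(
            quiz, n_participants=250, beta_bmi_density=0.02, sigma_noise=0.2
        )
        fit = fit_bias_model(metrics, participants, quiz, "bmi_density_interaction")
        coef = fit.coefficients["bmi_x_density"]
        assert coef["estimate"] > 0 and coef["p_value"] < 0.05
        assert fit.outcome == "eta"

    def test_demographics_recovery(self, quiz):
        participants, metrics = _fitted_cohort(
            quiz, n_participants=250, beta_male=0.25, sigma_noise=0.2
        )
        fit = fit_bias_model(metrics, participants, quiz, "demographics")
        assert fit.coefficients["male"]["estimate"] > 0
        assert fit.coefficients["male"]["p_value"] < 0.05

    def test_reference_object_model_runs_on_null_data(self, quiz):
        participants, metrics = _fitted_cohort(quiz)
        fit = fit_bias_model(metrics, participants, quiz, "reference_object")
        assert fit.converged
        assert set(fit.coefficients) == {"intercept", "has_reference_object"}
        assert 0.0 <= fit.r_squared <= 1.0
        assert fit.n_obs == len(metrics)

    def test_perfect_linear_outcome_gives_r_squared_one(self, quiz):
        """Outcome equal to the model's own prediction: r_squared = 1."""
        participants, metrics = _fitted_cohort(quiz, n_participants=40)
        density = {f.food_id: f.energy_kcal / f.mass_g for f in quiz.foods}
        cld = np.log(metrics["food_id"].map(density))
        metrics = metrics.assign(e=5.0 + 3.0 * (cld - cld.mean()))
        fit = fit_bias_model(metrics, participants, quiz, "density_bias")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_r_squared_invariant_to_affine_outcome_rescale(self, quiz):
        participants, metrics = _fitted_cohort(quiz, n_participants=60, beta_density=0.2)
        fit1 = fit_bias_model(metrics, participants, quiz, "density_bias")
        rescaled = metrics.assign(e=metrics["e"] * 3.0 + 10.0)
        fit2 = fit_bias_model(rescaled, participants, quiz, "density_bias")
        assert fit1.r_squared == pytest.approx(fit2.r_squared, rel=1e-3)

    def test_degenerate_variance_matches_ols_within_one_percent(self, quiz):
        participants, metrics = _fitted_cohort(
            quiz, n_participants=100, beta_density=0.3,
            sd_participant=0.0, sd_food=0.0, sigma_noise=0.2,
        )
        fit = fit_bias_model(metrics, participants, quiz, "density_bias")
        density = np.array([f.energy_kcal / f.mass_g for f in quiz.foods])
        cld_map = dict(zip(quiz.food_ids, np.log(density) - np.log(density).mean()))
        x = metrics["food_id"].map(cld_map).to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        ols = np.linalg.lstsq(X, metrics["e"].to_numpy(), rcond=None)[0]
        est = fit.coefficients["centered_log_density"]["estimate"]
        assert abs(est - ols[1]) / abs(ols[1]) < 0.01

    def test_unknown_model_rejected(self, quiz):
        participants, metrics = _fitted_cohort(quiz, n_participants=5)
        with pytest.raises(ValueError, match="registered"):
            fit_bias_model(metrics, participants, quiz, "astrology")

    def test_all_registered_models_fit_after_qc(self, quiz):
        config = SimulationConfig(n_participants=60, n_experts=0, seed=8, sigma_noise=0.3)
        participants, responses = simulate_cohort(quiz, config)
        participants, responses, _ = apply_qc(participants, responses, quiz)
        metrics = compute_metrics(responses, quiz)
        for name in REGISTERED_MODELS:
            fit = fit_bias_model(metrics, participants, quiz, name)
            assert fit.n_obs > 0
            assert np.isfinite(fit.sigma2)


class TestDensityBiasCurve:
    def test_positive_density_bias_gives_positive_trend(self, quiz):
        from scipy.stats import spearmanr

        participants, metrics = _fitted_cohort(
            quiz, n_participants=200, beta_density=0.3, sigma_noise=0.2
        )
        curve = density_bias_curve(metrics, quiz)
        rho = spearmanr(curve["energy_density_kcal_g"], curve["mean_eta"]).statistic
        assert rho > 0.5

    def test_rows_sorted_by_density(self, quiz, clean_metrics):
        curve = density_bias_curve(clean_metrics, quiz)
        assert curve["energy_density_kcal_g"].is_monotonic_increasing
        assert len(curve) == 20

    def test_single_food_single_row(self):
        q = _quiz_from([(200, 100)])
        metrics = compute_metrics(
            pd.DataFrame(
                {"participant_id": ["p1"], "food_id": ["f0"], "estimate_kcal": [250.0]}
            ),
            q,
        )
        curve = density_bias_curve(metrics, q)
        assert len(curve) == 1
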