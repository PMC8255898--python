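import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthlnc import (
    GrowthCurveFit,
    GrowthModelParams,
    evaluate_model,
    fit_growth_curve,
    fit_report,
    goodness_of_fit,
    inflection_summary,
    rank_models,
    read_weight_records,
    simulate_growth_cohort,
)

from conftest import TABLE1_PARAMS


class TestEvaluateModel:
    def test_logistic_halfway_at_inflection_age(self, table1_params):
        p = table1_params["logistic"]
        t_ip = np.log(p.B) / p.k
        assert evaluate_model(p, t_ip) == pytest.approx(p.A / 2, rel=1e-12)

    def test_von_bertalanffy_birth_weight_by_substitution(self, table1_params):
        p = table1_params["von_bertalanffy"]
        expected = p.A * (1 - p.B) ** 3  # direct substitution at t=0
        assert evaluate_model(p, 0.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "von_bertalanffy"])
    def test_asymptote(self, table1_params, model):
        p = table1_params[model]
        assert evaluate_model(p, 1e6) == pytest.approx(p.A, abs=1e-6)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "von_bertalanffy"])
    def test_strictly_increasing(self, table1_params, model):
        t = np.linspace(0, 600, 200)
        w = evaluate_model(table1_params[model], t)
        assert np.all(np.diff(w) > 0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            GrowthModelParams("richards", 100, 1, 0.01)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GrowthModelParams("logistic", 100, -1, 0.01)


class TestInflectionSummary:
    def test_logistic_published_inflection_age(self, table1_params):
        s = inflection_summary(table1_params["logistic"])
        assert s.age == pytest.approx(182.03, abs=0.01)
        assert not s.before_birth

    def test_von_bertalanffy_published_weight_and_gain(self, table1_params):
        s = inflection_summary(table1_params["von_bertalanffy"])
        assert s.weight == pytest.approx(58.93, abs=0.01)
        assert s.max_daily_gain == pytest.approx(442, rel=1e-3)

    def test_gompertz_weight_is_a_over_e(self, table1_params):
        s = inflection_summary(table1_params["gompertz"])
        assert s.weight == pytest.approx(165.829 / np.e, rel=1e-12)
        assert s.weight == pytest.approx(61.01, abs=0.01)

    def test_inflection_before_birth_flagged_not_clamped(self):
        p = GrowthModelParams("logistic", 100, 0.5, 0.01)
        with pytest.warns(UserWarning, match="precedes birth"):
            s = inflection_summary(p)
        assert s.before_birth
        assert s.age < 0

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "von_bertalanffy"])
    def test_weight_and_gain_consistent_with_curve(self, table1_params, model):
        """Closed forms vs the curve itself and its numerical derivative."""
        p = table1_params[model]
        s = inflection_summary(p)
        assert evaluate_model(p, s.age) == pytest.approx(s.weight, rel=1e-10)
        h = 1e-3
        deriv = (evaluate_model(p, s.age + h) - evaluate_model(p, s.age - h)) / (2 * h)
        assert deriv == pytest.approx(s.max_daily_gain / 1000.0, rel=1e-6)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "von_bertalanffy"])
    def test_gain_is_global_maximum_of_derivative(self, table1_params, model):
        p = table1_params[model]
        s = inflection_summary(p)
        t = np.linspace(1, 600, 500)
        deriv = (evaluate_model(p, t + 0.5) - evaluate_model(p, t - 0.5))
        assert deriv.max() <= s.max_daily_gain / 1000.0 + 1e-9


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        assert goodness_of_fit([1.0, 5.0, 9.0], [1.0, 5.0, 9.0]) == 1.0

    def test_mean_predictor_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert goodness_of_fit(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # SSE = 1, SST = 2
        assert goodness_of_fit([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observations_error(self):
        with pytest.raises(ValueError, match="sum of squares"):
            goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(shift=st.floats(-1e3, 1e3, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_common_shift(self, shift):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        pred = np.array([1.1, 1.9, 4.2, 7.7])
        base = goodness_of_fit(obs, pred)
        assert goodness_of_fit(obs + shift, pred + shift) == pytest.approx(base)


class TestFitGrowthCurve:
    def test_recovers_noise_free_truth(self):
        truth = GrowthModelParams("logistic", 135.0, 22.0, 0.017)
        records, _ = simulate_growth_cohort(
            truth, n_animals=1, noise_sd=0.0, animal_cv=0.0, seed=0
        )
        fit = fit_growth_curve(records, "logistic")
        assert fit.converged
        assert fit.params.A == pytest.approx(truth.A, rel=1e-4)
        assert fit.params.B == pytest.approx(truth.B, rel=1e-4)
        assert fit.params.k == pytest.approx(truth.k, rel=1e-4)
        assert fit.r_squared >= 1 - 1e-10

    def test_recovers_asymptote_from_noisy_cohort(self):
        truth = GrowthModelParams("logistic", 135.0, 22.0, 0.017)
        records, _ = simulate_growth_cohort(
            truth, n_animals=126, noise_sd=2.0, animal_cv=0.0, seed=7
        )
        fit = fit_growth_curve(records, "logistic")
        assert fit.converged
        assert fit.params.A == pytest.approx(truth.A, rel=0.05)

    def test_constant_weights_flagged_not_crashed(self):
        records = pd.DataFrame(
            {
                "animal_id": ["a"] * 5,
                "age_days": [0.0, 100.0, 200.0, 300.0, 400.0],
                "weight_kg": [50.0] * 5,
            }
        )
        fit = fit_growth_curve(records, "logistic")
        assert not fit.converged

    def test_too_few_ages_rejected(self):
        records = pd.DataFrame(
            {"animal_id": ["a"] * 3, "age_days": [0, 100, 200],
             "weight_kg": [5.0, 50.0, 100.0]}
        )
        with pytest.raises(ValueError, match="distinct ages"):
            fit_growth_curve(records, "logistic")

    def test_residuals_match_observation_count(self):
        truth = GrowthModelParams("gompertz", 160.0, 4.0, 0.008)
        records, _ = simulate_growth_cohort(
            truth, n_animals=3, noise_sd=1.0, animal_cv=0.0, seed=2
        )
        fit = fit_growth_curve(records, "gompertz")
        assert len(fit.residuals) == len(records)


class TestRankModels:
    def _fit(self, model, r2):
        p = GrowthModelParams(model, 100.0, 2.0, 0.01)
        return GrowthCurveFit(p, r2, np.zeros(1), True)

    def test_descending_r_squared(self):
        fits = [
            self._fit("gompertz", 0.996),
            self._fit("logistic", 0.999),
            self._fit("von_bertalanffy", 0.998),
        ]
        ranked = rank_models(fits)
        assert [f.params.model for f in ranked] == [
            "logistic", "von_bertalanffy", "gompertz",
        ]

    def test_single_fit(self):
        fits = [self._fit("logistic", 0.9)]
        assert rank_models(fits) == fits

    def test_tie_broken_lexicographically(self):
        fits = [self._fit("von_bertalanffy", 0.99), self._fit("gompertz", 0.99)]
        ranked = rank_models(fits)
        assert [f.params.model for f in ranked] == ["gompertz", "von_bertalanffy"]
        assert rank_models(list(reversed(fits)))[0].params.model == "gompertz"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestIO:
    def test_weight_records_roundtrip_and_report(self, tmp_path):
        truth = TABLE1_PARAMS["logistic"]
        records, _ = simulate_growth_cohort(
            truth, n_animals=5, noise_sd=1.0, seed=3
        )
        path = tmp_path / "weights.csv"
        records.to_csv(path, index=False)
        back = read_weight_records(path)
        pd.testing.assert_frame_equal(back, records)
        fits = [fit_growth_curve(back, m) for m in
                ("logistic", "gompertz", "von_bertalanffy")]
        report = fit_report(fits)
        assert list(report.columns) == [
            "model", "A", "B", "k", "R2", "inflection_day",
            "inflection_weight_kg", "max_daily_gain_g", "converged",
        ]
        assert len(report) == 3

    def test_invalid_weight_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"animal_id": ["a"], "age_days": [-1], "weight_kg": [2.0]}
                     ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-negative"):
            read_weight_records(path)
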