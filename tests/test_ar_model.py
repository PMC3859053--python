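import math

import numpy as np
import pytest
from statsmodels.regression.linear_model import burg as sm_burg

from arhar.ar_model import (
    ARModel,
    aic_score,
    extract_features,
    fit_ar_burg,
    plateau_select,
    predict_one_step,
    select_order,
    select_window_length,
    simulate_ar,
    snr,
    validate_model,
)
from arhar.exceptions import DegenerateSignalError, ParameterError, StabilityError
from arhar.signal_io import SignalWindow
from tests.conftest import ar_series


class TestBurg:
    def test_white_noise_has_near_zero_coefficient(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        model = fit_ar_burg(x, 1)
        assert abs(model.coefficients[0]) < 0.05

    def test_recovers_ar1_and_matches_yule_walker(self):
        x = ar_series([0.8], 10_000, seed=1)
        model = fit_ar_burg(x, 1)
        assert 0.77 <= model.coefficients[0] <= 0.83
        xc = x - x.mean()
        r0 = np.dot(xc, xc) / xc.size
        r1 = np.dot(xc[:-1], xc[1:]) / xc.size
        assert model.coefficients[0] == pytest.approx(r1 / r0, abs=1e-3)

    @pytest.mark.parametrize("coeffs", [[0.8], [1.2, -0.5]])
    def test_matches_statsmodels_oracle(self, coeffs):
        x = ar_series(coeffs, 10_000, seed=3)
        model = fit_ar_burg(x, len(coeffs))
        oracle, oracle_sigma2 = sm_burg(x, len(coeffs))
        np.testing.assert_allclose(
            model.coefficients, np.atleast_1d(oracle), atol=1e-10
        )
        assert model.innovation_variance == pytest.approx(oracle_sigma2, rel=1e-3)
        np.testing.assert_allclose(model.coefficients, coeffs, atol=0.05)

    def test_fitted_model_is_stable_on_rough_data(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.standard_normal(500))  # near-unit-root input
        model = fit_ar_burg(x, 10)
        assert model.is_stable()

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            fit_ar_burg(np.full(100, 2.0), 2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            fit_ar_burg(np.arange(10.0), 5)


class TestPredictSimulate:
    def test_unit_persistence_on_constant(self):
        model = ARModel(order=1, coefficients=[1.0], innovation_variance=0.0)
        preds, resid = predict_one_step(model, [2.0, 2.0, 2.0])
        np.testing.assert_array_equal(preds, [2.0, 2.0])
        np.testing.assert_array_equal(resid, [0.0, 0.0])

    def test_zero_coefficients_predict_zero(self):
        model = ARModel(order=2, coefficients=[0.0, 0.0], innovation_variance=1.0)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        preds, resid = predict_one_step(model, x)
        np.testing.assert_array_equal(preds, 0.0)
        np.testing.assert_array_equal(resid, x[2:])

    def test_hand_arithmetic(self):
        model = ARModel(order=2, coefficients=[0.5, 0.25], innovation_variance=1.0)
        preds, resid = predict_one_step(model, [4.0, 2.0, 1.0])
        assert preds[0] == pytest.approx(2.0)
        assert resid[0] == pytest.approx(-1.0)

    def test_simulate_deterministic_and_zero_noise(self):
        model = ARModel(order=1, coefficients=[0.5], innovation_variance=0.0)
        np.testing.assert_array_equal(simulate_ar(model, 50, seed=4), 0.0)
        model2 = ARModel(order=2, coefficients=[1.2, -0.5], innovation_variance=1.0)
        np.testing.assert_array_equal(
            simulate_ar(model2, 100, seed=8), simulate_ar(model2, 100, seed=8)
        )

    def test_simulate_matches_stationary_variance(self):
        model = ARModel(order=1, coefficients=[0.8], innovation_variance=1.0)
        x = simulate_ar(model, 100_000, seed=3)
        assert x.var() == pytest.approx(1.0 / (1.0 - 0.64), rel=0.05)

    def test_unstable_model_rejected(self):
        model = ARModel(order=1, coefficients=[1.05], innovation_variance=1.0)
        with pytest.raises(StabilityError):
            simulate_ar(model, 10, seed=0)


class TestAIC:
    def test_parameter_penalty_is_two_per_parameter(self):
        assert aic_score(1.0, 100, 3) - aic_score(1.0, 100, 2) == pytest.approx(2.0)

    def test_closed_form(self):
        assert aic_score(1.0, 100, 2) == pytest.approx(100 * (math.log(2 * math.pi) + 1) + 4)

    def test_halving_variance_drops_aic_by_n_log_two(self):
        drop = aic_score(1.0, 200, 2) - aic_score(0.5, 200, 2)
        assert drop == pytest.approx(200 * math.log(2.0))

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            aic_score(0.0, 100, 2)
        with pytest.raises(ParameterError):
            aic_score(1.0, 0, 2)


def _window_from_series(series3, fs=20.0):
    samples = np.column_stack(series3)
    return SignalWindow(
        samples=samples, sampling_rate=fs, window_seconds=samples.shape[0] / fs
    )


class TestSelectOrder:
    def test_single_candidate_selected(self):
        w = _window_from_series([ar_series([0.5], 200, seed=s) for s in range(3)])
        assert select_order([w], [5]).selected_order == 5

    def test_recovers_ar2_order_across_seeds(self):
        hits = 0
        for s in range(20):
            series = [
                ar_series([1.2, -0.5], 2000, seed=100 * s + j, sigma2=1.0)
                for j in range(3)
            ]
            curve = select_order([_window_from_series(series)], range(1, 9))
            hits += curve.selected_order == 2
        assert hits >= 16  # >= 80% of seeds

    def test_empty_windows_rejected(self):
        with pytest.raises(ParameterError):
            select_order([], [1, 2])

    def test_elbow_rule_picks_plateau_start(self):
        # drop of 30% then 0.1%: plateau starts at the second order
        w = _window_from_series([ar_series([0.7], 400, seed=s) for s in range(3)])
        curve = select_order([w], [1, 2, 3], rule="min")
        assert curve.scores.shape == (3,)


class TestPlateauRule:
    def test_snr_hand_curve_selects_previous_candidate(self):
        # gains: +60%, +0.6%, +0.1% -> plateau starts at candidate 2
        idx = plateau_select([5.0, 8.0, 8.05, 8.06], [1, 2, 3, 4], 0.01, maximize=True)
        assert idx == 1

    def test_strictly_improving_curve_selects_last(self):
        idx = plateau_select([1.0, 2.0, 4.0, 8.0], [1, 2, 3, 4], 0.01, maximize=True)
        assert idx == 3

    def test_aic_direction(self):
        idx = plateau_select([100.0, 60.0, 59.9, 59.8], [1, 2, 3, 4], 0.01, maximize=False)
        assert idx == 1


class TestSNR:
    def test_exact_fit_is_infinite(self):
        assert snr([1.0, 2.0], [1.0, 2.0]) == math.inf

    def test_zero_db_when_error_equals_signal(self):
        assert snr([1.0, 1.0], [0.0, 0.0]) == pytest.approx(0.0)

    def test_six_db_for_half_amplitude_error(self):
        assert snr([2.0], [1.0]) == pytest.approx(10 * math.log10(4), abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            snr([1.0, 2.0], [1.0])


class TestSelectWindowLength:
    def test_runs_on_synthetic_recording_and_curve_is_finite(self, walking_profile):
        from arhar.synthetic_data import default_position_transforms, generate_recording

        rec = generate_recording(
            walking_profile,
            default_position_transforms()[0],
            subject_seed=3,
            duration=40.0,
        )
        curve = select_window_length(rec, candidates=[1, 2, 3, 4], order=5)
        assert np.all(np.isfinite(curve.snr_values))
        assert curve.selected_window in [1, 2, 3, 4]

    def test_too_short_recording_rejected(self, simple_recording):
        with pytest.raises(ParameterError):
            select_window_length(simple_recording, candidates=[60.0], order=5)


class TestValidateModel:
    def test_matched_process_residuals_are_white(self, walking_profile):
        model0 = walking_profile.axis_model(0)
        whites = 0
        for i in range(10):
            fit_sample = simulate_ar(model0, 8000, seed=500 + 2 * i)
            heldout = simulate_ar(model0, 800, seed=501 + 2 * i)
            fitted = fit_ar_burg(fit_sample, 10)
            whites += validate_model(fitted, heldout, lags_tested=30).is_white
        assert whites >= 8

    def test_underspecified_model_fails_validation(self, walking_profile):
        model0 = walking_profile.axis_model(0)
        fails = 0
        for i in range(10):
            fit_sample = simulate_ar(model0, 8000, seed=700 + 2 * i)
            heldout = simulate_ar(model0, 800, seed=701 + 2 * i)
            fitted = fit_ar_burg(fit_sample, 1)
            fails += not validate_model(fitted, heldout, lags_tested=30).is_white
        assert fails >= 9

    def test_constant_residuals_not_white(self):
        model = ARModel(order=1, coefficients=[1.0], innovation_variance=0.0)
        report = validate_model(model, np.full(200, 5.0))
        assert not report.is_white


class TestExtractFeatures:
    def test_vector_length_is_three_p(self):
        series = [ar_series([0.6], 60, seed=s) for s in range(3)]
        w = _window_from_series(series)
        assert extract_features(w, order=10).values.shape == (30,)
        assert extract_features(w, order=1).values.shape == (3,)

    def test_recovers_generating_coefficients(self):
        true = [1.2, -0.5]
        series = [ar_series(true, 2000, seed=40 + j) for j in range(3)]
        fv = extract_features(_window_from_series(series), order=2)
        for axis in range(3):
            np.testing.assert_allclose(fv.values[2 * axis : 2 * axis + 2], true, atol=0.05)

    def test_deterministic(self):
        series = [ar_series([0.6], 80, seed=s) for s in range(3)]
        w = _window_from_series(series)
        np.testing.assert_array_equal(
            extract_features(w, order=4).values, extract_features(w, order=4).values
        )

    def test_metadata_copied(self):
        samples = np.column_stack([ar_series([0.5], 60, seed=s) for s in range(3)])
        w = SignalWindow(
            samples=samples, sampling_rate=20.0, window_seconds=3.0,
            activity_label="running", position_label="p", subject_id="s1",
        )
        fv = extract_features(w, order=10)
        assert (fv.activity_label, fv.position_label, fv.subject_id) == ("running", "p", "s1")


class TestInSampleMonotonicity:
    def test_prediction_snr_non_decreasing_in_order(self):
        x = ar_series([1.2, -0.5], 1500, seed=77)
        xc = x - x.mean()
        values = []
        for order in (1, 2, 4, 8):
            model = fit_ar_burg(x, order)
            preds, _ = predict_one_step(model, xc)
            values.append(snr(xc[order:], preds))
        assert all(b >= a - 0.2 for a, b in zip(values, values[1:]))
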