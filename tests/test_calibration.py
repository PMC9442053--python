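"""Objective, fitting, Fisher information, AICc and model comparison."""

import numpy as np
import pandas as pd
import pytest

from drumalg import MacroKineticModel
from drumalg.calibration import (
    MeasurementSet,
    aicc,
    fisher_information,
    fit_parameters,
    infer_sample_size,
    output_uncertainty,
    parameter_std,
    percent_improvement,
    weighted_sse,
)
from drumalg.synthetic import SyntheticProtocolSpec, generate_calibration_dataset


class TestAicc:
    def test_small_sample_formula(self):
        # n ln(SSE/n) + 2(p+1) + 2(p+1)(p+2)/(n-p-2)
        assert aicc(58.5, 289, 10) == pytest.approx(-438.7, abs=0.05)
        assert aicc(33.4, 289, 11) == pytest.approx(-598.5, abs=0.05)

    def test_halving_sse_shifts_by_n_ln2(self):
        n, p = 200, 5
        assert aicc(10.0, n, p) - aicc(5.0, n, p) == pytest.approx(n * np.log(2))

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(1.0, 12, 10)

    def test_sample_size_inference(self):
        n_true = 289
        rows = [(58.5, 10, round(aicc(58.5, n_true, 10))),
                (46.0, 10, round(aicc(46.0, n_true, 10)))]
        assert infer_sample_size(rows) == [n_true]

    def test_inconsistent_rows_give_empty(self):
        assert infer_sample_size([(10.0, 3, -50), (10.0, 3, 50)]) == []


class TestPercentImprovement:
    @pytest.mark.parametrize("ref,sse,expected", [
        (46.0, 33.4, 27.4),
        (46.0, 46.0, 0.0),
        (46.0, 58.5, -27.2),
    ])
    def test_values(self, ref, sse, expected):
        assert percent_improvement(ref, sse) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_improvement(0.0, 1.0)


class TestMeasurementSet:
    def test_schema_validation(self, day_night_protocol, initial_state):
        bad = pd.DataFrame({"time_h": [1.0], "value": [0.1]})
        with pytest.raises(ValueError, match="missing columns"):
            MeasurementSet(bad, day_night_protocol, initial_state)
        unknown = pd.DataFrame({"time_h": [1.0], "observable": ["pH"], "value": [0.1]})
        with pytest.raises(ValueError, match="unknown observables"):
            MeasurementSet(unknown, day_night_protocol, initial_state)
        bad_sd = pd.DataFrame({"time_h": [1.0], "observable": ["XC"],
                               "value": [0.1], "sd": [0.0]})
        with pytest.raises(ValueError, match="standard deviations"):
            MeasurementSet(bad_sd, day_night_protocol, initial_state)

    def test_window_restriction(self, tiny_dataset):
        _, data = tiny_dataset
        first_day = data.restricted_to(24.0)
        assert first_day.n_obs < data.n_obs
        assert first_day.data["time_h"].max() <= 24.0

    def test_scales_prefer_sd_and_fall_back_to_mean(self, day_night_protocol, initial_state):
        df = pd.DataFrame({
            "time_h": [1.0, 2.0, 1.0],
            "observable": ["XC", "XC", "nitrate"],
            "value": [0.2, 0.4, 1e-4],
            "sd": [0.05, np.nan, np.nan],
        })
        ms = MeasurementSet(df, day_night_protocol, initial_state)
        np.testing.assert_allclose(ms.scales(), [0.05, 0.3, 1e-4])


class TestObjective:
    def test_sse_vanishes_at_generating_parameters(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        assert weighted_sse(excarb, excarb_params, data) < 1e-8

    def test_sse_increases_under_perturbation(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        base = weighted_sse(excarb, excarb_params, data)
        for name, factor in [("k_MR1", 1.3), ("k_EX", 2.0), ("k_MR5p", 0.5)]:
            bumped = excarb_params.updated(**{name: excarb_params[name] * factor})
            assert weighted_sse(excarb, bumped, data) > base + 1e-4

    def test_noisy_sse_near_observation_count(self, excarb, excarb_params):
        """With sd-scaled residuals, SSE at the truth is a chi-square with
        one degree of freedom per observation."""
        spec = SyntheticProtocolSpec(experiment="day_night_starvation",
                                     variant="ExCARB", noise_cv=0.05, seed=11)
        data = generate_calibration_dataset(spec)
        sse = weighted_sse(excarb, excarb_params, data)
        n = data.n_obs
        assert n - 5 * np.sqrt(2 * n) < sse < n + 5 * np.sqrt(2 * n)


class TestFit:
    def test_single_parameter_recovery(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        skewed = excarb_params.updated(k_EX=0.5)
        fit = fit_parameters(excarb, data, base_params=skewed, fit_names=["k_EX"],
                             n_starts=2, seed=5, compute_uncertainty=False)
        assert fit.params.k_EX == pytest.approx(excarb_params.k_EX, rel=1e-2)
        assert fit.sse <= weighted_sse(excarb, excarb_params, data) + 1e-6

    def test_refit_from_optimum_is_fixed_point(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        fit = fit_parameters(excarb, data, base_params=excarb_params,
                             fit_names=["k_EX"], n_starts=1, seed=1,
                             start=excarb_params, compute_uncertainty=False)
        refit = fit_parameters(excarb, data, base_params=fit.params,
                               fit_names=["k_EX"], n_starts=1, seed=2,
                               start=fit.params, compute_uncertainty=False)
        assert refit.sse <= fit.sse + 1e-6 * max(fit.sse, 1e-12)

    def test_multistart_record_is_reproducible(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        kw = dict(base_params=excarb_params, fit_names=["k_EX"], n_starts=2,
                  seed=42, compute_uncertainty=False, maxfev=30)
        a = fit_parameters(excarb, data, **kw)
        b = fit_parameters(excarb, data, **kw)
        assert a.sse == b.sse
        assert [r["objective"] for r in a.multistart_record] == \
               [r["objective"] for r in b.multistart_record]

    def test_quantum_limit_respected(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        fit = fit_parameters(excarb, data, base_params=excarb_params,
                             fit_names=["k_MR1"], n_starts=2, seed=3,
                             compute_uncertainty=False)
        assert fit.params.k_MR1 <= 4.5e-3 + 1e-12

    def test_summary_and_results_object(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        model = MacroKineticModel("ExCARB")
        fit = model.fit(data, base_params=excarb_params, fit_names=["k_EX"],
                        n_starts=1, seed=0, start=excarb_params)
        text = fit.summary()
        assert "k_EX" in text and "SSE" in text
        ci = fit.conf_int()
        assert (ci["lower"] <= ci["estimate"]).all()
        assert fit.aicc is not None


class TestUncertainty:
    def test_parameter_std_closed_forms(self):
        np.testing.assert_allclose(parameter_std(np.eye(3)), np.ones(3))
        np.testing.assert_allclose(parameter_std(np.diag([4.0, 4.0])), [0.5, 0.5])
        # linear toy model y = theta t at t in {1, 2}: FIM = 1 + 4 = 5
        assert parameter_std(np.array([[5.0]]))[0] == pytest.approx(1 / np.sqrt(5))

    def test_singular_fim_uses_pseudo_inverse(self):
        fim = np.array([[1.0, 1.0], [1.0, 1.0]])
        sigma, pinv_used = parameter_std(fim, return_flag=True)
        assert pinv_used
        assert np.all(np.isfinite(sigma) | np.isnan(sigma))

    def test_duplicating_observations_doubles_fim(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        doubled = MeasurementSet(
            pd.concat([data.data, data.data], ignore_index=True),
            data.protocol, data.initial, data.warmup_h)
        f1 = fisher_information(excarb, excarb_params, data, ["k_EX", "k_MR1"])
        f2 = fisher_information(excarb, excarb_params, doubled, ["k_EX", "k_MR1"])
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-6)

    def test_output_bands_scale_with_parameter_sd(self, tiny_dataset, excarb, excarb_params):
        _, data = tiny_dataset
        zero = output_uncertainty(excarb, excarb_params, np.zeros(1), data, ["k_EX"])
        assert np.all(zero["sd"] == 0)
        np.testing.assert_allclose(zero["lower"], zero["prediction"])
        one = output_uncertainty(excarb, excarb_params, np.array([0.01]), data, ["k_EX"])
        two = output_uncertainty(excarb, excarb_params, np.array([0.02]), data, ["k_EX"])
        np.testing.assert_allclose(two["sd"], 2 * one["sd"], rtol=1e-9)
        np.testing.assert_allclose(one["upper"] - one["lower"], 2 * 1.96 * one["sd"])
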