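"""Calibration, IS correction, drift correction and the full round trip."""

import numpy as np
import pandas as pd
import pytest

import ionkernel as ik
from ionkernel.processing import ProcessingError


class TestCalibration:
    def test_two_point_exact_line(self):
        std = pd.DataFrame({"element": "Fe", "nominal_ppb": [0.0, 10.0],
                            "signal": [0.0, 100.0]})
        cal = ik.calibrate_from_standards(std)
        assert cal.slope["Fe"] == pytest.approx(10.0)
        assert cal.intercept["Fe"] == pytest.approx(0.0, abs=1e-12)
        assert cal.to_ppb("Fe", np.array([50.0]))[0] == pytest.approx(5.0)

    def test_six_collinear_standards_exact_recovery(self):
        x = np.linspace(0, 100, 6)
        std = pd.DataFrame({"element": "Zn", "nominal_ppb": x,
                            "signal": 3.5 * x + 5.0})
        cal = ik.calibrate_from_standards(std)
        assert cal.slope["Zn"] == pytest.approx(3.5, rel=1e-12)
        assert cal.intercept["Zn"] == pytest.approx(5.0, rel=1e-10)
        assert cal.r2["Zn"] == pytest.approx(1.0)

    def test_noisy_slope_within_analytic_ols_se(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 100, 6)
        sigma = 2.0
        y = 4.0 * x + 1.0 + rng.normal(0, sigma, 6)
        cal = ik.calibrate_from_standards(pd.DataFrame(
            {"element": "Cu", "nominal_ppb": x, "signal": y}))
        se_slope = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(cal.slope["Cu"] - 4.0) < 4 * se_slope

    def test_single_level_rejected(self):
        std = pd.DataFrame({"element": "Fe", "nominal_ppb": [10.0, 10.0],
                            "signal": [99.0, 101.0]})
        with pytest.raises(ProcessingError, match="distinct nominal"):
            ik.calibrate_from_standards(std)

    def test_negative_slope_flagged(self):
        std = pd.DataFrame({"element": "Se", "nominal_ppb": [0.0, 10.0],
                            "signal": [100.0, 0.0]})
        with pytest.warns(UserWarning, match="slope"):
            cal = ik.calibrate_from_standards(std)
        assert "nonpositive_slope:Se" in cal.flags

    def test_negative_backcalculation_floored(self):
        std = pd.DataFrame({"element": "Fe", "nominal_ppb": [0.0, 10.0],
                            "signal": [10.0, 110.0]})
        cal = ik.calibrate_from_standards(std)
        assert cal.to_ppb("Fe", np.array([5.0]))[0] == 0.0
        assert any(f.startswith("floored_negative") for f in cal.flags)


class TestInternalStandard:
    def test_identity_when_observed_equals_nominal(self):
        corr, f = ik.apply_internal_standard_correction(
            np.array([[100.0]]), np.array([20.0]), 20.0)
        assert corr[0, 0] == 100.0 and f[0] == 1.0

    def test_half_recovery_doubles(self):
        corr, _ = ik.apply_internal_standard_correction(
            np.array([[100.0]]), np.array([10.0]), 20.0)
        assert corr[0, 0] == pytest.approx(200.0)

    def test_hand_arithmetic(self):
        # 150 x 20/25 = 120
        corr, _ = ik.apply_internal_standard_correction(
            np.array([[150.0]]), np.array([25.0]), 20.0)
        assert corr[0, 0] == pytest.approx(120.0)

    def test_dead_is_gives_nan_factor(self):
        corr, f = ik.apply_internal_standard_correction(
            np.array([[150.0], [150.0]]), np.array([0.0, 25.0]), 20.0)
        assert np.isnan(f[0]) and np.isnan(corr[0, 0])
        assert corr[1, 0] == pytest.approx(120.0)


class TestWithinRunDrift:
    def test_no_drift_identity(self):
        f = ik.interpolate_drift_factors(np.arange(11), np.array([0, 10]),
                                         np.array([100.0, 100.0]))
        assert np.allclose(f, 1.0)

    def test_hand_oracle_midpoint(self):
        # c0=100, c1=120, slot 5 of 10: 110 / 1.10 = 100
        f = ik.interpolate_drift_factors(np.array([5]), np.array([0, 10]),
                                         np.array([100.0, 120.0]))
        assert 110.0 / f[0] == pytest.approx(100.0)

    def test_first_sample_gets_tenth_of_drift(self):
        # c0=100, c1=110: first post-control sample corrected by 1/10
        f = ik.interpolate_drift_factors(np.array([1]), np.array([0, 10]),
                                         np.array([100.0, 110.0]))
        assert f[0] == pytest.approx(1.01)
        assert 101.0 / f[0] == pytest.approx(100.0)

    def test_chaining_restores_first_control_level(self):
        positions = np.arange(21)
        ctrl = np.zeros(21, dtype=bool)
        ctrl[[0, 10, 20]] = True
        # drifting control: 100 -> 120 -> 90; samples sit at twice the
        # control's concentration and experience the same drift
        traj = np.interp(positions, [0, 10, 20], [100.0, 120.0, 90.0])
        vals = np.where(ctrl, traj, traj * 2.0)
        corrected, model = ik.correct_within_run_drift(
            "r", positions, ctrl, pd.DataFrame({"Ca": vals}))
        assert np.allclose(corrected["Ca"][~ctrl], 200.0, rtol=1e-12)
        assert np.allclose(corrected["Ca"][ctrl], 100.0, rtol=1e-12)
        assert model.run_level["Ca"] == pytest.approx(100.0)

    def test_outside_bracket_rejected_unless_extrapolating(self):
        f = ik.interpolate_drift_factors(np.array([0, 5]), np.array([1, 4]),
                                         np.array([100.0, 130.0]))
        assert np.isnan(f[0]) and np.isnan(f[1])
        f2 = ik.interpolate_drift_factors(np.array([0, 5]), np.array([1, 4]),
                                          np.array([100.0, 130.0]),
                                          allow_extrapolation=True)
        assert f2[0] == pytest.approx(0.9)   # nearest segment extended
        assert f2[1] == pytest.approx(1.4)

    def test_too_few_controls_raises(self):
        with pytest.raises(ProcessingError, match=">= 2 controls"):
            ik.interpolate_drift_factors(np.array([1]), np.array([0]),
                                         np.array([100.0]))

    def test_nonpositive_control_raises(self):
        with pytest.raises(ProcessingError, match="positive"):
            ik.interpolate_drift_factors(np.array([1]), np.array([0, 2]),
                                         np.array([0.0, 100.0]))


class TestBetweenRunDrift:
    def _model(self, run_id, level):
        return ik.DriftCorrectionModel(
            run_id=run_id, control_positions={}, control_values={},
            drift_factors={}, run_level={"Ca": level})

    def test_single_run_identity(self):
        m = self._model("a", 100.0)
        factors = ik.correct_between_run_drift([m])
        assert factors["a"]["Ca"] == pytest.approx(1.0)

    def test_proportionality(self):
        # run control 80, reference 100: value 40 -> 50
        m = self._model("a", 80.0)
        factors = ik.correct_between_run_drift([m], {"Ca": 100.0})
        assert 40.0 * factors["a"]["Ca"] == pytest.approx(50.0)

    def test_no_runs_raises(self):
        with pytest.raises(ProcessingError):
            ik.correct_between_run_drift([])


class TestNormalization:
    def test_dimensional_analysis_oracle(self):
        # 1 ppb, 10 mL digest, 5.0/0.9 secondary dilution, 0.25 g seed
        # -> (1 ug/L x 5.556 x 0.010 L) / 0.00025 kg = 222.2 ug/kg = 0.2222 ppm
        cfg = ik.NormalizationConfig()
        assert ik.normalize_to_seed(1.0, cfg, 0.25) == pytest.approx(
            0.22222, rel=1e-4)

    def test_weight_inverse_proportionality(self):
        cfg = ik.NormalizationConfig()
        assert ik.normalize_to_seed(1.0, cfg, 0.5) == pytest.approx(
            ik.normalize_to_seed(1.0, cfg, 0.25) / 2)

    def test_zero_weight_is_error_not_infinity(self):
        with pytest.raises(ProcessingError, match="weight"):
            ik.normalize_to_seed(1.0, ik.NormalizationConfig(), 0.0)


class TestProcessRuns:
    def _render(self, effects3, small_design, drift, seed=20, **kw):
        samples, _ = ik.generate_field_experiment(small_design, effects3,
                                                  seed=seed)
        rendered = ik.render_instrument_runs(samples, drift, seed=seed + 1,
                                             **kw)
        weights = samples.set_index("sample_id")["weight_g"]
        return samples, rendered, weights

    def test_round_trip_exact_with_drift(self, effects3, small_design,
                                         linear_drift):
        _, rendered, weights = self._render(effects3, small_design,
                                            linear_drift, run_size=100)
        assert len(rendered.runs) >= 2
        res = ik.process_runs(rendered.runs, weights)
        merged = res.table.merge(rendered.expected_ppm,
                                 on=["sample_id", "element"],
                                 suffixes=("", "_true"))
        assert len(merged) == len(rendered.expected_ppm)
        rel = np.abs(merged["ppm"] / merged["ppm_true"] - 1)
        assert rel.max() <= 1e-9

    def test_scale_invariance_at_each_position(self, effects3, small_design,
                                               linear_drift):
        _, rendered, weights = self._render(effects3, small_design,
                                            linear_drift, run_size=200)
        base = ik.process_runs(rendered.runs, weights)
        rng = np.random.default_rng(0)
        for run in rendered.runs:
            f = rng.uniform(0.5, 2.0, size=len(run.table))
            cols = list(run.elements) + ["is_signal"]
            run.table[cols] = run.table[cols].mul(f, axis=0)
        scaled = ik.process_runs(rendered.runs, weights)
        a = base.table.set_index(["sample_id", "element"])["ppm"]
        b = scaled.table.set_index(["sample_id", "element"])["ppm"]
        assert np.abs(b / a - 1).max() <= 1e-12

    def test_audit_factor_product_reproduces_output(self, effects3,
                                                    small_design,
                                                    linear_drift):
        _, rendered, weights = self._render(effects3, small_design,
                                            linear_drift)
        res = ik.process_runs(rendered.runs, weights)
        a = res.audit
        recomputed = (a["raw_signal"].to_numpy() * a["is_factor"].to_numpy()
                      / a["drift_factor"].to_numpy()
                      * a["run_factor"].to_numpy()
                      * a["norm_factor"].to_numpy())
        ok = np.isfinite(recomputed)
        assert np.array_equal(recomputed[ok], a["ppm"].to_numpy()[ok])

    def test_controls_fixed_point_across_runs(self, effects3, small_design,
                                              linear_drift):
        _, rendered, weights = self._render(effects3, small_design,
                                            linear_drift, run_size=60)
        res = ik.process_runs(rendered.runs, weights)
        ref = res.models[0].run_level
        for m in res.models:
            for el, lev in m.run_level.items():
                assert lev * m.run_factor[el] == pytest.approx(
                    ref[el], rel=1e-9)

    def test_empty_run_list(self):
        res = ik.process_runs([], pd.Series(dtype=float))
        assert res.table.empty and res.audit.empty

    def test_dead_is_excludes_only_that_sample(self, effects3, small_design,
                                               no_drift):
        samples, rendered, weights = self._render(effects3, small_design,
                                                  no_drift, run_size=1000)
        run = rendered.runs[0]
        victim_pos = run.table.index[~run.table["is_control"]][3]
        victim = run.table.loc[victim_pos, "sample_id"]
        run.table.loc[victim_pos, "is_signal"] = 0.0
        res = ik.process_runs(rendered.runs, weights)
        assert victim not in set(res.table["sample_id"])
        assert (res.exclusions["sample_id"] == victim).any()
        expected_rest = rendered.expected_ppm[
            rendered.expected_ppm["sample_id"] != victim]
        merged = res.table.merge(expected_rest, on=["sample_id", "element"],
                                 suffixes=("", "_true"))
        assert len(merged) == len(expected_rest)
        assert np.abs(merged["ppm"] / merged["ppm_true"] - 1).max() <= 1e-9

    def test_missing_weight_excluded_with_reason(self, effects3,
                                                 small_design, no_drift):
        samples, rendered, weights = self._render(effects3, small_design,
                                                  no_drift)
        weights = weights.drop(weights.index[0])
        res = ik.process_runs(rendered.runs, weights)
        missing = samples["sample_id"].iloc[0]
        assert missing not in set(res.table["sample_id"])
        reasons = res.exclusions.set_index("sample_id")["reason"]
        assert "weight" in reasons.loc[missing]

    def test_calibration_integration(self, effects3, small_design, no_drift):
        """Signals through a non-trivial response line are inverted exactly."""
        samples, rendered, weights = self._render(effects3, small_design,
                                                  no_drift, run_size=1000)
        slope, intercept = 2.5, 7.0
        run = rendered.runs[0]
        els = list(run.elements)
        run.table[els] = run.table[els] * slope + intercept
        std = ik.render_calibration_standards(els, slope=slope,
                                              intercept=intercept)
        cal = ik.calibrate_from_standards(std)
        res = ik.process_runs(rendered.runs, weights, calibration=cal)
        merged = res.table.merge(rendered.expected_ppm,
                                 on=["sample_id", "element"],
                                 suffixes=("", "_true"))
        assert np.abs(merged["ppm"] / merged["ppm_true"] - 1).max() <= 1e-9
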