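"""Trigger, calibration, drift, wheel speed, max-concatenation, spline."""

import numpy as np
import pandas as pd
import pytest

from wheelgait.gaits import GRAVITY, canonical_gait
from wheelgait.reconstruct import (
    CalibrationMatrix,
    ForceTrace,
    concatenate_max,
    detect_activity,
    estimate_drift,
    estimate_speed,
    fit_calibration,
    smooth_spline,
)
from wheelgait.simulate import (
    SensorModel,
    VirtualMouse,
    VoltageRecord,
    WheelGeometry,
    generate_calibration_set,
    generate_trial,
)


def _idle_record(sensors, seconds=2.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(seconds * 3000)
    ch = sensors.baseline_voltage + rng.normal(0, sensors.noise_sd, (9, n))
    return VoltageRecord(sample_rate=3000.0, channels=ch)


class TestDetectActivity:
    def test_flat_record_has_no_intervals(self, sensors):
        assert detect_activity(_idle_record(sensors)) == []

    def test_long_run_tiles_into_5s_blocks(self, geometry, sensors):
        mouse = VirtualMouse(gait=canonical_gait("trot", stride_period=0.15))
        record = generate_trial(geometry, sensors, mouse, 2.0, 12.0, seed=1)
        intervals = detect_activity(record)
        assert len(intervals) >= 3
        assert all(t1 - t0 <= 5.0 + 1e-9 for t0, t1 in intervals)
        covered = sum(t1 - t0 for t0, t1 in intervals)
        assert covered > 11.0  # the run is continuously active

    def test_trigger_crossings_match_brute_force(self, sensors):
        rng = np.random.default_rng(2)
        n = 6000
        ch = sensors.baseline_voltage + rng.normal(0, sensors.noise_sd, (9, n))
        ch[4, 3000:3300] += 0.5  # a deliberate excursion on the central sensor
        record = VoltageRecord(sample_rate=3000.0, channels=ch)
        intervals = detect_activity(record)
        assert len(intervals) == 1
        t0, t1 = intervals[0]
        assert t0 == pytest.approx(1.0, abs=0.01)


class TestFitCalibration:
    def test_noiseless_line_exact(self):
        forces = np.array([0.01, 0.1, 0.2, 0.4])
        rows = []
        for k in range(3):
            intercept, slope = 2.4 + 0.05 * k, 1.8 + 0.1 * k
            for f in forces:
                rows.append(
                    {"mass_kg": f / GRAVITY, "sensor": k,
                     "mean_voltage": intercept + slope * f}
                )
        matrix = fit_calibration(pd.DataFrame(rows))
        for k in range(3):
            assert matrix.slope[k] == pytest.approx(1.8 + 0.1 * k, rel=1e-9)
            assert matrix.intercept[k] == pytest.approx(2.4 + 0.05 * k, rel=1e-9)

    def test_simulated_protocol_r2(self, calibration):
        assert np.all(calibration.fit_r2 > 0.9)

    def test_slope_matches_covariance_formula(self, geometry, sensors):
        table = generate_calibration_set(
            geometry, sensors, np.arange(1, 42, 5) / 1000.0, seed=3
        )
        matrix = fit_calibration(table)
        sub = table[table["sensor"] == 0]
        f = sub["mass_kg"].to_numpy() * GRAVITY
        v = sub["mean_voltage"].to_numpy()
        slope = np.cov(f, v, ddof=1)[0, 1] / np.var(f, ddof=1)
        assert matrix.slope[0] == pytest.approx(slope, abs=1e-10)

    def test_too_few_masses_rejected(self):
        df = pd.DataFrame(
            {"mass_kg": [0.01, 0.02], "sensor": [0, 0], "mean_voltage": [2.5, 2.6]}
        )
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration(df)

    def test_round_trip_through_json(self, calibration, tmp_path):
        path = tmp_path / "cal.json"
        calibration.to_json(path)
        loaded = CalibrationMatrix.from_json(path)
        assert np.array_equal(loaded.slope, calibration.slope)
        assert np.array_equal(loaded.intercept, calibration.intercept)


class TestEstimateDrift:
    @staticmethod
    def _low_rate_record(drift_v_per_h, hours, seed=0, noise_sd=0.0133):
        rng = np.random.default_rng(seed)
        n = int(hours * 3600)
        t_h = np.arange(n) / 3600.0
        ch = 2.5 + drift_v_per_h * t_h + rng.normal(0, noise_sd, (9, n))
        return VoltageRecord(sample_rate=1.0, channels=ch)

    def test_zero_drift_slopes_near_zero(self):
        record = self._low_rate_record(0.0, hours=4.0, seed=4)
        slopes, flagged = estimate_drift(record)
        se = 0.0133 / (np.std(np.arange(4 * 3600) / 3600.0) * np.sqrt(4 * 3600))
        assert np.all(np.abs(slopes) < 3 * se)
        assert not flagged.any()

    def test_configured_drift_recovered_within_10pct(self):
        record = self._low_rate_record(0.00063, hours=15.7, seed=5)
        slopes, _ = estimate_drift(record)
        assert np.mean(slopes) == pytest.approx(0.00063, rel=0.10)

    def test_qc_flag_raised_above_bound(self):
        record = self._low_rate_record(0.02, hours=2.0, seed=6)
        _, flagged = estimate_drift(record, qc_bound_v_per_h=0.005)
        assert flagged.all()

    def test_short_record_rejected(self):
        record = self._low_rate_record(0.0, hours=0.5, seed=7)
        with pytest.raises(ValueError, match="1 hour"):
            estimate_drift(record)


class TestEstimateSpeed:
    def test_formula_arithmetic(self, geometry, sensors):
        """Minima 750 samples apart at 3 kHz give 1 rps; 375 give 2 rps."""
        for s, rps_expected in ((750, 1.0), (375, 2.0)):
            n = 6000
            ch = np.full((9, n), sensors.baseline_voltage)
            for i in range(100, n, s):
                ch[geometry.central_sensor, i - 3 : i + 4] -= 0.5
            record = VoltageRecord(sample_rate=3000.0, channels=ch)
            estimates = estimate_speed(record, geometry)
            assert estimates
            assert all(e.samples_between_minima == s for e in estimates)
            assert all(e.rps == pytest.approx(rps_expected) for e in estimates)
            assert all(
                e.linear_speed == pytest.approx(rps_expected * 0.25)
                for e in estimates
            )

    def test_simulated_constant_speed_within_2pct(self, geometry, sensors):
        mouse = VirtualMouse(gait=canonical_gait("trot", stride_period=0.14))
        record = generate_trial(geometry, sensors, mouse, 1.99, 2.0, seed=8)
        estimates = estimate_speed(record, geometry)
        mean_speed = np.mean([e.linear_speed for e in estimates])
        assert mean_speed == pytest.approx(0.4975, rel=0.02)

    def test_no_systematic_bias_over_seeded_trials(self, geometry, sensors):
        errs = []
        for seed in range(50):
            mouse = VirtualMouse(
                gait=canonical_gait("trot", stride_period=0.155)
            )
            record = generate_trial(geometry, sensors, mouse, 2.0, 1.5, seed=seed)
            estimates = estimate_speed(record, geometry)
            errs.append(np.mean([e.linear_speed for e in estimates]) - 0.5)
        errs = np.asarray(errs)
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) <= max(2 * se, 1e-4)

    def test_idle_record_yields_no_estimate(self, geometry, sensors):
        assert estimate_speed(_idle_record(sensors), geometry) == []


class TestConcatenateMax:
    def test_single_active_sensor_identity(self, calibration):
        rng = np.random.default_rng(9)
        n = 3000
        ch = np.tile(calibration.intercept[:, None], (1, n))
        force = 0.3 * np.abs(np.sin(np.linspace(0, 6 * np.pi, n)))
        ch[4] += calibration.slope[4] * force
        record = VoltageRecord(sample_rate=3000.0, channels=ch)
        trace = concatenate_max(record, calibration)
        assert np.allclose(trace.force, force, atol=1e-9)

    def test_equals_elementwise_max_oracle(
        self, geometry, sensors, calibration, trot_record
    ):
        trace = concatenate_max(trot_record, calibration)
        forces = (
            trot_record.channels - calibration.intercept[:, None]
        ) / calibration.slope[:, None]
        oracle = np.max(np.clip(forces, 0, None), axis=0)
        assert np.allclose(trace.force, oracle)

    def test_two_limbs_on_different_pads_take_max_not_sum(
        self, geometry, sensors, calibration
    ):
        """During trot double-support the trace tracks the larger limb."""
        T = 0.16
        mouse = VirtualMouse(
            lateral_bias=0.5,
            gait=canonical_gait("trot", stride_period=T, duty_factor=0.45,
                                fore_hind_duty_split=1.0),
        )
        record = generate_trial(geometry, sensors, mouse, 2.0, 8 * T, seed=10)
        trace = concatenate_max(record, calibration)
        truth = record.ground_truth["limb_forces"]
        larger = np.max(np.stack(list(truth.values())), axis=0)
        total = record.ground_truth["total_force"]
        # compare at mid-stance instants where two limbs are loaded
        both = (larger > 0.1) & (total > 1.5 * larger)
        assert both.any()
        assert np.all(trace.force[both] < 1.3 * larger[both])

    def test_missing_sensor_rejected(self, calibration):
        record = VoltageRecord(sample_rate=3000.0, channels=np.zeros((5, 100)))
        with pytest.raises(ValueError, match="channels"):
            concatenate_max(record, calibration)


class TestSmoothSpline:
    def test_constant_trace_unchanged(self):
        trace = ForceTrace(
            time=np.arange(100) / 3000.0,
            force=np.full(100, 0.2),
            stage="raw_max",
            sample_rate=3000.0,
            meta={"argmax_sensor": np.zeros(100, int)},
        )
        out = smooth_spline(trace)
        assert np.allclose(out.force, 0.2)
        assert out.stage == "splined"

    def test_spline_matches_knot_values(self, calibration, trot_record):
        from wheelgait.reconstruct import _handoff_knots

        raw = concatenate_max(trot_record, calibration)
        out = smooth_spline(raw)
        knots, values = _handoff_knots(raw)
        assert np.allclose(out.force[knots], np.clip(values, 0, None), atol=1e-9)

    def test_bounded_fidelity_and_ripple_reduction(
        self, geometry, sensors, calibration
    ):
        """The spline stays close to the true force and strips the
        sensor-handoff ripple band."""
        T = 0.14
        mouse = VirtualMouse(
            gait=canonical_gait("gallop", stride_period=T, duty_factor=0.3)
        )
        record = generate_trial(geometry, sensors, mouse, 3.0, 10 * T, seed=11)
        raw = concatenate_max(record, calibration)
        spl = smooth_spline(raw)
        truth = np.max(
            np.stack(list(record.ground_truth["limb_forces"].values())), axis=0
        )

        def rms(x):
            return float(np.sqrt(np.mean(np.square(x))))

        assert rms(spl.force - truth) < 0.15 * truth.max()
        assert rms(spl.force - truth) < 2.0 * rms(raw.force - truth)
        # ripple band: around the sensor-passage frequency
        freqs = np.fft.rfftfreq(raw.n_samples, 1 / 3000.0)
        ripple_hz = 3.0 * 2 * np.pi / geometry.sensor_pitch
        band = (freqs > 0.7 * ripple_hz) & (freqs < 1.3 * ripple_hz)
        raw_band = np.abs(np.fft.rfft(raw.force))[band].sum()
        spl_band = np.abs(np.fft.rfft(spl.force))[band].sum()
        assert spl_band < raw_band

    def test_too_short_rejected(self):
        trace = ForceTrace(
            time=np.arange(3) / 3000.0, force=np.zeros(3),
            stage="raw_max", sample_rate=3000.0,
        )
        with pytest.raises(ValueError):
            smooth_spline(trace)
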