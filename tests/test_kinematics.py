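"""Stride/stance segmentation, kinematic summaries, force predictions."""

import math

import numpy as np
import pytest

from wheelgait.gaits import GRAVITY, canonical_gait
from wheelgait.kinematics import (
    extract_kinematics,
    impulse_ratio,
    predict_peak_force,
    segment_stances,
    segment_strides,
)
from wheelgait.reconstruct import ForceTrace
from wheelgait.simulate import (
    VirtualMouse,
    generate_trial,
    stride_frequency_at_speed,
)
from conftest import run_pipeline


def make_trace(force, fs=3000.0, stage="filtered"):
    force = np.asarray(force, dtype=float)
    return ForceTrace(
        time=np.arange(force.size) / fs, force=force,
        stage=stage, sample_rate=fs,
    )


def pulse_train(
    n_pulses=6, period=300, width=100, amp=0.3, offset=0, n_total=None
):
    """Separated half-sine pulses on a zero baseline."""
    n = n_total or (n_pulses * period + 2 * offset)
    x = np.zeros(n)
    starts = []
    for k in range(n_pulses):
        s = offset + k * period
        if s + width > n:
            break
        x[s : s + width] += amp * np.sin(np.pi * np.arange(width) / width)
        starts.append(s)
    return x, starts


class TestSegmentStrides:
    def test_identical_synthetic_strides_equal_windows(self):
        # one asymmetric two-pulse pattern per 300-sample stride
        period = 300
        x = np.zeros(6 * period)
        for k in range(6):
            s = k * period
            x[s : s + 80] += 0.3 * np.sin(np.pi * np.arange(80) / 80)
            x[s + 130 : s + 190] += 0.18 * np.sin(np.pi * np.arange(60) / 60)
        windows = segment_strides(make_trace(x))
        lengths = [b - a for a, b in windows]
        assert len(windows) >= 3
        assert max(lengths) - min(lengths) <= 1

    def test_simulated_trot_period_within_5pct(
        self, geometry, sensors, calibration
    ):
        from wheelgait.simulate import generate_labeled_cohort

        cohort = generate_labeled_cohort(3, {"trot": 1.0}, (0.5, 0.8), seed=12)
        for record, _, timings in cohort:
            chain = run_pipeline(record, calibration, geometry)
            windows = segment_strides(chain["filtered"])
            T = np.mean([b - a for a, b in windows]) / 3000.0
            assert T == pytest.approx(timings.stride_period, rel=0.05)

    def test_boundaries_match_autocorrelation_oracle(self):
        period = 300
        x = np.zeros(6 * period)
        for k in range(6):
            s = k * period
            x[s : s + 80] += 0.3 * np.sin(np.pi * np.arange(80) / 80)
            x[s + 130 : s + 190] += 0.18 * np.sin(np.pi * np.arange(60) / 60)
        windows = segment_strides(make_trace(x))
        measured = np.mean([b - a for a, b in windows])
        xc = x - x.mean()
        acf = np.correlate(xc, xc, mode="full")[xc.size - 1 :]
        lo, hi = 150, 450  # bracket one stride
        oracle = lo + int(np.argmax(acf[lo:hi]))
        assert abs(measured - oracle) <= 2

    def test_flat_spectrum_trace_rejected(self):
        # a lone impulse has a flat magnitude spectrum: no dominant line
        x = np.zeros(2048)
        x[100] = 1.0
        with pytest.raises(ValueError, match="periodicity"):
            segment_strides(make_trace(x))


class TestSegmentStances:
    def test_half_sine_train_matches_contacts(self):
        x, starts = pulse_train(n_pulses=5, period=300, width=100)
        stances = segment_stances(make_trace(x), (0, x.size))
        assert len(stances) == 5
        for s, true_start in zip(stances, starts):
            assert abs(s.start_idx - true_start) <= 2
            assert abs(s.stop_idx - (true_start + 100)) <= 2
            assert s.single_peak

    def test_all_zero_stride_has_no_stances(self):
        assert segment_stances(make_trace(np.zeros(500)), (0, 500)) == []

    def test_merged_double_hump_flagged_multi_peak(self):
        x = np.zeros(900)
        x[100:300] += 0.3 * np.sin(np.pi * np.arange(200) / 200)
        x[280:480] += 0.3 * np.sin(np.pi * np.arange(200) / 200)
        stances = segment_stances(make_trace(x), (0, 900))
        assert len(stances) == 1
        assert not stances[0].single_peak

    def test_grounded_interval_flagged(self):
        x = 0.2 + 0.05 * np.sin(np.linspace(0, 8 * np.pi, 1200))
        stances = segment_stances(make_trace(x), (0, 1200))
        assert len(stances) == 1
        assert stances[0].grounded


class TestExtractKinematics:
    def test_constant_speed_trot_duty_recovered(
        self, geometry, sensors, calibration
    ):
        from wheelgait.simulate import generate_labeled_cohort

        # at ~0.73 m/s the trend duty factor is ~0.40
        cohort = generate_labeled_cohort(2, {"trot": 1.0}, (0.72, 0.74), seed=14)
        for record, _, timings in cohort:
            chain = run_pipeline(record, calibration, geometry)
            kin = extract_kinematics(
                chain["filtered"], chain["speeds"],
                noise_floor=0.025, stance_trace=chain["splined"],
                footfall_times=chain["peak_times"],
            )
            duties = [k.duty_factor for k in kin if k.duty_factor is not None]
            assert duties
            df_true = np.mean(list(timings.stance_fraction.values()))
            assert np.mean(duties) == pytest.approx(df_true, abs=0.05)

    def test_speed_swing_blocks_discarded(self, calibration, geometry, sensors):
        T = 0.15
        mouse = VirtualMouse(gait=canonical_gait("trot", stride_period=T))
        record = generate_trial(geometry, sensors, mouse, 2.0, 10 * T, seed=15)
        chain = run_pipeline(record, calibration, geometry)
        swinging = np.linspace(0.0, 2.6, record.n_samples)  # steep ramp
        with pytest.raises(ValueError, match="speed"):
            extract_kinematics(chain["filtered"], swinging)

    def test_stride_frequency_is_reciprocal_period(
        self, calibration, geometry, sensors
    ):
        from wheelgait.simulate import generate_labeled_cohort

        cohort = generate_labeled_cohort(1, {"trot": 1.0}, (0.6, 0.7), seed=16)
        record = cohort[0][0]
        chain = run_pipeline(record, calibration, geometry)
        kin = extract_kinematics(chain["filtered"], chain["speeds"])
        assert kin
        for k in kin:
            assert k.stride_frequency * k.stride_period == pytest.approx(1.0)


class TestPredictPeakForce:
    def test_unit_weight_fixed_point(self):
        pred = predict_peak_force(0.034, 0.5, math.pi / 8.0)
        assert pred.predicted_peak == pytest.approx(0.034 * GRAVITY)

    def test_matches_simulator_configured_peak(self):
        from wheelgait.simulate import peak_limb_force

        g = canonical_gait("trot", duty_factor=0.4, fore_hind_duty_split=1.0)
        mouse = VirtualMouse(mass=0.034, fore_hind_bias=(0.51, 0.49), gait=g)
        pred = predict_peak_force(0.034, 0.51, 0.4)
        assert peak_limb_force(mouse, "LF") == pytest.approx(
            pred.predicted_peak, rel=0.01
        )

    def test_strictly_decreasing_in_duty_factor(self):
        peaks = [
            predict_peak_force(0.034, 0.51, df).predicted_peak
            for df in np.linspace(0.2, 0.8, 13)
        ]
        assert all(b < a for a, b in zip(peaks, peaks[1:]))

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            predict_peak_force(0.034, 0.5, 1.2)
        with pytest.raises(ValueError):
            predict_peak_force(0.034, 0.0, 0.4)


class TestImpulseRatio:
    @staticmethod
    def _half_bound_trace(geometry, sensors, calibration, bias, seed):
        """Fast half-bound: aerial gaps separate the three force pulses."""
        speed = 0.95
        T = 1.0 / stride_frequency_at_speed(speed)
        mouse = VirtualMouse(
            fore_hind_bias=bias,
            gait=canonical_gait("half_bound", stride_period=T, duty_factor=0.28),
        )
        record = generate_trial(
            geometry, sensors, mouse, speed / 0.25, 16 * T, seed=seed
        )
        return record

    def test_biased_mouse_ratio_near_construction(
        self, geometry, sensors, calibration
    ):
        values = []
        for seed in range(8):
            record = self._half_bound_trace(
                geometry, sensors, calibration, (0.51, 0.49), seed
            )
            chain = run_pipeline(record, calibration, geometry)
            values.append(
                impulse_ratio(chain["splined"], chain["peak_times"])
            )
        assert np.mean(values) == pytest.approx(0.49 / 0.51, abs=0.02)

    def test_equal_bias_ratio_near_one(self, geometry, sensors, calibration):
        record = self._half_bound_trace(
            geometry, sensors, calibration, (0.5, 0.5), 9
        )
        chain = run_pipeline(record, calibration, geometry)
        ratio = impulse_ratio(chain["splined"], chain["peak_times"])
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_trapezoid_impulse_matches_half_sine_closed_form(self):
        width, amp, fs = 150, 0.3, 3000.0
        x, starts = pulse_train(n_pulses=8, period=400, width=width, amp=amp)
        # alternate tall (hind-like) and short (fore-like) pulses
        for j, s in enumerate(starts):
            if j % 2:
                x[s : s + width] *= 2.0
        trace = make_trace(x, stage="splined")
        pts = (np.array(starts) + width / 2) / fs
        ratio = impulse_ratio(trace, pts)
        # analytic: hind pulse impulse (2/pi)*2A*tc vs 2 * fore (2/pi)*A*tc
        assert ratio == pytest.approx(1.0, rel=0.005)

    def test_indistinguishable_clusters_rejected(self):
        x, starts = pulse_train(n_pulses=8, period=400, width=150)
        trace = make_trace(x, stage="splined")
        pts = (np.array(starts) + 75) / 3000.0
        with pytest.raises(ValueError, match="distinguishable"):
            impulse_ratio(trace, pts)
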