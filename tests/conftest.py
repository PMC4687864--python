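import math

import numpy as np
import pytest

from wheelgait.reconstruct import (
    concatenate_max,
    estimate_speed,
    fit_calibration,
    smooth_spline,
    speed_at,
)
from wheelgait.simulate import (
    SensorModel,
    VirtualMouse,
    WheelGeometry,
    generate_calibration_set,
    generate_trial,
)
from wheelgait.gaits import canonical_gait
from wheelgait.spectral import two_peak_filter
from wheelgait.symmetry import peak_times

MASSES_KG = np.arange(1, 42, 5) / 1000.0  # 1-41 g calibration masses


@pytest.fixture(scope="session")
def geometry():
    return WheelGeometry()


@pytest.fixture(scope="session")
def sensors():
    return SensorModel()


@pytest.fixture(scope="session")
def calibration(geometry, sensors):
    table = generate_calibration_set(geometry, sensors, masses=MASSES_KG, seed=1)
    return fit_calibration(table)


@pytest.fixture(scope="session")
def trot_record(geometry, sensors):
    """A steady 0.5 m/s trot trial with ground truth."""
    speed = 0.5
    timings = canonical_gait("trot", stride_period=0.155, duty_factor=0.5)
    mouse = VirtualMouse(gait=timings)
    return generate_trial(
        geometry, sensors, mouse, speed / geometry.running_path_length,
        12 * 0.155, seed=42,
    )


def run_pipeline(record, calibration, geometry):
    """raw -> splined -> filtered traces plus speed series and peak times."""
    raw = concatenate_max(record, calibration)
    splined = smooth_spline(raw)
    filtered, result = two_peak_filter(splined)
    estimates = estimate_speed(record, geometry)
    rps = float(np.mean([e.rps for e in estimates]))
    fmax = 0.9 * rps * 2.0 * math.pi / geometry.sensor_pitch
    pts = peak_times(splined, max_frequency_hz=fmax)
    speeds = speed_at(estimates, record.time)
    return {
        "raw": raw,
        "splined": splined,
        "filtered": filtered,
        "filter_result": result,
        "estimates": estimates,
        "speeds": speeds,
        "rps": rps,
        "peak_times": pts,
    }
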