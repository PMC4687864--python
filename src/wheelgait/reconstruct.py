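"""From raw sensor voltages to a calibrated single-limb force trace.

The stages mirror the instrument's processing chain:

1. **Activity triggering** — recording intervals open when the central
   sensor departs +/-0.2 V from its rolling baseline (the wheel has started
   to turn) and are chunked into 5-s blocks.
2. **Calibration** — per-sensor least-squares lines mapping voltage to
   applied force, fitted from the rotating-wheel mass protocol.
3. **Drift QC** — slow baseline wander per sensor in V/h from long
   low-rate recordings.
4. **Speed estimation** — the support struts carry no magnet, so a voltage
   minimum passes the central sensor four times per revolution; wheel speed
   in revolutions/s is ``omega = f / (4 s)`` with ``f`` the sample rate and
   ``s`` the samples between consecutive minima.
5. **Maximum concatenation** — per sample, the largest calibrated force
   across the nine sensors; the single-limb force trace.
6. **Spline smoothing** — a cubic spline through the best-aligned sample of
   each sensor-handoff segment, removing the sensor-response ripple.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from scipy.stats import linregress

from .gaits import GRAVITY
from .simulate import VoltageRecord, WheelGeometry

__all__ = [
    "CalibrationMatrix",
    "SpeedEstimate",
    "ForceTrace",
    "detect_activity",
    "fit_calibration",
    "estimate_drift",
    "estimate_speed",
    "speed_at",
    "concatenate_max",
    "smooth_spline",
]


@dataclass
class CalibrationMatrix:
    """Per-sensor linear voltage-force calibration.

    ``voltage = intercept + slope * force`` with force in newtons; slopes in
    V/N must be positive, and the fit quality (R^2) is recorded per sensor.
    """

    intercept: np.ndarray
    slope: np.ndarray
    fit_r2: np.ndarray

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        self.fit_r2 = np.asarray(self.fit_r2, dtype=float)
        if not (self.intercept.shape == self.slope.shape == self.fit_r2.shape):
            raise ValueError("calibration arrays must have matching shapes")
        if np.any(self.slope <= 0):
            raise ValueError("calibration slopes must be positive")
        if np.any((self.fit_r2 < 0) | (self.fit_r2 > 1)):
            raise ValueError("R^2 must lie in [0, 1]")

    @property
    def n_sensors(self) -> int:
        return self.intercept.size

    def to_force(self, volts: np.ndarray) -> np.ndarray:
        """Convert a (n_sensors, n_samples) voltage matrix to forces (N)."""
        volts = np.asarray(volts, dtype=float)
        if volts.shape[0] != self.n_sensors:
            raise ValueError(
                f"record has {volts.shape[0]} channels but calibration covers "
                f"{self.n_sensors} sensors"
            )
        return (volts - self.intercept[:, None]) / self.slope[:, None]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept_v": self.intercept.tolist(),
                    "slope_v_per_n": self.slope.tolist(),
                    "fit_r2": self.fit_r2.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationMatrix":
        d = json.loads(Path(path).read_text())
        return cls(d["intercept_v"], d["slope_v_per_n"], d["fit_r2"])


@dataclass(frozen=True)
class SpeedEstimate:
    """Wheel speed from one pair of consecutive strut minima."""

    time_s: float  # midpoint of the minima pair
    rps: float
    linear_speed: float  # m/s
    samples_between_minima: int
    sample_rate: float


@dataclass
class ForceTrace:
    """A single-limb force time series at one processing stage."""

    time: np.ndarray
    force: np.ndarray
    stage: str  # raw_max | splined | filtered
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have the same shape")
        if self.stage not in ("raw_max", "splined", "filtered"):
            raise ValueError(f"unknown trace stage {self.stage!r}")

    @property
    def n_samples(self) -> int:
        return self.force.size

    def percent_body_weight(self, mass: float) -> np.ndarray:
        """Force expressed as % body weight for a mouse of ``mass`` kg."""
        return 100.0 * self.force / (mass * GRAVITY)


def _rolling_baseline(x: np.ndarray, window: int) -> np.ndarray:
    """Median of the preceding ``window`` samples (causal, partial at start)."""
    s = pd.Series(x)
    return s.rolling(window, min_periods=1).median().shift(1).bfill().to_numpy()


def detect_activity(
    record: VoltageRecord,
    trigger_delta: float = 0.2,
    block_s: float = 5.0,
    baseline_window_s: float = 1.0,
    gap_s: float = 1.5,
) -> list[tuple[float, float]]:
    """Active (rotating) intervals from the central-sensor trigger.

    An interval opens when the central sensor departs ``trigger_delta`` volts
    from its rolling baseline (median of the preceding second) and closes
    after ``gap_s`` seconds without a trigger; intervals are chunked into
    blocks of at most ``block_s`` seconds.
    """
    fs = record.sample_rate
    central = record.channels[(record.channels.shape[0] - 1) // 2]
    baseline = _rolling_baseline(central, max(2, int(round(baseline_window_s * fs))))
    triggered = np.abs(central - baseline) > trigger_delta
    idx = np.flatnonzero(triggered)
    if idx.size == 0:
        return []
    gap = int(round(gap_s * fs))
    # group trigger samples separated by less than the gap tolerance
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    intervals: list[tuple[float, float]] = []
    for i0, i1 in zip(starts, stops):
        t_start = record.t0 + i0 / fs
        t_stop = record.t0 + (i1 + 1) / fs
        while t_stop - t_start > block_s:
            intervals.append((t_start, t_start + block_s))
            t_start += block_s
        intervals.append((t_start, t_stop))
    return intervals


def fit_calibration(table: pd.DataFrame) -> CalibrationMatrix:
    """Least-squares voltage-force lines from a mass calibration table.

    ``table`` must have columns ``mass_kg``, ``sensor``, ``mean_voltage``
    with at least 3 distinct masses per sensor.
    """
    required = {"mass_kg", "sensor", "mean_voltage"}
    if not required.issubset(table.columns):
        raise ValueError(f"calibration table must have columns {sorted(required)}")
    sensors = sorted(table["sensor"].unique())
    intercepts, slopes, r2s = [], [], []
    for k in sensors:
        sub = table[table["sensor"] == k]
        if sub["mass_kg"].nunique() < 3:
            raise ValueError(f"sensor {k}: need at least 3 distinct calibration masses")
        force = sub["mass_kg"].to_numpy() * GRAVITY
        volts = sub["mean_voltage"].to_numpy()
        if np.ptp(volts) == 0:
            raise ValueError(f"sensor {k}: zero-variance voltages")
        fit = linregress(force, volts)
        intercepts.append(fit.intercept)
        slopes.append(fit.slope)
        r2s.append(fit.rvalue**2)
    return CalibrationMatrix(intercepts, slopes, r2s)


def estimate_drift(
    record: VoltageRecord,
    qc_bound_v_per_h: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sensor baseline drift in V/h from a long low-rate recording.

    Returns ``(slopes_v_per_h, flagged)`` where ``flagged`` marks sensors
    whose |drift| exceeds the QC bound.  Requires at least 1 h of data.
    """
    t_h = record.time / 3600.0
    if t_h[-1] - t_h[0] < 1.0:
        raise ValueError("drift estimation requires at least 1 hour of data")
    slopes = np.array(
        [linregress(t_h, ch).slope for ch in record.channels]
    )
    return slopes, np.abs(slopes) > qc_bound_v_per_h


def estimate_speed(
    record: VoltageRecord,
    geometry: WheelGeometry | None = None,
    window: tuple[float, float] | None = None,
    minima_depth_v: float = 0.1,
    minima_prominence_v: float = 0.25,
    rps_max: float = 5.0,
) -> list[SpeedEstimate]:
    """Wheel speed from central-sensor strut minima: ``omega = f / (4 s)``.

    Local minima deeper than ``minima_depth_v`` below the unloaded baseline
    (estimated as the 10th percentile of the window — limb forces only raise
    the voltage) and with prominence of at least ``minima_prominence_v``
    (strut dips are ~0.5 V deep, noise wiggles far shallower), separated by
    at least ``f / (4 rps_max)`` samples, mark strut passages; each
    consecutive pair yields one estimate at the pair's midpoint time.
    """
    geometry = geometry or WheelGeometry()
    fs = record.sample_rate
    central = record.channels[geometry.central_sensor]
    t = record.time
    if window is not None:
        sel = (t >= window[0]) & (t < window[1])
        central, t = central[sel], t[sel]
    if central.size < 2:
        return []
    # limb forces raise the voltage and strut gaps lower it, so the unloaded
    # baseline is the low quantile of the window, not its median
    baseline = float(np.quantile(central, 0.10))
    depth = baseline - central
    min_sep = max(1, int(round(fs / (4.0 * rps_max))))
    minima, _ = find_peaks(
        depth, height=minima_depth_v, prominence=minima_prominence_v, distance=min_sep
    )
    if minima.size < 2:
        return []
    out = []
    for i0, i1 in zip(minima[:-1], minima[1:]):
        s = int(i1 - i0)
        rps = fs / (geometry.n_struts_per_rev * s)
        out.append(
            SpeedEstimate(
                time_s=float(0.5 * (t[i0] + t[i1])),
                rps=rps,
                linear_speed=rps * geometry.running_path_length,
                samples_between_minima=s,
                sample_rate=fs,
            )
        )
    return out


def speed_at(estimates: Sequence[SpeedEstimate], t: np.ndarray) -> np.ndarray:
    """Linear speed (m/s) interpolated at times ``t`` from strut estimates."""
    if not estimates:
        raise ValueError("no speed estimates available")
    times = np.array([e.time_s for e in estimates])
    speeds = np.array([e.linear_speed for e in estimates])
    return np.interp(np.asarray(t, dtype=float), times, speeds)


def concatenate_max(
    record: VoltageRecord, calibration: CalibrationMatrix
) -> ForceTrace:
    """Maximum-concatenated single-limb force trace (stage ``raw_max``).

    Each sample takes the largest calibrated force across sensors (negative
    calibrated readings from unloaded pads are floored at zero), so when two
    feet load different pads only the greater force enters the trace; two
    feet on one pad appear summed, as in the physical instrument.
    """
    forces = calibration.to_force(record.channels)
    np.clip(forces, 0.0, None, out=forces)
    argmax = np.argmax(forces, axis=0)
    force = forces[argmax, np.arange(forces.shape[1])]
    return ForceTrace(
        time=record.time,
        force=force,
        stage="raw_max",
        sample_rate=record.sample_rate,
        meta={"argmax_sensor": argmax},
    )


def _handoff_knots(trace: ForceTrace, smooth_samples: int = 15) -> np.ndarray:
    """Knot indices: the best-aligned (maximal) sample of each constant-
    argmax-sensor segment, plus the trace endpoints.

    The winning-sensor index is median-filtered first: where two sensors
    read near-equal forces (crossovers, unloaded noise) the argmax flickers
    sample to sample, and unfiltered flicker would put a knot on nearly
    every sample."""
    argmax = trace.meta.get("argmax_sensor")
    if argmax is None:
        # fall back to local extrema of the trace itself
        peaks, _ = find_peaks(trace.force)
        troughs, _ = find_peaks(-trace.force)
        knots = np.unique(
            np.concatenate([[0], peaks, troughs, [trace.n_samples - 1]])
        )
        return knots, trace.force[knots]
    argmax = median_filter(np.asarray(argmax), size=smooth_samples, mode="nearest")
    boundaries = np.flatnonzero(np.diff(argmax) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [trace.n_samples]])
    force = trace.force
    # sample-to-sample noise scale; the force signal itself varies slowly
    sigma = 1.4826 * float(np.median(np.abs(np.diff(force)))) / math.sqrt(2.0)
    floor = 5.0 * sigma
    knots, values = [], []
    for s, e in zip(starts, stops):
        seg = force[s:e]
        if seg.max() < floor:
            # unloaded segment: anchor at the median level, not the noise max
            knots.append(s + (e - s) // 2)
            values.append(float(np.median(seg)))
        else:
            j = s + int(np.argmax(seg))
            knots.append(j)
            values.append(float(force[j]))
    if 0 not in knots:
        knots.insert(0, 0)
        values.insert(0, float(force[0]))
    if trace.n_samples - 1 not in knots:
        knots.append(trace.n_samples - 1)
        values.append(float(force[-1]))
    order = np.argsort(knots)
    knots = np.asarray(knots)[order]
    values = np.asarray(values)[order]
    keep = np.concatenate([[True], np.diff(knots) > 0])
    return knots[keep], values[keep]


def smooth_spline(trace: ForceTrace) -> ForceTrace:
    """Cubic-spline smoothing of a raw_max trace (stage ``splined``).

    Knots sit at the best-aligned sample of each sensor-handoff segment —
    where the sensor response is maximal and the reading closest to the true
    pad force — and a natural cubic spline through them is evaluated on the
    original time grid.  Endpoints are preserved; traces with fewer than 4
    knots are returned unchanged.
    """
    if trace.n_samples < 4:
        raise ValueError("spline smoothing needs at least 4 samples")
    knots, knot_values = _handoff_knots(trace)
    if knots.size < 4:
        force = trace.force.copy()
    else:
        spline = CubicSpline(trace.time[knots], knot_values, bc_type="natural")
        force = np.clip(spline(trace.time), 0.0, None)  # forces are compressive
        force[knots] = np.clip(knot_values, 0.0, None)  # exact at knots
    return ForceTrace(
        time=trace.time.copy(),
        force=force,
        stage="splined",
        sample_rate=trace.sample_rate,
        meta=dict(trace.meta),
    )
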