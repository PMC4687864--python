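"""Virtual force-sensing exercise wheel: a physics-based signal generator.

The simulated instrument mirrors the real one: a wheel of 16 sprung pads
(4 groups of 4, separated by support struts) rotates over a fixed arc of 9
Hall sensors sampled in parallel at 3 kHz.  Each pad carries a magnet; a
loaded pad deflects and raises the voltage of whichever sensor it is passing
over.  Strut gaps carry no magnet, so a dip sweeps across the sensor array
four times per revolution — the central-sensor minima used for wheel-speed
estimation.

A virtual mouse runs in place at a fixed station while the wheel rotates
under it.  Each limb exerts a half-sine vertical force during its stance,
with the peak set by impulse balance so that each limb pair supports its
share of body weight:

    F_peak(limb) = pi * beta_pair * m * g / (4 * duty_factor)

where ``beta_pair`` is the fore:hind weight-support split (default
0.51:0.49).  A foot lands on whichever pad is under its station at touch-down
and rides that pad across the sensor array for the stance; two feet landing
on one pad sum their forces, as in the real wheel.

Sensor response to a pad is a smooth raised cosine in angular offset,
reaching zero at one pad pitch, so that with every pad equally loaded the
summed response is exactly 1 (cos^2 + sin^2) — the regime in which the
instrument's linear calibration is carried out.

Everything is deterministic given a seed, and every record carries its
ground truth (speed profile, per-limb force traces, contact events), so each
downstream processing stage can be validated without an instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gaits import LIMBS, GRAVITY, GaitLabel, GaitTimings, canonical_gait

__all__ = [
    "WheelGeometry",
    "SensorModel",
    "VirtualMouse",
    "VoltageRecord",
    "limb_force_profile",
    "generate_trial",
    "generate_calibration_set",
    "generate_labeled_cohort",
    "stride_frequency_at_speed",
    "duty_factor_at_speed",
]


@dataclass(frozen=True)
class WheelGeometry:
    """Wheel and sensor-array geometry.

    ``running_path_length`` is the distance a mouse covers per wheel
    revolution (0.25 m, so 1 rps = 0.25 m/s).  Sensors sit on a fixed arc
    under the running station; pads pass over them as the wheel turns.
    """

    n_pads: int = 16
    pads_per_group: int = 4
    n_groups: int = 4
    n_sensors: int = 9
    n_struts_per_rev: int = 4
    running_path_length: float = 0.25
    sensor_pitch: float = 2.0 * math.pi / 28.0  # radians between sensors
    pad_angular_width: float = 2.0 * math.pi / 16.0  # response window width
    strut_half_width: float = 0.04  # radians; angular extent of a strut gap
    # touch-down stations (radians): the wheel turns toward positive angles,
    # so stances sweep from the station across the sensor arc.  Hind feet sit
    # nearly side by side (they share a pad when landing together, as in
    # half-bounding); fore feet are laterally offset on the curved track and
    # land on distinct pads.
    fore_station: float = -0.36
    hind_station: float = -0.85
    fore_lateral_offset: float = 0.10
    hind_lateral_offset: float = 0.02

    def __post_init__(self) -> None:
        if self.n_pads != self.n_groups * self.pads_per_group:
            raise ValueError("n_pads must equal n_groups * pads_per_group")
        if self.running_path_length <= 0:
            raise ValueError("running_path_length must be positive")

    @property
    def sensor_angles(self) -> np.ndarray:
        """Sensor angular positions, centered on the running station."""
        k = np.arange(self.n_sensors)
        return (k - (self.n_sensors - 1) / 2.0) * self.sensor_pitch

    @property
    def central_sensor(self) -> int:
        return (self.n_sensors - 1) // 2

    @property
    def pad_pitch(self) -> float:
        return 2.0 * math.pi / self.n_pads

    @property
    def pad_centers(self) -> np.ndarray:
        return np.arange(self.n_pads) * self.pad_pitch

    @property
    def strut_angles(self) -> np.ndarray:
        """Strut (group-boundary) angles in the wheel frame."""
        return (
            np.arange(self.n_struts_per_rev) * (2.0 * math.pi / self.n_struts_per_rev)
            - self.pad_pitch / 2.0
        )

    def station(self, limb: str) -> float:
        base, off = (
            (self.fore_station, self.fore_lateral_offset)
            if limb in ("LF", "RF")
            else (self.hind_station, self.hind_lateral_offset)
        )
        return base - off if limb.startswith("L") else base + off


@dataclass(frozen=True)
class SensorModel:
    """Hall-sensor transfer characteristics.

    ``noise_sd`` defaults to 0.0133 V so that the 3-sigma band is ~0.04 V,
    the instrument's noise threshold.  ``drift_rate`` is the slow baseline
    wander (0.63 mV/h).  ``trigger_delta`` (0.2 V) is the departure from
    baseline that starts a recording.  ``strut_dip`` is the voltage drop when
    a magnet-free strut gap sits over a sensor.
    """

    baseline_voltage: float = 2.5
    gain: float = 2.0  # V per newton
    noise_sd: float = 0.0133
    drift_rate: float = 0.00063  # V per hour
    trigger_delta: float = 0.2
    strut_dip: float = 0.5

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class VirtualMouse:
    """A mouse defined by mass, weight-support bias, leg length and gait.

    ``fore_hind_bias`` splits body-weight support between the fore and hind
    pairs (0.51:0.49 in mice).  ``lateral_bias`` is the left limb's share of
    each pair's load (0.5 = perfectly balanced; real animals show a few
    percent of limb dominance).
    """

    mass: float = 0.034  # kg
    fore_hind_bias: tuple[float, float] = (0.51, 0.49)
    lateral_bias: float = 0.5
    gait: GaitTimings = field(default_factory=lambda: canonical_gait("trot"))
    leg_length: float = 0.026  # m (hip height)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not math.isclose(sum(self.fore_hind_bias), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("fore:hind bias fractions must sum to 1")
        if not 0.0 < self.lateral_bias < 1.0:
            raise ValueError("lateral bias must lie in (0, 1)")

    def pair_bias(self, limb: str) -> float:
        return self.fore_hind_bias[0] if limb in ("LF", "RF") else self.fore_hind_bias[1]

    def limb_share(self, limb: str) -> float:
        """This limb's share of body-weight support (all four sum to 1)."""
        side = self.lateral_bias if limb.startswith("L") else 1.0 - self.lateral_bias
        return self.pair_bias(limb) * side

    @property
    def body_weight(self) -> float:
        return self.mass * GRAVITY


@dataclass
class VoltageRecord:
    """A 9-channel voltage recording with optional simulation ground truth."""

    sample_rate: float
    channels: np.ndarray  # (n_sensors, n_samples)
    t0: float = 0.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2-D (sensor x sample) array")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-pi, pi)."""
    return (np.asarray(angle) + math.pi) % (2.0 * math.pi) - math.pi


def peak_limb_force(mouse: VirtualMouse, limb: str) -> float:
    """Half-sine peak force (N) for one limb from the impulse-balance model.

    With a balanced lateral bias this is ``pi * beta_pair * m * g / (4 DF)``;
    in general the pair's share splits between its limbs as
    ``limb_share = beta_pair * (lateral or 1 - lateral)``.
    """
    duty = mouse.gait.stance_fraction[limb]
    if not 0.0 < duty < 1.0:
        raise ValueError(f"duty factor for {limb} must lie in (0, 1), got {duty}")
    return math.pi * mouse.limb_share(limb) * mouse.mass * GRAVITY / (2.0 * duty)


def limb_force_profile(
    mouse: VirtualMouse, limb: str, stride_phase: np.ndarray | float
) -> np.ndarray | float:
    """Vertical force (N) exerted by ``limb`` at the given stride phase(s).

    The force is a half sine over the limb's stance window and zero in swing.
    """
    phase = np.asarray(stride_phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("stride phase must lie in [0, 1)")
    onset = mouse.gait.contact_onset[limb]
    duty = mouse.gait.stance_fraction[limb]
    f_peak = peak_limb_force(mouse, limb)
    s = (phase - onset) % 1.0
    force = np.where(s < duty, f_peak * np.sin(math.pi * np.minimum(s / duty, 1.0)), 0.0)
    return force if force.ndim else float(force)


def _strut_coverage(theta: np.ndarray, geometry: WheelGeometry) -> np.ndarray:
    """Fractional strut-gap coverage (n_sensors, n_samples) in [0, 1].

    1 means a magnet-free strut gap is centered over the sensor; the sensor
    then reads the magnet-free floor no matter what forces act on the pads.
    """
    cov = np.zeros((geometry.n_sensors, theta.size))
    hw = geometry.strut_half_width
    for s_angle in geometry.strut_angles:
        for k, sigma in enumerate(geometry.sensor_angles):
            delta = np.abs(_wrap(s_angle + theta - sigma))
            active = delta < hw
            if np.any(active):
                cov[k, active] += 1.0 - delta[active] / hw
    return np.clip(cov, 0.0, 1.0)


def _rps_array(
    speed_profile: float | Callable[[np.ndarray], np.ndarray],
    t: np.ndarray,
) -> np.ndarray:
    if callable(speed_profile):
        rps = np.asarray(speed_profile(t), dtype=float) * np.ones_like(t)
    else:
        rps = np.full_like(t, float(speed_profile))
    if np.any(rps < 0):
        raise ValueError("speed profile must be non-negative")
    return rps


def generate_trial(
    geometry: WheelGeometry,
    sensors: SensorModel,
    mouse: VirtualMouse,
    speed_profile: float | Callable[[np.ndarray], np.ndarray],
    duration: float,
    seed: int | None = 0,
    hitch_prob: float = 0.0,
    hitch_max: float = 0.4,
) -> VoltageRecord:
    """Simulate one wheel recording.

    Parameters
    ----------
    speed_profile
        Wheel speed in revolutions per second: a constant or a callable of
        time (seconds).
    duration
        Recording length in seconds.
    seed
        Seed for sensor noise and contact hitches; the mechanics are
        otherwise deterministic.
    hitch_prob
        Per-stride probability of a hesitation: the stride clock pauses for
        up to ``hitch_max`` stride fractions before that stride, delaying
        every subsequent contact.  Models the stop-start irregularity of
        exploratory (creeping) locomotion; 0 for steady gaits.

    Returns
    -------
    VoltageRecord
        With ``ground_truth`` holding the speed profile, wheel angle,
        per-limb force traces and the contact-event table
        (limb, pad, onset, offset).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = 3000.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rps = _rps_array(speed_profile, t)

    omega = 2.0 * math.pi * rps  # rad/s
    max_omega = float(np.max(omega))
    if max_omega > 0 and geometry.pad_angular_width / max_omega < 2.0 / fs:
        raise ValueError(
            "wheel speed too high: a pad crosses a sensor in under 2 samples; "
            "use a higher sample rate or a slower speed profile"
        )
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1])) / fs])

    gait = mouse.gait
    T = gait.stride_period
    force_on_sensor = np.zeros((geometry.n_sensors, n))
    limb_forces = {limb: np.zeros(n) for limb in LIMBS}
    events: list[dict] = []
    sensor_angles = geometry.sensor_angles
    w = geometry.pad_angular_width

    rng = np.random.default_rng(seed)
    # intermittency: the stride clock occasionally pauses, delaying every
    # later contact of every limb together (a per-limb hitch would be
    # swallowed by the maximum over the other limbs' unchanged forces)
    k_lo = int(math.floor(-2.0 * T / T)) - 2
    k_hi = int(math.ceil(duration / T)) + 3
    stride_delay = np.zeros(k_hi - k_lo + 1)
    if hitch_prob > 0:
        pauses = np.where(
            rng.random(stride_delay.size) < hitch_prob,
            rng.uniform(0.1, hitch_max, stride_delay.size) * T,
            0.0,
        )
        stride_delay = np.cumsum(pauses)

    for limb in LIMBS:
        onset_phase = gait.contact_onset[limb]
        duty = gait.stance_fraction[limb]
        f_peak = peak_limb_force(mouse, limb)
        t_c = duty * T
        station = geometry.station(limb)
        k_first = int(math.floor((-onset_phase * T - t_c) / T)) - 1
        k_last = int(math.ceil((duration - onset_phase * T) / T)) + 1
        for k in range(max(k_first, k_lo), min(k_last, k_hi) + 1):
            t_on = (k + onset_phase) * T + stride_delay[k - k_lo]
            t_off = t_on + t_c
            if t_off <= 0 or t_on >= duration:
                continue
            i0 = max(0, int(math.ceil(t_on * fs)))
            i1 = min(n, int(math.ceil(t_off * fs)))
            if i1 <= i0:
                continue
            # the foot lands on the pad under its station and rides it
            theta_on = np.interp(t_on, t, theta)
            pad = int(
                np.argmin(np.abs(_wrap(geometry.pad_centers + theta_on - station)))
            )
            idx = slice(i0, i1)
            s = (t[idx] - t_on) / t_c
            f = f_peak * np.sin(math.pi * s)
            limb_forces[limb][idx] += f
            pad_angle = geometry.pad_centers[pad] + theta[idx]
            for ks, sigma in enumerate(sensor_angles):
                delta = np.abs(_wrap(pad_angle - sigma))
                hit = delta < w
                if np.any(hit):
                    # raised-cosine magnet-sensor coupling: smooth, unity at
                    # alignment, zero at one pad pitch; adjacent responses
                    # tile to exactly 1 (cos^2 + sin^2), so a uniformly
                    # loaded wheel reads its true total force
                    resp = np.cos(math.pi * delta[hit] / (2.0 * w)) ** 2
                    force_on_sensor[ks, i0:i1][hit] += f[hit] * resp
            events.append(
                {"limb": limb, "pad": pad, "onset_s": t_on, "offset_s": t_off,
                 "peak_n": f_peak}
            )

    noise = rng.normal(0.0, sensors.noise_sd, size=force_on_sensor.shape)
    cov = _strut_coverage(theta, geometry)
    volts = (
        sensors.baseline_voltage
        + (1.0 - cov) * sensors.gain * force_on_sensor
        - cov * sensors.strut_dip
        + noise
        + sensors.drift_rate * (t / 3600.0)
    )

    ground_truth = {
        "rps": rps,
        "theta": theta,
        "linear_speed": rps * geometry.running_path_length,
        "stride_period": T,
        "duty_factor": dict(gait.stance_fraction),
        "limb_forces": limb_forces,
        "total_force": sum(limb_forces.values()),
        "events": events,
        "seed": seed,
    }
    return VoltageRecord(sample_rate=fs, channels=volts, ground_truth=ground_truth)


def generate_calibration_set(
    geometry: WheelGeometry,
    sensors: SensorModel,
    masses: Sequence[float],
    seed: int | None = 0,
    duration: float = 5.0,
    rps: float = 1.0,
) -> pd.DataFrame:
    """Simulate the static-mass calibration protocol.

    Identical masses are attached to every pad and the wheel is rotated for
    ``duration`` seconds at ``rps``; the mean voltage per sensor is recorded
    for each mass.  Because the triangular sensor response tiles the pad
    pitch exactly, the summed response of a uniformly loaded wheel is 1, so
    mean voltage is linear in applied force (minus a constant strut-gap
    offset that the calibration intercept absorbs).

    Returns a tidy table with columns ``mass_kg``, ``sensor``,
    ``mean_voltage``.
    """
    if len(masses) == 0:
        raise ValueError("mass list must not be empty")
    if any(m < 0 for m in masses):
        raise ValueError("masses must be non-negative")
    fs = 3000.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    theta = 2.0 * math.pi * rps * t
    cov = _strut_coverage(theta, geometry)
    rng = np.random.default_rng(seed)
    rows = []
    for m in masses:
        force = m * GRAVITY
        noise = rng.normal(0.0, sensors.noise_sd, size=cov.shape)
        volts = (
            sensors.baseline_voltage
            + (1.0 - cov) * sensors.gain * force
            - cov * sensors.strut_dip
            + noise
        )
        for k in range(geometry.n_sensors):
            # strut-gap passages are obvious outliers in the dip direction;
            # the protocol gates them out of the averaging window
            ch = volts[k]
            keep = ch > np.median(ch) - 0.1
            rows.append(
                {"mass_kg": float(m), "sensor": k, "mean_voltage": float(ch[keep].mean())}
            )
    return pd.DataFrame(rows)


def _naturalize_timings(
    timings: GaitTimings, category: str, rng: np.random.Generator
) -> GaitTimings:
    """Perturb idealized footfall timings the way real strides deviate.

    A real trot is never perfectly left-right symmetric: its two diagonal
    steps are unevenly spaced by a few percent of the stride (drawn here
    from 2-6%), which is what makes the stride — rather than the step — the
    true period of the force trace.  Other gaits get a small white phase
    jitter.  Perturbations are small enough to preserve the category label.
    """
    onset = dict(timings.contact_onset)
    if category == "trot":
        delta = float(rng.uniform(0.02, 0.06))
        # the second diagonal step (RH + LF at phase 0.5) lands early
        onset["RH"] = (onset["RH"] - delta) % 1.0
        onset["LF"] = (onset["LF"] - delta) % 1.0
    else:
        # creeping is intermittent and irregularly timed; other gaits get
        # small white phase jitter
        sd = 0.03 if category == "creep" else 0.008
        for limb in onset:
            onset[limb] = float((onset[limb] + rng.normal(0.0, sd)) % 1.0)
    return GaitTimings(
        contact_onset=onset,
        stance_fraction=dict(timings.stance_fraction),
        stride_period=timings.stride_period,
    )


# ---------------------------------------------------------------------------
# Speed scaling of gait parameters
# ---------------------------------------------------------------------------

def stride_frequency_at_speed(speed: float) -> float:
    """Stride frequency (Hz) at a given linear speed (m/s).

    Linear trend fitted to mouse wheel-running kinematics: ~3.6 Hz near
    0.08 m/s rising to ~9 Hz near 1.1 m/s.
    """
    return 3.2 + 5.4 * speed


def duty_factor_at_speed(speed: float, *, creep: bool = False) -> float:
    """Duty factor at a given speed: decreasing from ~0.8 toward ~0.25.

    Creeping gaits keep grounded duty factors (>= 0.6) regardless of speed.
    """
    df = float(np.clip(0.8 - 0.55 * speed, 0.22, 0.8))
    return max(df, 0.62) if creep else df


def generate_labeled_cohort(
    n_trials: int,
    gait_mix: Mapping[str, float] | None = None,
    speed_range: tuple[float, float] = (0.06, 0.90),
    seed: int | None = 0,
    geometry: WheelGeometry | None = None,
    sensors: SensorModel | None = None,
    mass: float = 0.034,
    fore_hind_bias: tuple[float, float] = (0.51, 0.49),
    n_strides: float = 16.0,
) -> list[tuple[VoltageRecord, GaitLabel, GaitTimings]]:
    """Generate a reproducible cohort of labeled trials.

    Each trial draws a gait category from ``gait_mix`` and a speed uniformly
    from ``speed_range``; stride frequency and duty factor follow their
    speed trends, so stance fractions decrease with speed.  The trial lasts
    ``n_strides`` strides (at least 1 s).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if gait_mix is None:
        gait_mix = {"creep": 0.25, "trot": 0.25, "gallop": 0.25, "half_bound": 0.25}
    gait_mix = dict(gait_mix)
    if not gait_mix:
        raise ValueError("gait mix must not be empty")
    cats = sorted(gait_mix)
    probs = np.array([gait_mix[c] for c in cats], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("gait mix weights must sum to a positive value")
    probs = probs / probs.sum()

    geometry = geometry or WheelGeometry()
    sensors = sensors or SensorModel()
    rng = np.random.default_rng(seed)
    out = []
    # Per-gait speed preferences: wheel-running speeds center on a preferred
    # speed of ~0.50 +/- 0.13 m/s overall, with creeping confined below the
    # walk-trot transition band (whose Froude-predicted lower edge is
    # 0.36 m/s), trotting centered mid-range, and bounding/galloping fastest.
    speed_prefs = {
        "creep": (0.25, 0.08, 0.06, 0.38),
        "trot": (0.52, 0.12, 0.36, 1.2),
        "gallop": (0.72, 0.15, 0.40, 1.2),
        "half_bound": (0.72, 0.15, 0.40, 1.2),
    }
    for _ in range(n_trials):
        category = cats[int(rng.choice(len(cats), p=probs))]
        lo, hi = speed_range
        mu, sd, band_lo, band_hi = speed_prefs[category]
        s_lo, s_hi = max(lo, band_lo), min(hi, band_hi)
        if s_lo >= s_hi:  # requested range misses the gait's band entirely
            s_lo, s_hi = lo, hi
        speed = float(np.clip(rng.normal(mu, sd), s_lo, s_hi))
        for _ in range(20):  # rejection sampling; clip only as last resort
            cand = rng.normal(mu, sd)
            if s_lo <= cand <= s_hi:
                speed = float(cand)
                break
        T = 1.0 / stride_frequency_at_speed(speed)
        df = duty_factor_at_speed(speed, creep=(category == "creep"))
        if category in ("gallop", "half_bound"):
            # asymmetric gaits are running gaits with aerial phases
            df = min(df, 0.35)
        timings = canonical_gait(category, stride_period=T, duty_factor=df)
        timings = _naturalize_timings(timings, category, rng)
        mouse = VirtualMouse(
            mass=mass,
            fore_hind_bias=fore_hind_bias,
            lateral_bias=float(rng.uniform(0.52, 0.55)),
            gait=timings,
        )
        rps = speed / geometry.running_path_length
        # whole strides per trial: steady bouts start and end at stride
        # boundaries, which also keeps spectral lines on FFT bin centers
        duration = math.ceil(max(n_strides, 1.0 / T)) * T
        trial_seed = int(rng.integers(0, 2**31 - 1))
        record = generate_trial(
            geometry,
            sensors,
            mouse,
            rps,
            duration,
            seed=trial_seed,
            hitch_prob=0.35 if category == "creep" else 0.0,
        )
        record.ground_truth["category"] = category
        record.ground_truth["speed"] = speed
        out.append((record, GaitLabel(category), timings))
    return out
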