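"""The 3S (stride signal symmetry) metric and the gait continuum.

3S places every gait on a continuous scale from asymmetric (half-bound-like)
to symmetric (trot-like) using only the force trace, no video.  The
inter-peak intervals of the trace are differenced once to give a triangle or
sawtooth wave and a second time to give the wave ``u``; the half-wave
symmetry of ``u`` is then measured.  A perfectly half-wave antisymmetric
``u`` — the alternating long-short interval pattern of a trot — satisfies
``u(i + P/2) = -u(i)`` over one stride of ``P`` peaks, so the mean square
error between ``u`` and a half-stride circular shift of itself is maximal,
``4 * mean(u^2)``.  The normalized score

    3S = MSE(u, shift(u, round(P/2))) / (4 * mean(u^2))

therefore lies in [0, 1]: a square trot scores 1, a skewed half-bound
sawtooth scores low.  A perfectly regular peak train (``u = 0``) scores 1
by convention — maximal symmetry.

The symmetric/asymmetric threshold is not portable across normalizations,
so it is calibrated per dataset by sweeping candidate thresholds and
finding the intersection of the specificity curve (fraction of symmetric
gaits called symmetric) and the sensitivity curve (fraction of asymmetric
gaits called not-symmetric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .gaits import GaitLabel
from .reconstruct import ForceTrace

__all__ = [
    "GaitSample",
    "ThresholdCalibration",
    "TdiffRegression",
    "ContinuumSummary",
    "peak_times",
    "compute_3s",
    "score_trace",
    "calibrate_threshold",
    "tdiff_regression",
    "continuum_summary",
]


@dataclass
class GaitSample:
    """One classified gait observation."""

    speed: float  # m/s
    s3: float
    symmetric_call: bool | None = None
    video_label: GaitLabel | None = None
    t_diff: float | None = None


@dataclass(frozen=True)
class ThresholdCalibration:
    """Sensitivity/specificity threshold sweep and its crossing point."""

    threshold: float
    thresholds: np.ndarray
    specificity_curve: np.ndarray  # P(call symmetric | symmetric)
    sensitivity_curve: np.ndarray  # P(call asymmetric | asymmetric)
    accuracy_at_threshold: float


@dataclass(frozen=True)
class TdiffRegression:
    """Least-squares line of 3S against the T_diff timing contrast."""

    slope: float
    intercept: float
    r: float
    p_value: float
    s3_at_tdiff_zero: float


@dataclass(frozen=True)
class ContinuumSummary:
    """Speed histogram, per-bin symmetric fraction, candidate boundaries."""

    bin_edges: np.ndarray
    counts: np.ndarray
    proportion_symmetric: np.ndarray  # NaN for empty bins
    boundary_speeds: tuple[float, ...]
    region_fits: tuple[dict, ...] = field(default=())


def peak_times(
    trace: ForceTrace,
    min_height_frac: float = 0.1,
    min_prominence_frac: float = 0.10,
    min_separation_periods: float = 0.15,
    max_frequency_hz: float | None = None,
    refine: bool = True,
) -> np.ndarray:
    """Times (s) of force peaks exceeding ``min_height_frac`` of the maximum.

    Residual sensor-handoff ripple can split one stance hump into several
    local maxima, so besides a prominence requirement, peaks must be
    separated by at least ``min_separation_periods`` of the trace's own
    dominant period (footfalls are never packed tighter than that; when two
    candidates conflict the taller wins).  Peak locations are refined to
    sub-sample precision by parabolic interpolation of the three samples
    around each maximum; at a 3 kHz sample rate the raw quantization
    otherwise injects white jitter into the twice-differenced interval
    wave.  Requires at least 4 peaks.
    """
    x = np.asarray(trace.force, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("trace has no peaks")
    fx = np.fft.rfft(x - x.mean())
    distance = None
    if fx.size > 1 and np.abs(fx[1:]).max() > 0:
        dom_bin = 1 + int(np.argmax(np.abs(fx[1:])))
        distance = max(1, int(min_separation_periods * x.size / dom_bin))
        # anti-ripple guard band: sensor-handoff ripple rides at the wheel's
        # sensor-passage rate, above the footfall harmonics; a zero-phase
        # low-pass removes it while keeping the harmonics that resolve
        # closely spaced footfalls.  The cut sits just under the ripple
        # frequency when the caller supplies it, but never below 3x the
        # dominant line (the resolution floor for a 0.2-stride footfall
        # lag) nor above 7x
        cut = 7 * dom_bin
        if max_frequency_hz is not None:
            duration = x.size / trace.sample_rate
            cut = min(cut, int(max_frequency_hz * duration))
        cut = max(3 * dom_bin, min(fx.size - 1, cut))
        cut = min(cut, fx.size - 1)
        fx[cut + 1 :] = 0.0
        x = x.mean() + np.fft.irfft(fx, x.size)
    idx, _ = find_peaks(
        x,
        height=min_height_frac * x.max(),
        prominence=min_prominence_frac * x.max(),
        distance=distance,
    )
    if idx.size < 4:
        raise ValueError(f"need at least 4 peaks for 3S, found {idx.size}")
    t = np.asarray(trace.time, dtype=float)
    if not refine:
        return t[idx]
    dt = 1.0 / trace.sample_rate
    times = []
    for i in idx:
        if 0 < i < x.size - 1:
            denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
            delta = 0.5 * (x[i - 1] - x[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        times.append(t[i] + delta * dt)
    return np.asarray(times)


def _peaks_per_stride(d: np.ndarray, max_period: int = 4) -> int:
    """Dominant repeat period of the inter-peak interval sequence (min 2).

    The period is read off a periodogram of the de-meaned interval sequence
    at the candidate periods (2-4 peaks per stride cover quadruped gaits):
    an alternating trot puts its power at period 2, a three-pulse half-bound
    at period 3.  This is robust to the slow amplitude modulation that
    repeat-error matching mistakes for a longer period.
    """
    var = float(np.var(d))
    if var <= 1e-12 * float(np.mean(d)) ** 2:
        return 2
    x = d - d.mean()
    pos = np.arange(d.size)
    best_p, best_power = 2, -1.0
    for p in range(2, min(max_period, d.size - 1) + 1):
        phase = np.exp(-2j * math.pi * pos / p)
        power = float(np.abs(np.sum(x * phase)) ** 2)
        if power > best_power:
            best_power, best_p = power, p
    return best_p


def compute_3s(
    peak_time_values: Sequence[float] | np.ndarray,
    peaks_per_stride: int | None = None,
) -> float:
    """3S score in [0, 1] from ordered force-peak times.

    ``peaks_per_stride`` overrides the automatic period estimate from the
    dominant repeat of the interval sequence.  Invariant to time translation
    and positive time scaling.
    """
    times = np.asarray(peak_time_values, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 peak times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("peak times must be strictly increasing")
    d = np.diff(times)
    w = np.diff(d)
    u = np.diff(w)
    mean_u2 = float(np.mean(u**2))
    if mean_u2 <= (1e-6 * float(np.mean(d))) ** 2:
        return 1.0  # perfectly even peak train: maximal symmetry
    p = peaks_per_stride if peaks_per_stride is not None else _peaks_per_stride(d)
    p = max(2, int(p))
    # the circular shift is only meaningful over whole pattern periods:
    # a trailing partial period breaks the wrap-around pairing and deflates
    # even a perfectly antisymmetric wave, so trim to a multiple of p
    whole = (u.size // p) * p
    if whole >= p:
        u = u[:whole]
        mean_u2 = float(np.mean(u**2))
        if mean_u2 <= (1e-6 * float(np.mean(d))) ** 2:
            return 1.0
    shift = int(np.floor(p / 2.0 + 0.5))  # round half up
    mse = float(np.mean((u - np.roll(u, shift)) ** 2))
    return float(np.clip(mse / (4.0 * mean_u2), 0.0, 1.0))


def score_trace(
    peak_time_values: Sequence[float] | np.ndarray,
    window_peaks: int = 9,
    peaks_per_stride: int | None = None,
) -> float:
    """Robust trace-level 3S: median of window scores.

    :func:`compute_3s` is a mean-square statistic, so one glitched stride
    (a missed or split peak) can dominate a long trace's score.  Scoring
    overlapping windows of ``window_peaks`` peaks and taking the median
    keeps the metric identical on clean traces while containing isolated
    artifacts, which corrupt only the minority of windows that contain them.
    """
    times = np.asarray(peak_time_values, dtype=float)
    if times.size <= window_peaks + 3:
        return compute_3s(times, peaks_per_stride)
    scores = []
    step = max(2, window_peaks // 3)
    for start in range(0, times.size - window_peaks + 1, step):
        win = times[start : start + window_peaks]
        try:
            scores.append(compute_3s(win, peaks_per_stride))
        except ValueError:
            continue
    if not scores:
        return compute_3s(times, peaks_per_stride)
    return float(np.median(scores))


def calibrate_threshold(
    scores: Sequence[float] | np.ndarray,
    symmetric_labels: Sequence[bool] | np.ndarray,
) -> ThresholdCalibration:
    """Optimal symmetric/asymmetric 3S cut-off from labeled samples.

    Sweeps the midpoints between consecutive sorted unique scores.  At each
    candidate threshold, specificity is the fraction of (video-)symmetric
    gaits scored at or above it, and sensitivity the fraction of asymmetric
    gaits scored below it; the returned threshold is where the two curves
    cross (their absolute difference is minimal, ties broken by accuracy).
    Depends only on score ranks, so any strictly monotone rescoring leaves
    the classification unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(symmetric_labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("both symmetric and asymmetric samples are required")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("scores are constant; no threshold exists")
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    sym = scores[labels]
    asym = scores[~labels]
    spec = np.array([(sym >= c).mean() for c in cands])
    sens = np.array([(asym < c).mean() for c in cands])
    acc = np.array(
        [((sym >= c).sum() + (asym < c).sum()) / scores.size for c in cands]
    )
    gap = np.abs(spec - sens)
    # with discrete scores the curves cross between candidates; any
    # candidate near the minimal gap is "the intersection", so take the
    # most accurate one in that neighborhood (ties: the first, lowest)
    best = np.flatnonzero(gap <= gap.min() + 0.02)
    j = best[np.argmax(acc[best])]
    return ThresholdCalibration(
        threshold=float(cands[j]),
        thresholds=cands,
        specificity_curve=spec,
        sensitivity_curve=sens,
        accuracy_at_threshold=float(acc[j]),
    )


def tdiff_regression(
    s3_values: Sequence[float] | np.ndarray,
    t_diff_values: Sequence[float] | np.ndarray,
) -> TdiffRegression:
    """Least-squares line and Pearson r of 3S against T_diff."""
    s3 = np.asarray(s3_values, dtype=float)
    td = np.asarray(t_diff_values, dtype=float)
    if s3.size != td.size:
        raise ValueError("3S and T_diff arrays must align")
    if s3.size < 10:
        raise ValueError("need at least 10 paired samples")
    if np.ptp(td) == 0 or np.ptp(s3) == 0:
        raise ValueError("zero variance in 3S or T_diff")
    fit = linregress(td, s3)
    return TdiffRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        s3_at_tdiff_zero=float(fit.intercept),
    )


def continuum_summary(
    samples: Sequence[GaitSample],
    bin_width: float = 0.05,
    fit_regions: bool = False,
) -> ContinuumSummary:
    """Speed histogram, symmetric fractions per bin, candidate boundaries.

    Local minima of the occupancy histogram mark candidate boundaries
    between gait regions (speeds mice avoid, analogous to gait transition
    speeds).  With ``fit_regions``, 3S is regressed on speed separately in
    the regions delimited by the first two boundaries.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not samples:
        raise ValueError("no samples")
    speeds = np.array([s.speed for s in samples])
    calls = np.array([bool(s.symmetric_call) for s in samples])
    lo = np.floor(speeds.min() / bin_width) * bin_width
    hi = np.ceil(speeds.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(speeds, bins=edges)
    prop = np.full(counts.size, np.nan)
    which = np.clip(np.digitize(speeds, edges) - 1, 0, counts.size - 1)
    for b in range(counts.size):
        sel = which == b
        if sel.any():
            prop[b] = calls[sel].mean()
    # interior local minima of the occupancy histogram
    boundaries = []
    for b in range(1, counts.size - 1):
        if counts[b] < counts[b - 1] and counts[b] < counts[b + 1]:
            boundaries.append(float(0.5 * (edges[b] + edges[b + 1])))
    fits: tuple[dict, ...] = ()
    if fit_regions and len(boundaries) >= 2:
        b1, b2 = boundaries[0], boundaries[1]
        region_masks = [speeds < b1, (speeds >= b1) & (speeds < b2), speeds >= b2]
        region_fits = []
        s3 = np.array([s.s3 for s in samples])
        for mask in region_masks:
            if mask.sum() >= 3 and np.ptp(speeds[mask]) > 0:
                f = linregress(speeds[mask], s3[mask])
                region_fits.append(
                    {"n": int(mask.sum()), "slope": float(f.slope),
                     "intercept": float(f.intercept), "r": float(f.rvalue)}
                )
            else:
                region_fits.append({"n": int(mask.sum())})
        fits = tuple(region_fits)
    return ContinuumSummary(
        bin_edges=edges,
        counts=counts,
        proportion_symmetric=prop,
        boundary_speeds=tuple(boundaries),
        region_fits=fits,
    )
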