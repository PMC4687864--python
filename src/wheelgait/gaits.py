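"""Footfall timing, gait labels, Hildebrand phase statistics, and Froude scaling.

A quadruped stride is described by the phase (fraction of the stride period)
at which each limb touches down and the fraction of the stride each limb
spends on the ground (its duty factor).  From these, Hildebrand-style phase
differences between limb pairs are computed:

* ``F``  — fore pair (LF vs RF)
* ``R``  — hind pair (LH vs RH)
* ``D1`` — diagonal pair LF/RH
* ``D2`` — diagonal pair RF/LH

Each is a circular phase distance folded into [0, 0.5].  A symmetric gait
(walk, trot) has pair members half a stride apart (F, R near 0.5); an
asymmetric gait (gallop, half-bound) has a pair landing near-simultaneously.
The scalar ``t_diff = R - max(D1, D2)`` is positive for trot-like timing and
negative for bound-like timing.

Dynamic similarity across body sizes is captured by the Froude number
``Fr = V^2 / (g L)`` with ``L`` a characteristic leg (hip) length; quadrupeds
typically switch from walking to trotting between Fr 0.5 and 1.0 and from
trotting to galloping near Fr 1.8.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "LIMBS",
    "PAIRS",
    "GaitTimings",
    "GaitLabel",
    "FroudeModel",
    "phase_differences",
    "t_diff",
    "label_gait",
    "froude_number",
    "predict_transition_speeds",
    "canonical_gait",
    "CANONICAL_GAITS",
    "save_gait_library",
    "load_gait_library",
]

#: Limb identifiers: left/right fore, left/right hind.
LIMBS = ("LF", "RF", "LH", "RH")

#: Named limb pairs used in Hildebrand phase statistics.
PAIRS = {
    "F": ("LF", "RF"),
    "R": ("LH", "RH"),
    "D1": ("LF", "RH"),
    "D2": ("RF", "LH"),
}

GRAVITY = 9.81  # m/s^2


def _circular_distance(a: float, b: float) -> float:
    """Circular distance between two phases in [0, 1), folded into [0, 0.5]."""
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


@dataclass(frozen=True)
class GaitTimings:
    """Hildebrand description of one stride.

    Parameters
    ----------
    contact_onset
        Touch-down phase per limb, as a fraction of the stride in [0, 1).
        Phases are conventionally anchored so the first hind contact is at 0,
        but only pairwise differences matter downstream.
    stance_fraction
        Per-limb duty factor in (0, 1).
    stride_period
        Stride duration in seconds (> 0).
    """

    contact_onset: Mapping[str, float]
    stance_fraction: Mapping[str, float]
    stride_period: float

    def __post_init__(self) -> None:
        for limb in LIMBS:
            if limb not in self.contact_onset:
                raise ValueError(f"missing contact onset for limb {limb!r}")
            if limb not in self.stance_fraction:
                raise ValueError(f"missing stance fraction for limb {limb!r}")
        for limb, phase in self.contact_onset.items():
            if not 0.0 <= phase < 1.0:
                raise ValueError(f"contact phase for {limb} must lie in [0, 1), got {phase}")
        for limb, sf in self.stance_fraction.items():
            if not 0.0 < sf < 1.0:
                raise ValueError(f"stance fraction for {limb} must lie in (0, 1), got {sf}")
        if self.stride_period <= 0:
            raise ValueError(f"stride period must be positive, got {self.stride_period}")

    def onset_times(self) -> dict[str, float]:
        """Contact onsets in seconds from stride start."""
        return {limb: self.contact_onset[limb] * self.stride_period for limb in LIMBS}

    def to_dict(self) -> dict:
        return {
            "contact_onset": dict(self.contact_onset),
            "stance_fraction": dict(self.stance_fraction),
            "stride_period": self.stride_period,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaitTimings":
        return cls(
            contact_onset=dict(d["contact_onset"]),
            stance_fraction=dict(d["stance_fraction"]),
            stride_period=float(d["stride_period"]),
        )


@dataclass(frozen=True)
class GaitLabel:
    """A categorical gait call with its Hildebrand symmetry flag."""

    category: str  # one of creep, trot, gallop, half_bound
    symmetric: bool = field(default=None)  # type: ignore[assignment]

    # Hildebrand symmetry requires pair footfalls evenly spaced in time; a
    # trot qualifies, gallops and half-bounds do not, and neither does
    # creeping — an intermittent, irregularly timed exploratory gait.
    _SYMMETRIC = {"creep": False, "trot": True, "gallop": False, "half_bound": False}

    def __post_init__(self) -> None:
        if self.category not in self._SYMMETRIC:
            raise ValueError(f"unknown gait category {self.category!r}")
        expected = self._SYMMETRIC[self.category]
        if self.symmetric is None:
            object.__setattr__(self, "symmetric", expected)
        elif self.category in ("trot", "gallop", "half_bound") and self.symmetric is not expected:
            raise ValueError(
                f"{self.category} must have symmetric={expected}, got {self.symmetric}"
            )


@dataclass(frozen=True)
class FroudeModel:
    """Dynamic-similarity model for gait transition speeds.

    ``leg_length`` is the hip height in meters (2.6 cm for a typical adult
    mouse).  The transition Froude numbers follow the cross-species pattern:
    the walk-trot transition falls between Fr 0.5 and 1.0 and the trot-gallop
    transition near Fr 1.8.
    """

    leg_length: float = 0.026
    gravity: float = GRAVITY
    walk_trot_low_fr: float = 0.5
    walk_trot_high_fr: float = 1.0
    trot_gallop_fr: float = 1.8

    def __post_init__(self) -> None:
        if self.leg_length <= 0:
            raise ValueError("leg length must be positive")
        frs = (self.walk_trot_low_fr, self.walk_trot_high_fr, self.trot_gallop_fr)
        if not all(f > 0 for f in frs) or not frs[0] <= frs[1] <= frs[2]:
            raise ValueError("transition Froude numbers must be positive and ordered")


def phase_differences(timings: GaitTimings) -> dict[str, float]:
    """Hildebrand pairwise phase differences F, R, D1, D2.

    Each value is the circular distance between the contact phases of the two
    limbs of the pair, folded into [0, 0.5] stride fractions.
    """
    onset = timings.contact_onset
    return {
        name: _circular_distance(onset[a], onset[b]) for name, (a, b) in PAIRS.items()
    }


def t_diff(timings: GaitTimings) -> float:
    """Timing contrast ``R - max(D1, D2)`` in stride fractions, in [-0.5, 0.5].

    Positive for trot-like timing (hind pair out of phase, diagonals in
    phase); negative for bound-like timing (hind pair synchronized).
    """
    pd = phase_differences(timings)
    return pd["R"] - max(pd["D1"], pd["D2"])


def label_gait(
    contact_onsets: Mapping[str, float],
    stride_period: float,
    *,
    hind_sync_s: float = 0.025,
    creep_tolerance: float = 0.10,
) -> GaitLabel:
    """Rule-based categorical gait call from per-limb contact times.

    The rule hierarchy mirrors standard video-based classification:

    * *creep* when the smallest diagonal-pair timing difference and the
      smallest fore/hind-pair difference are similar (within
      ``creep_tolerance`` of the stride period);
    * *trot* when the smallest pairwise timing difference is between a
      diagonal pair of legs;
    * otherwise *half_bound* when the hind feet touch down within
      ``hind_sync_s`` seconds of each other (default 0.025 s), else *gallop*.

    Parameters
    ----------
    contact_onsets
        One touch-down time in seconds per limb, all within one stride.
    stride_period
        Stride duration in seconds.
    """
    if stride_period <= 0:
        raise ValueError(f"stride period must be positive, got {stride_period}")
    for limb in LIMBS:
        if limb not in contact_onsets:
            raise ValueError(f"missing contact onset for limb {limb!r}")

    def circ_dt(a: str, b: str) -> float:
        d = abs(contact_onsets[a] - contact_onsets[b]) % stride_period
        return min(d, stride_period - d)

    diag = min(circ_dt("LF", "RH"), circ_dt("RF", "LH"))
    fore = circ_dt("LF", "RF")
    hind = circ_dt("LH", "RH")
    lateral = min(fore, hind)

    if abs(diag - lateral) <= creep_tolerance * stride_period:
        return GaitLabel("creep")
    if diag < lateral:
        return GaitLabel("trot")
    if hind < hind_sync_s:
        return GaitLabel("half_bound")
    return GaitLabel("gallop")


def froude_number(speed: float, model: FroudeModel) -> float:
    """Dimensionless Froude number ``V^2 / (g L)``."""
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return speed**2 / (model.gravity * model.leg_length)


def predict_transition_speeds(model: FroudeModel) -> dict[str, float]:
    """Gait-transition speeds ``V = sqrt(Fr g L)`` in m/s.

    Returns the walk-trot transition band (low/high) and the trot-gallop
    transition speed.  For a mouse hip height of 2.6 cm these are 0.36, 0.51
    and 0.68 m/s.
    """
    gl = model.gravity * model.leg_length
    return {
        "walk_trot_low": math.sqrt(model.walk_trot_low_fr * gl),
        "walk_trot_high": math.sqrt(model.walk_trot_high_fr * gl),
        "trot_gallop": math.sqrt(model.trot_gallop_fr * gl),
    }


# ---------------------------------------------------------------------------
# Canonical (idealized) gait library
# ---------------------------------------------------------------------------

def canonical_gait(
    category: str,
    stride_period: float = 0.143,
    duty_factor: float = 0.4,
    fore_hind_duty_split: float = 0.9,
) -> GaitTimings:
    """Idealized footfall timings for a named gait category.

    These are textbook idealizations, anchored at first hind contact:

    * *trot* — diagonal pairs synchronous, pairs half a stride apart.
    * *half_bound* — hind pair synchronous, fore feet landing separately.
    * *gallop* — all four footfalls staggered, hind pair clearly apart.
    * *creep* — slow lateral-couplet walk (each fore foot follows the
      ipsilateral hind closely) with a high duty factor.
    """
    phases = {
        "trot": {"LH": 0.0, "RF": 0.0, "RH": 0.5, "LF": 0.5},
        "half_bound": {"LH": 0.0, "RH": 0.0, "RF": 0.55, "LF": 0.75},
        "gallop": {"LH": 0.0, "RH": 0.22, "RF": 0.42, "LF": 0.62},
        "creep": {"LH": 0.0, "LF": 0.08, "RH": 0.5, "RF": 0.58},
    }
    if category not in phases:
        raise ValueError(f"unknown gait category {category!r}")
    df = duty_factor if category != "creep" else max(duty_factor, 0.6)
    # fore stances are shorter than hind stances in mice; the split scales
    # fore duty by the given factor and hind by its complement about the mean
    df_fore = min(df * fore_hind_duty_split, 0.95)
    df_hind = min(df * (2.0 - fore_hind_duty_split), 0.95)
    return GaitTimings(
        contact_onset=phases[category],
        stance_fraction={
            "LF": df_fore, "RF": df_fore, "LH": df_hind, "RH": df_hind
        },
        stride_period=stride_period,
    )


CANONICAL_GAITS = ("creep", "trot", "gallop", "half_bound")


def save_gait_library(path: str | Path, gaits: Mapping[str, GaitTimings]) -> None:
    """Serialize a named gait library to JSON."""
    payload = {name: g.to_dict() for name, g in gaits.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_gait_library(path: str | Path) -> dict[str, GaitTimings]:
    payload = json.loads(Path(path).read_text())
    return {name: GaitTimings.from_dict(d) for name, d in payload.items()}
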