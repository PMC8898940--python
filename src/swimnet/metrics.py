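"""Stroke kinematics, somatic maturity offset, and seasonal change scores.

The kinematic chain is computed from stopwatch measurements of a 25-m
all-out swim: mid-pool speed from the intermediate 10 m, stroke rate from
the time of three consecutive stroke cycles, and from those stroke length
(distance per cycle) and stroke index (speed x stroke length, an indirect
efficiency measure).

Somatic maturation is summarized by the Mirwald maturity offset: the
predicted number of years from age at peak height velocity (PHV), from a
sex-specific regression on age, sitting height, leg length (stature minus
sitting height) and the mass-to-stature ratio. A negative offset means the
swimmer has not yet reached PHV.

Seasonal change is expressed per variable as a relative percent change,
100*(after - before)/before.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

from .errors import (
    InvalidAnthropometricsError,
    InvalidMeasurementError,
    PairingError,
    UndefinedChangeError,
)

TECHNIQUES = ("BREAST", "FLY")

#: Order of the change-score variables in every downstream table/matrix
#: (gender is prepended as a dichotomous node when the network is built).
CHANGE_VARIABLES = (
    "age",
    "height",
    "arm_span",
    "body_mass",
    "T25",
    "v",
    "SR",
    "SL",
    "SI",
    "MO",
)

#: gender coding used throughout: 1 = girls, 2 = boys
GENDER_CODE = {"F": 1, "M": 2}


@dataclass(frozen=True)
class TrialTiming:
    """Stopwatch readings of one 25-m all-out trial.

    t25: total 25-m time (s); t10: intermediate 10-m time (s);
    t3cycles: time of three consecutive stroke cycles (s).
    """

    t25: float
    t10: float
    t3cycles: float

    def __post_init__(self):
        for name in ("t25", "t10", "t3cycles"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidMeasurementError(f"{name} must be positive, got {v!r}")
        if not self.t10 < self.t25:
            raise InvalidMeasurementError(
                f"intermediate 10-m time ({self.t10}) must be below the 25-m time ({self.t25})"
            )


@dataclass(frozen=True)
class SwimmerSession:
    """One swimmer measured at one time point (before or after the season)."""

    swimmer_id: str
    sex: str  # "F" or "M"
    age: float  # decimal years, consumed as given
    height: float  # cm
    sitting_height: float  # cm
    arm_span: float  # cm
    body_mass: float  # kg
    trials: Mapping[str, TrialTiming] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in GENDER_CODE:
            raise InvalidAnthropometricsError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("age", "height", "sitting_height", "arm_span", "body_mass"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidAnthropometricsError(f"{name} must be positive, got {v!r}")
        if not self.sitting_height < self.height:
            raise InvalidAnthropometricsError(
                f"sitting height ({self.sitting_height}) must be below stature ({self.height})"
            )
        for tech in self.trials:
            if tech not in TECHNIQUES:
                raise InvalidMeasurementError(f"unknown technique {tech!r}")

    @property
    def gender_code(self) -> int:
        return GENDER_CODE[self.sex]


@dataclass(frozen=True)
class KinematicSummary:
    """Derived kinematics of one trial.

    v: mid-pool speed (m/s); sr_cps / sr_cpm: stroke rate in cycles/s and
    cycles/min; sl: stroke length (m); si: stroke index (m^2/s).
    """

    v: float
    sr_cps: float
    sr_cpm: float
    sl: float
    si: float


@dataclass(frozen=True)
class MaturityResult:
    """Maturity offset in years (negative = before PHV) and the leg length
    (cm) used to compute it."""

    offset: float
    leg_length: float


@dataclass(frozen=True)
class ChangeVector:
    """Per-swimmer seasonal percent changes for one technique, plus the
    dichotomous gender code (1 = girls, 2 = boys)."""

    swimmer_id: str
    gender_code: int
    technique: str
    delta: Dict[str, float]  # variable name -> percent change

    def __post_init__(self):
        if self.gender_code not in (1, 2):
            raise InvalidAnthropometricsError(
                f"gender_code must be 1 (girls) or 2 (boys), got {self.gender_code}"
            )


def compute_speed(distance: float, time: float) -> float:
    """Mean swimming speed (m/s) over ``distance`` metres swum in ``time`` s."""
    if not (distance > 0) or not (time > 0):
        raise InvalidMeasurementError(
            f"distance and time must be positive, got {distance!r}, {time!r}"
        )
    return distance / time


def compute_stroke_rate(n_cycles: int, time: float) -> Tuple[float, float]:
    """Stroke rate from ``n_cycles`` strokes in ``time`` seconds.

    Returns (cycles/s, cycles/min); the per-minute value is just 60x the
    per-second value and is the one conventionally reported.
    """
    if n_cycles < 1:
        raise InvalidMeasurementError(f"n_cycles must be >= 1, got {n_cycles}")
    if not (time > 0):
        raise InvalidMeasurementError(f"time must be positive, got {time!r}")
    cps = n_cycles / time
    return cps, 60.0 * cps


def compute_kinematics(t: TrialTiming, *, distance: float = 10.0, n_cycles: int = 3) -> KinematicSummary:
    """Full kinematic chain from one trial's timings.

    v = distance/t10; SR = n_cycles/t3cycles; SL = v/SR (cycles/s);
    SI = v*SL.
    """
    v = compute_speed(distance, t.t10)
    sr_cps, sr_cpm = compute_stroke_rate(n_cycles, t.t3cycles)
    sl = v / sr_cps
    si = v * sl
    return KinematicSummary(v=v, sr_cps=sr_cps, sr_cpm=sr_cpm, sl=sl, si=si)


# Mirwald sex-specific maturity-offset regressions. The final term of each is
# the mass-to-stature ratio (kg/cm) scaled by 100.
def maturity_offset(
    sex: str, age: float, height: float, sitting_height: float, body_mass: float
) -> MaturityResult:
    """Predicted years from peak height velocity (negative = pre-PHV)."""
    for name, v in (("age", age), ("height", height), ("sitting_height", sitting_height), ("body_mass", body_mass)):
        if not (v > 0) or not math.isfinite(v):
            raise InvalidAnthropometricsError(f"{name} must be positive, got {v!r}")
    if sitting_height >= height:
        raise InvalidAnthropometricsError(
            f"sitting height ({sitting_height}) must be below stature ({height})"
        )
    ll = height - sitting_height
    mass_stature = (body_mass / height) * 100.0
    if sex == "M":
        offset = (
            -9.236
            + 0.0002708 * (ll * sitting_height)
            - 0.001663 * (age * ll)
            + 0.007216 * (age * sitting_height)
            + 0.02292 * mass_stature
        )
    elif sex == "F":
        offset = (
            -9.376
            + 0.0001882 * (ll * sitting_height)
            + 0.0022 * (age * ll)
            + 0.005847 * (age * sitting_height)
            - 0.002658 * (age * body_mass)
            + 0.07693 * mass_stature
        )
    else:
        raise InvalidAnthropometricsError(f"sex must be 'F' or 'M', got {sex!r}")
    return MaturityResult(offset=offset, leg_length=ll)


def session_maturity(session: SwimmerSession) -> MaturityResult:
    """Maturity offset of one measured session."""
    return maturity_offset(
        session.sex, session.age, session.height, session.sitting_height, session.body_mass
    )


def percent_change(before: float, after: float) -> float:
    """Relative change in percent, 100*(after - before)/before."""
    if before == 0:
        raise UndefinedChangeError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def build_change_vector(before: SwimmerSession, after: SwimmerSession, technique: str) -> ChangeVector:
    """Seasonal percent changes of all ten variables for one swimmer.

    The maturity-offset change is the percent change of the offset itself;
    because the offset crosses zero around PHV this can be extreme or
    sign-flipped, which is retained deliberately (no winsorization).
    """
    if before.swimmer_id != after.swimmer_id:
        raise PairingError(
            f"session ids differ: {before.swimmer_id!r} vs {after.swimmer_id!r}"
        )
    if technique not in TECHNIQUES:
        raise PairingError(f"unknown technique {technique!r}")
    for s, label in ((before, "before"), (after, "after")):
        if technique not in s.trials:
            raise PairingError(
                f"swimmer {s.swimmer_id!r} has no {technique} trial in the {label} session"
            )

    kb = compute_kinematics(before.trials[technique])
    ka = compute_kinematics(after.trials[technique])
    mb = session_maturity(before)
    ma = session_maturity(after)

    delta = {
        "age": percent_change(before.age, after.age),
        "height": percent_change(before.height, after.height),
        "arm_span": percent_change(before.arm_span, after.arm_span),
        "body_mass": percent_change(before.body_mass, after.body_mass),
        "T25": percent_change(before.trials[technique].t25, after.trials[technique].t25),
        "v": percent_change(kb.v, ka.v),
        "SR": percent_change(kb.sr_cpm, ka.sr_cpm),
        "SL": percent_change(kb.sl, ka.sl),
        "SI": percent_change(kb.si, ka.si),
        "MO": percent_change(mb.offset, ma.offset),
    }
    return ChangeVector(
        swimmer_id=before.swimmer_id,
        gender_code=before.gender_code,
        technique=technique,
        delta=delta,
    )
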