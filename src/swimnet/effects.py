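"""Paired-comparison statistics for the seasonal summary table.

For each variable the cohort is described by before/after mean +/- SD with
95% confidence intervals, a paired t-test, a standardized mean difference
(Hedges' g with the mean-of-variances pooled SD and no small-sample
correction — the variant that reproduces the published table), its Hopkins
magnitude label, and the mean +/- SD of the individual percent changes.

Normality (Shapiro–Wilk) is checked but only logged: the analysis proceeds
with t-tests for every variable regardless.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientSampleError
from .metrics import (
    SwimmerSession,
    build_change_vector,
    compute_kinematics,
    session_maturity,
)

logger = logging.getLogger(__name__)

#: Hopkins magnitude bands, lower-edge inclusive.
MAGNITUDE_BANDS = (
    (0.0, "trivial"),
    (0.2, "small"),
    (0.6, "moderate"),
    (1.2, "large"),
    (2.0, "very large"),
    (4.0, "nearly perfect"),
)


@dataclass(frozen=True)
class EffectSizeRow:
    """One row of the seasonal summary table."""

    variable: str
    technique: Optional[str]
    mean_before: float
    sd_before: float
    ci95_before: Tuple[float, float]
    mean_after: float
    sd_after: float
    ci95_after: Tuple[float, float]
    p_value: float
    g: float
    magnitude_label: str
    delta_mean: float
    delta_sd: float


def shapiro_wilk_gate(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro–Wilk W and p; advisory only (a warning is logged on p < .05)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise InsufficientSampleError(f"Shapiro–Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro–Wilk undefined for a constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(x)
    if p < 0.05:
        logger.warning("Shapiro–Wilk suggests non-normality (W=%.4f, p=%.4g)", w, p)
    return float(w), float(p)


def paired_t_test(before: Sequence[float], after: Sequence[float]) -> Tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise InsufficientSampleError("before/after must have equal length")
    n = b.size
    if n < 2:
        raise InsufficientSampleError(f"paired t-test needs n >= 2, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def hedges_g(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference |mean2 - mean1| / sqrt((sd1^2 + sd2^2)/2).

    Pooled SD is the root mean of the two variances; no small-sample
    correction is applied.
    """
    if sd1 < 0 or sd2 < 0:
        raise DegenerateInputError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both standard deviations are zero")
    return abs(mean2 - mean1) / math.sqrt((sd1 * sd1 + sd2 * sd2) / 2.0)


def classify_effect(g: float) -> str:
    """Hopkins magnitude label for a non-negative effect size."""
    if g < 0 or not math.isfinite(g):
        raise DegenerateInputError(f"effect size must be non-negative and finite, got {g}")
    label = MAGNITUDE_BANDS[0][1]
    for lower, name in MAGNITUDE_BANDS:
        if g >= lower:
            label = name
    return label


def ci95(sample: Sequence[float]) -> Tuple[float, float]:
    """Two-sided 95% CI of the mean: mean +/- t_{.975, n-1} * sd / sqrt(n)."""
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientSampleError(f"ci95 needs n >= 2, got {n}")
    m = x.mean()
    half = stats.t.ppf(0.975, n - 1) * x.std(ddof=1) / math.sqrt(n)
    return float(m - half), float(m + half)


def ci95_from_summary(mean: float, sd: float, n: int) -> Tuple[float, float]:
    """95% CI of the mean from summary statistics (same t quantile as ci95)."""
    if n < 2:
        raise InsufficientSampleError(f"ci95 needs n >= 2, got {n}")
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return float(mean - half), float(mean + half)


def _row(
    variable: str,
    technique: Optional[str],
    before: np.ndarray,
    after: np.ndarray,
    deltas: np.ndarray,
) -> EffectSizeRow:
    mb, sb = before.mean(), before.std(ddof=1)
    ma, sa = after.mean(), after.std(ddof=1)
    try:
        shapiro_wilk_gate(after - before)
    except DegenerateInputError:
        logger.warning("%s: constant paired differences; normality gate skipped", variable)
    try:
        _, _, p = paired_t_test(before, after)
    except DegenerateInputError:
        p = float("nan")
    try:
        g = hedges_g(mb, sb, ma, sa)
    except DegenerateInputError:
        g = 0.0
    return EffectSizeRow(
        variable=variable,
        technique=technique,
        mean_before=float(mb),
        sd_before=float(sb),
        ci95_before=ci95(before),
        mean_after=float(ma),
        sd_after=float(sa),
        ci95_after=ci95(after),
        p_value=float(p),
        g=float(g),
        magnitude_label=classify_effect(g),
        delta_mean=float(deltas.mean()),
        delta_sd=float(deltas.std(ddof=1)),
    )


def summarize_cohort(
    pairs: Sequence[Tuple[SwimmerSession, SwimmerSession]],
    techniques: Sequence[str] = ("BREAST", "FLY"),
) -> List[EffectSizeRow]:
    """Seasonal summary table: anthropometric/maturation rows followed by the
    per-technique kinematic rows.

    ``pairs`` is a sequence of (before, after) sessions, one per swimmer.
    Delta columns are mean/SD of the individual percent changes.
    """
    if len(pairs) < 2:
        raise InsufficientSampleError(
            f"cohort summary needs at least 2 paired swimmers, got {len(pairs)}"
        )

    rows: List[EffectSizeRow] = []

    def col(getter):
        b = np.array([getter(p[0]) for p in pairs], dtype=float)
        a = np.array([getter(p[1]) for p in pairs], dtype=float)
        return b, a

    anthro = {
        "age": lambda s: s.age,
        "height": lambda s: s.height,
        "arm_span": lambda s: s.arm_span,
        "body_mass": lambda s: s.body_mass,
        "MO": lambda s: session_maturity(s).offset,
    }
    for var, getter in anthro.items():
        b, a = col(getter)
        with np.errstate(divide="ignore"):
            deltas = 100.0 * (a - b) / b
        rows.append(_row(var, None, b, a, deltas))

    for tech in techniques:
        changes = [build_change_vector(b, a, tech) for b, a in pairs]
        getters = {
            "T25": lambda s, t=tech: s.trials[t].t25,
            "v": lambda s, t=tech: compute_kinematics(s.trials[t]).v,
            "SR": lambda s, t=tech: compute_kinematics(s.trials[t]).sr_cpm,
            "SL": lambda s, t=tech: compute_kinematics(s.trials[t]).sl,
            "SI": lambda s, t=tech: compute_kinematics(s.trials[t]).si,
        }
        for var, getter in getters.items():
            b, a = col(getter)
            deltas = np.array([c.delta[var] for c in changes], dtype=float)
            rows.append(_row(var, tech, b, a, deltas))

    return rows
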