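"""Published summary statistics of the 47-week age-group swimming season.

These are the group-level targets the synthetic cohort emulates and the
inputs to the effect-size reproduction checks: before/after mean +/- SD per
variable, and the mean +/- SD of the individual relative changes (Delta %).
Kinematic rows are per technique (BREAST = breaststroke, FLY = butterfly);
anthropometric rows are pooled over the whole cohort (n = 20: 11 girls,
9 boys).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

N_GIRLS = 11
N_BOYS = 9
N_SWIMMERS = N_GIRLS + N_BOYS

#: decimal age at the first session, by sex: (mean, SD) in years
AGE_BEFORE = {"F": (10.0, 1.3), "M": (10.5, 0.9)}

SEASON_WEEKS = 47


@dataclass(frozen=True)
class SummaryRow:
    """Before/after group summary of one variable.

    ``technique`` is None for anthropometrics/maturation (single cohort-wide
    row); mean/SD units are the variable's natural units; delta is the
    mean/SD of the individual percent changes.
    """

    variable: str
    technique: Optional[str]
    before: Tuple[float, float]  # (mean, sd)
    after: Tuple[float, float]
    delta: Tuple[float, float]  # (mean %, sd %)


#: Cohort-wide seasonal summary (the generator's default targets).
SEASON_SUMMARY = (
    SummaryRow("age", None, (10.2, 1.2), (11.1, 1.2), (8.9, 1.3)),
    SummaryRow("height", None, (142.3, 9.7), (147.8, 9.5), (3.8, 1.4)),
    SummaryRow("arm_span", None, (143.6, 10.4), (150.8, 11.3), (4.9, 1.8)),
    SummaryRow("body_mass", None, (36.7, 8.2), (41.4, 8.5), (12.1, 6.7)),
    SummaryRow("MO", None, (-2.0, 0.9), (-1.3, 1.0), (50.9, 281.0)),
    SummaryRow("T25", "BREAST", (32.0, 7.5), (24.5, 3.8), (-21.9, 9.5)),
    SummaryRow("T25", "FLY", (30.3, 7.0), (21.8, 3.6), (-26.5, 11.0)),
    SummaryRow("v", "BREAST", (0.71, 0.12), (0.90, 0.12), (28.5, 19.7)),
    SummaryRow("v", "FLY", (0.76, 0.18), (1.05, 0.16), (41.0, 25.3)),
    SummaryRow("SR", "BREAST", (45.9, 11.9), (58.6, 8.6), (26.7, 44.1)),
    SummaryRow("SR", "FLY", (37.1, 9.7), (45.6, 11.8), (16.3, 23.0)),
    SummaryRow("SL", "BREAST", (0.96, 0.23), (0.93, 0.13), (2.2, 26.1)),
    SummaryRow("SL", "FLY", (1.30, 0.38), (1.43, 0.25), (16.7, 32.5)),
    SummaryRow("SI", "BREAST", (0.69, 0.24), (0.84, 0.20), (31.9, 49.2)),
    SummaryRow("SI", "FLY", (1.04, 0.41), (1.50, 0.35), (66.8, 77.4)),
)


def summary_row(variable: str, technique: Optional[str] = None) -> SummaryRow:
    """Look up one summary row by variable (and technique for kinematics)."""
    for row in SEASON_SUMMARY:
        if row.variable == variable and row.technique == technique:
            return row
    raise KeyError(f"no summary row for {variable!r} / {technique!r}")
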