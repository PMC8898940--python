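"""Reading and writing the cohort CSV.

One row per swimmer per session. Required columns: swimmer_id, session
(before/after), sex (F/M), age_y, height_cm, sitting_height_cm, arm_span_cm,
body_mass_kg, and per technique the trial timings breast_t25_s, breast_t10_s,
breast_t3cycles_s, fly_t25_s, fly_t10_s, fly_t3cycles_s.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .errors import PairingError, SchemaError
from .metrics import SwimmerSession, TrialTiming

SESSIONS = ("before", "after")

BASE_COLUMNS = [
    "swimmer_id",
    "session",
    "sex",
    "age_y",
    "height_cm",
    "sitting_height_cm",
    "arm_span_cm",
    "body_mass_kg",
]

TRIAL_COLUMNS = {
    "BREAST": ["breast_t25_s", "breast_t10_s", "breast_t3cycles_s"],
    "FLY": ["fly_t25_s", "fly_t10_s", "fly_t3cycles_s"],
}

ALL_COLUMNS = BASE_COLUMNS + TRIAL_COLUMNS["BREAST"] + TRIAL_COLUMNS["FLY"]


def read_table(path) -> pd.DataFrame:
    """Read the raw cohort table, checking the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return df


def _session_from_row(row: pd.Series) -> SwimmerSession:
    trials = {}
    for tech, cols in TRIAL_COLUMNS.items():
        t25, t10, t3 = (row[c] for c in cols)
        if pd.notna(t25) and pd.notna(t10) and pd.notna(t3):
            trials[tech] = TrialTiming(t25=float(t25), t10=float(t10), t3cycles=float(t3))
    return SwimmerSession(
        swimmer_id=str(row["swimmer_id"]),
        sex=str(row["sex"]),
        age=float(row["age_y"]),
        height=float(row["height_cm"]),
        sitting_height=float(row["sitting_height_cm"]),
        arm_span=float(row["arm_span_cm"]),
        body_mass=float(row["body_mass_kg"]),
        trials=trials,
    )


def read_sessions(path) -> List[Tuple[SwimmerSession, SwimmerSession]]:
    """Read the cohort CSV into paired (before, after) sessions.

    Raises a pairing error listing every swimmer lacking one of the two
    sessions.
    """
    df = read_table(path)
    by_swimmer: Dict[str, Dict[str, SwimmerSession]] = {}
    for _, row in df.iterrows():
        session = str(row["session"])
        if session not in SESSIONS:
            raise SchemaError(f"session must be one of {SESSIONS}, got {session!r}")
        sid = str(row["swimmer_id"])
        slot = by_swimmer.setdefault(sid, {})
        if session in slot:
            raise PairingError(f"duplicate row for swimmer {sid!r}, session {session!r}")
        slot[session] = _session_from_row(row)
    unpaired = sorted(sid for sid, s in by_swimmer.items() if len(s) != 2)
    if unpaired:
        raise PairingError(f"swimmer(s) without both sessions: {', '.join(unpaired)}")
    return [
        (by_swimmer[sid]["before"], by_swimmer[sid]["after"])
        for sid in sorted(by_swimmer)
    ]


def sessions_to_frame(
    pairs: Sequence[Tuple[SwimmerSession, SwimmerSession]]
) -> pd.DataFrame:
    rows = []
    for before, after in pairs:
        for session, s in (("before", before), ("after", after)):
            row = {
                "swimmer_id": s.swimmer_id,
                "session": session,
                "sex": s.sex,
                "age_y": s.age,
                "height_cm": s.height,
                "sitting_height_cm": s.sitting_height,
                "arm_span_cm": s.arm_span,
                "body_mass_kg": s.body_mass,
            }
            for tech, cols in TRIAL_COLUMNS.items():
                t = s.trials.get(tech)
                row[cols[0]] = t.t25 if t else float("nan")
                row[cols[1]] = t.t10 if t else float("nan")
                row[cols[2]] = t.t3cycles if t else float("nan")
            rows.append(row)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def write_sessions(pairs, path) -> None:
    """Write paired sessions back to the standard cohort CSV."""
    sessions_to_frame(pairs).to_csv(path, index=False, float_format="%.12g")
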