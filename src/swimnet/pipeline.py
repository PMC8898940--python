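"""End-to-end orchestration: input validation, the full analysis run, and
report writing.

A run reads the paired cohort CSV and writes, per technique: the seasonal
effect-size table, the EBIC-selected partial-correlation weight matrix
(display and full precision), the edge list, the centrality table (z-scores
plus raw companion), the EBIC trace, optional GraphML, and a log/summary
carrying the selected penalty, edge count, EBIC, seed and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .centrality import write_centrality, zscore_table
from .effects import EffectSizeRow, summarize_cohort
from .errors import SchemaError
from .io import ALL_COLUMNS, TRIAL_COLUMNS, read_sessions, read_table
from .metrics import TECHNIQUES, build_change_vector
from .network import (
    CohortChangeMatrix,
    select_network,
    write_ebic_trace,
    write_edge_list,
    write_graphml,
    write_weight_matrix,
    write_weight_matrix_full,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str
    output_dir: str
    techniques: Sequence[str] = TECHNIQUES
    gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    seed: int = 2022
    report_decimals: int = 2
    write_graphml: bool = True

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file; kwargs override keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def validate_input(path) -> List[str]:
    """Schema and plausibility checks; returns violations without aborting.

    Checks: required columns, session/sex values, duplicate (swimmer,
    session) rows, unpaired swimmers, positive measurements, sitting height
    below stature, and t10 below t25 for each recorded trial.
    """
    violations: List[str] = []
    try:
        df = read_table(path)
    except SchemaError as exc:
        return [str(exc)]

    seen = set()
    for i, row in df.iterrows():
        where = f"row {i + 2}"  # 1-based with header line
        sid, session = row["swimmer_id"], row["session"]
        if session not in ("before", "after"):
            violations.append(f"{where}: session must be before/after, got {session!r}")
        if row["sex"] not in ("F", "M"):
            violations.append(f"{where}: sex must be F/M, got {row['sex']!r}")
        key = (sid, session)
        if key in seen:
            violations.append(f"{where}: duplicate (swimmer, session) {key}")
        seen.add(key)
        for col in ("age_y", "height_cm", "sitting_height_cm", "arm_span_cm", "body_mass_kg"):
            if not row[col] > 0:
                violations.append(f"{where}: {col} must be positive, got {row[col]}")
        if row["sitting_height_cm"] >= row["height_cm"]:
            violations.append(
                f"{where}: sitting_height_cm ({row['sitting_height_cm']}) must be "
                f"below height_cm ({row['height_cm']})"
            )
        for tech, cols in TRIAL_COLUMNS.items():
            vals = [row[c] for c in cols]
            if all(pd.notna(v) for v in vals):
                t25, t10, _t3 = vals
                for c, v in zip(cols, vals):
                    if not v > 0:
                        violations.append(f"{where}: {c} must be positive, got {v}")
                if t10 >= t25:
                    violations.append(
                        f"{where}: {cols[1]} ({t10}) must be below {cols[0]} ({t25})"
                    )
    counts: Dict[str, int] = {}
    for sid, _ in seen:
        counts[sid] = counts.get(sid, 0) + 1
    for sid in sorted(k for k, v in counts.items() if v != 2):
        violations.append(f"swimmer {sid!r} does not have exactly one before and one after session")
    return violations


def effect_rows_to_frame(rows: Sequence[EffectSizeRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "technique": [r.technique or "" for r in rows],
            "mean_before": [r.mean_before for r in rows],
            "sd_before": [r.sd_before for r in rows],
            "ci95_before_lo": [r.ci95_before[0] for r in rows],
            "ci95_before_hi": [r.ci95_before[1] for r in rows],
            "mean_after": [r.mean_after for r in rows],
            "sd_after": [r.sd_after for r in rows],
            "ci95_after_lo": [r.ci95_after[0] for r in rows],
            "ci95_after_hi": [r.ci95_after[1] for r in rows],
            "p_value": [r.p_value for r in rows],
            "g": [r.g for r in rows],
            "magnitude": [r.magnitude_label for r in rows],
            "delta_mean_pct": [r.delta_mean for r in rows],
            "delta_sd_pct": [r.delta_sd for r in rows],
        }
    )


def write_effect_table(rows: Sequence[EffectSizeRow], csv_path, json_path=None) -> None:
    df = effect_rows_to_frame(rows)
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if json_path is not None:
        payload = [dataclasses.asdict(r) for r in rows]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_effect_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis; returns a summary dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("swimnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "swimnet %s | numpy %s scipy %s pandas %s networkx %s | python %s",
            __version__, np.__version__, scipy.__version__,
            pd.__version__, networkx.__version__, platform.python_version(),
        )
        logger.info("config: %s", dataclasses.asdict(config))

        violations = validate_input(config.input_path)
        if violations:
            raise SchemaError("; ".join(violations))
        pairs = read_sessions(config.input_path)
        logger.info("read %d paired swimmers from %s", len(pairs), config.input_path)

        rows = summarize_cohort(pairs, config.techniques)
        write_effect_table(rows, outdir / "effect_sizes.csv", outdir / "effect_sizes.json")

        summary: Dict = {
            "config": dataclasses.asdict(config),
            "n_swimmers": len(pairs),
            "techniques": {},
        }
        for tech in config.techniques:
            changes = [build_change_vector(b, a, tech) for b, a in pairs]
            matrix = CohortChangeMatrix.from_change_vectors(changes, tech)
            network, trace = select_network(
                matrix,
                gamma=config.gamma,
                n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            prefix = tech.lower()
            write_weight_matrix(network, outdir / f"{prefix}_weight_matrix.csv",
                                decimals=config.report_decimals)
            write_weight_matrix_full(network, outdir / f"{prefix}_weight_matrix_full.csv")
            write_edge_list(network, outdir / f"{prefix}_edges.csv")
            write_ebic_trace(trace, outdir / f"{prefix}_ebic_trace.csv")
            if config.write_graphml:
                write_graphml(network, outdir / f"{prefix}_network.graphml")

            table = zscore_table(network.weights, network.nodes, network.groups)
            write_centrality(
                table,
                outdir / f"{prefix}_centrality.csv",
                outdir / f"{prefix}_centrality_raw.csv",
                decimals=config.report_decimals,
            )
            logger.info(
                "%s: selected lambda=%.6g, E=%d, EBIC=%.4f (gamma=%.2f)",
                tech, network.selected_lambda, network.n_edges,
                network.ebic_value, network.gamma,
            )
            summary["techniques"][tech] = {
                "selected_lambda": network.selected_lambda,
                "n_edges": network.n_edges,
                "ebic": network.ebic_value,
                "gamma": network.gamma,
            }

        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
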