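#!/usr/bin/env python
"""Seasonal effect-size table for the simulated cohort.

Reads results/cohort.csv (produced by 01_simulate_cohort.py), computes the
before/after summary with paired t-tests, Hedges' g, Hopkins labels and
individual Delta%, and prints the rows with large or moderate changes.
"""

from pathlib import Path

from swimnet.effects import summarize_cohort
from swimnet.io import read_sessions
from swimnet.pipeline import write_effect_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pairs = read_sessions(RESULTS / "cohort.csv")
    rows = summarize_cohort(pairs)
    write_effect_table(rows, RESULTS / "effect_sizes.csv", RESULTS / "effect_sizes.json")
    print(f"wrote {len(rows)} rows to {RESULTS / 'effect_sizes.csv'}")
    print("\nvariable (technique): g [label], mean Δ%")
    for r in sorted(rows, key=lambda r: -r.g):
        tech = f" ({r.technique})" if r.technique else ""
        print(f"  {r.variable}{tech}: g = {r.g:.2f} [{r.magnitude_label}], "
              f"Δ = {r.delta_mean:.1f} ± {r.delta_sd:.1f} %")


if __name__ == "__main__":
    main()
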