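#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws a paired before/after cohort of 20 age-group swimmers (11 girls, 9
boys) whose seasonal percent-change distributions match the published
47-week summary, and writes the standard cohort CSV plus the generating
ground truth (latent factors, targets, loadings).
"""

import json
from pathlib import Path

from swimnet.io import write_sessions
from swimnet.simulate import CohortSimConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2022


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = CohortSimConfig(seed=SEED)
    cohort = simulate_cohort(config)
    csv_path = RESULTS / "cohort.csv"
    write_sessions(list(zip(cohort.before, cohort.after)), csv_path)
    with open(RESULTS / "cohort_truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    n = config.n_girls + config.n_boys
    print(f"wrote {n} paired swimmers (seed {SEED}) to {csv_path}")
    print(f"latent maturation-tempo loadings: {config.loadings}")


if __name__ == "__main__":
    main()
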