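#!/usr/bin/env python
"""Centrality of the seasonal-change networks.

Reads the full-precision weight matrices written by 03_estimate_networks.py,
computes betweenness, closeness and strength (z-scored over all nodes), and
prints the most central changes per technique. The gender node is
standardized with the rest but excluded from interpretation (it is a fixed
dichotomy, not a seasonal change).
"""

from pathlib import Path

from swimnet.centrality import write_centrality, zscore_table
from swimnet.network import NODE_GROUPS, read_weight_matrix_full

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for tech in ("breast", "fly"):
        W, nodes = read_weight_matrix_full(RESULTS / f"{tech}_weight_matrix_full.csv")
        table = zscore_table(W, nodes, NODE_GROUPS)
        write_centrality(
            table,
            RESULTS / f"{tech}_centrality.csv",
            RESULTS / f"{tech}_centrality_raw.csv",
        )
        df = table.table.drop(index="gender")
        print(f"\n{tech.upper()} centrality (z-scores, gender excluded):")
        for measure in ("betweenness_z", "closeness_z", "strength_z"):
            col = df[measure]
            if col.max() == col.min():
                print(f"  {measure.replace('_z', '')}: constant over nodes "
                      "(disconnected network)")
                continue
            top = col.idxmax()
            print(f"  highest {measure.replace('_z', '')}: Δ{top} "
                  f"(z = {col[top]:.2f})")


if __name__ == "__main__":
    main()
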