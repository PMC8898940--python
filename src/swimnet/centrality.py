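"""Node centrality on the weighted signed partial-correlation network.

Shortest-path measures use the standard convention of the network-
psychometrics software: an edge of weight w has path length 1/|w|, so
stronger associations are shorter. Strength is the sum of absolute incident
edge weights. All three measures are reported raw and as z-scores over all
nodes (sample SD); the gender node is z-scored with the rest but flagged so
reports can mark it as not interpreted (it is a fixed dichotomy, not a
seasonal change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientSampleError

logger = logging.getLogger(__name__)

EDGE_EPS = 1e-8


@dataclass
class CentralityTable:
    """Raw and z-scored betweenness, closeness and strength per node."""

    table: pd.DataFrame  # index: node; columns: *_raw, *_z, group, excluded
    excluded: List[str]

    def to_report_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Display table: node, group, z-scores rounded for reporting."""
        out = self.table[["group", "betweenness_z", "closeness_z", "strength_z"]].copy()
        for c in ("betweenness_z", "closeness_z", "strength_z"):
            out[c] = out[c].round(decimals)
        out["excluded_from_interpretation"] = [
            n in self.excluded for n in self.table.index
        ]
        return out


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if W.shape != (p, p) or not np.allclose(W, W.T, atol=1e-8):
        raise DegenerateInputError("weight matrix must be square and symmetric")
    if np.any(np.abs(np.diag(W)) > 1e-8):
        raise DegenerateInputError("weight matrix must have a zero diagonal")
    return 0.5 * (W + W.T)


def to_distance_graph(W: np.ndarray, nodes: Optional[Sequence] = None) -> nx.Graph:
    """Graph with edge attribute ``length`` = 1/|w| for every |w| > 1e-8."""
    W = _check_weights(W)
    p = W.shape[0]
    names = list(nodes) if nodes is not None else list(range(p))
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            w = W[i, j]
            if abs(w) > EDGE_EPS:
                G.add_edge(names[i], names[j], weight=float(w), length=1.0 / abs(w))
    return G


def strength(W: np.ndarray) -> np.ndarray:
    """Per-node strength: sum of absolute incident edge weights."""
    W = _check_weights(W)
    return np.abs(W).sum(axis=1)


def closeness(W: np.ndarray) -> np.ndarray:
    """Per-node closeness: inverse of the summed shortest-path distances to
    all other nodes; zero if any node is unreachable."""
    W = _check_weights(W)
    p = W.shape[0]
    G = to_distance_graph(W)
    out = np.zeros(p)
    for i in range(p):
        dists = nx.single_source_dijkstra_path_length(G, i, weight="length")
        if len(dists) < p:
            continue  # some node unreachable
        total = sum(d for node, d in dists.items() if node != i)
        out[i] = 1.0 / total if total > 0 else 0.0
    return out


def betweenness(W: np.ndarray) -> np.ndarray:
    """Per-node betweenness: over unordered node pairs, the fraction of
    shortest paths (by 1/|w| length) passing through the node, summed;
    tied shortest paths share credit fractionally."""
    W = _check_weights(W)
    p = W.shape[0]
    G = to_distance_graph(W)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(p)])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("constant centrality column; z-scores set to zero")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def zscore_table(
    W: np.ndarray,
    nodes: Sequence[str],
    groups: Optional[Dict[str, int]] = None,
    excluded: Sequence[str] = ("gender",),
) -> CentralityTable:
    """Centrality table with z-scores standardized over all nodes.

    Nodes listed in ``excluded`` (by default the gender node) are kept in
    the standardization but flagged as not interpreted.
    """
    W = _check_weights(W)
    p = W.shape[0]
    if p < 2:
        raise InsufficientSampleError(f"need at least 2 nodes, got {p}")
    if len(nodes) != p:
        raise DegenerateInputError("node name count must match matrix size")
    b = betweenness(W)
    c = closeness(W)
    s = strength(W)
    groups = groups or {}
    df = pd.DataFrame(
        {
            "group": [groups.get(n, 0) for n in nodes],
            "betweenness_raw": b,
            "closeness_raw": c,
            "strength_raw": s,
            "betweenness_z": _zscore(b),
            "closeness_z": _zscore(c),
            "strength_z": _zscore(s),
        },
        index=pd.Index(nodes, name="node"),
    )
    return CentralityTable(table=df, excluded=[n for n in excluded if n in nodes])


def write_centrality(table: CentralityTable, path, raw_path=None, decimals: int = 2) -> None:
    """Report CSV (z-scores, rounded) and optional full-precision companion."""
    table.to_report_frame(decimals).to_csv(path)
    if raw_path is not None:
        table.table.to_csv(raw_path, float_format="%.12g")


def read_centrality(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="node")
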