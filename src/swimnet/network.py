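"""Partial-correlation network estimation over the cohort change matrix.

The input is an n x p matrix of observations: one row per swimmer, columns
being the dichotomous gender code (1 = girls, 2 = boys, treated numerically)
followed by the ten seasonal percent-change variables. The association input
is the Pearson correlation matrix; the network is the EBIC-selected
graphical-lasso fit, reported as regularized partial correlations (the
penalized estimates are reported as-is, without refitting).

Nodes carry a group attribute: 1 = gender + anthropometrics, 2 =
performance/kinematics, 3 = maturation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientSampleError
from .glasso import (
    EbicTrace,
    count_edges,
    ebic_score,
    glasso_fit,
    lambda_path,
    precision_to_partial,
)

logger = logging.getLogger(__name__)

#: network node order: gender first, then the change variables
NODE_ORDER = (
    "gender",
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

#: node group: 1 = gender + anthropometrics, 2 = performance/kinematics,
#: 3 = maturation
NODE_GROUPS: Dict[str, int] = {
    "gender": 1,
    "age": 1,
    "height": 1,
    "arm_span": 1,
    "body_mass": 1,
    "T25": 2,
    "v": 2,
    "SR": 2,
    "SL": 2,
    "SI": 2,
    "MO": 3,
}


@dataclass
class CohortChangeMatrix:
    """n x p observation matrix with named columns and a technique tag."""

    data: pd.DataFrame
    technique: Optional[str] = None

    def __post_init__(self):
        if self.data.isna().any().any():
            raise DegenerateInputError("change matrix contains missing values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def columns(self) -> List[str]:
        return list(self.data.columns)

    @classmethod
    def from_change_vectors(cls, changes: Sequence, technique: Optional[str] = None) -> "CohortChangeMatrix":
        """Assemble the network input from per-swimmer change vectors."""
        rows = []
        for c in changes:
            row = {"gender": float(c.gender_code)}
            row.update({k: float(v) for k, v in c.delta.items()})
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(NODE_ORDER))
        tech = technique if technique is not None else getattr(changes[0], "technique", None)
        return cls(data=df, technique=tech)


@dataclass
class PartialCorrelationNetwork:
    """EBIC-selected regularized partial-correlation network."""

    weights: np.ndarray  # p x p, symmetric, zero diagonal
    nodes: List[str]
    groups: Dict[str, int]
    technique: Optional[str]
    selected_lambda: float
    ebic_value: float
    gamma: float

    @property
    def n_edges(self) -> int:
        return count_edges(self.weights)

    def to_graph(self) -> nx.Graph:
        """networkx graph with weight/sign edge attributes and group node
        attribute (positive edges conventionally drawn green, negative red)."""
        G = nx.Graph()
        for name in self.nodes:
            G.add_node(name, group=self.groups.get(name, 0))
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                w = float(self.weights[i, j])
                if abs(w) > 1e-8:
                    G.add_edge(
                        self.nodes[i],
                        self.nodes[j],
                        weight=w,
                        sign="positive" if w > 0 else "negative",
                    )
        return G


def correlation_matrix(data: CohortChangeMatrix) -> np.ndarray:
    """Pearson correlation matrix of the change matrix columns."""
    X = data.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientSampleError(f"correlation needs n >= 3, got {n}")
    sd = X.std(axis=0, ddof=1)
    ptp = X.max(axis=0) - X.min(axis=0)
    bad = np.flatnonzero((sd == 0) | (ptp == 0))
    if bad.size:
        names = [data.columns[i] for i in bad]
        raise DegenerateInputError(f"zero-variance column(s): {', '.join(names)}")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def select_network(
    data: CohortChangeMatrix,
    gamma: float = 0.25,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> Tuple[PartialCorrelationNetwork, EbicTrace]:
    """Fit the graphical lasso along a penalty path, score each fit with the
    EBIC, and return the minimizing network (ties broken toward the larger,
    sparser penalty) together with the full trace."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    S = correlation_matrix(data)
    n, p = data.n, data.p
    if n < p:
        logger.warning(
            "n (%d) < p (%d): the regularized network may be unstable", n, p
        )
    lams = lambda_path(S, n_lambda=n_lambda, min_ratio=lambda_min_ratio)

    trace = EbicTrace()
    best = None
    best_ebic = np.inf
    warm = None
    for lam in lams:
        sol = glasso_fit(S, float(lam), warm=warm)
        warm = (sol.covariance, _betas_from(sol))
        weights = precision_to_partial(sol.precision)
        ebic = ebic_score(sol.precision, S, n, gamma)
        trace.append(lam, count_edges(weights), _loglik(sol.precision, S, n), ebic)
        if ebic < best_ebic:  # strict: first (largest lambda) minimizer wins ties
            best_ebic = ebic
            best = (float(lam), weights)
    sel_lam, sel_weights = best
    network = PartialCorrelationNetwork(
        weights=sel_weights,
        nodes=data.columns,
        groups={c: NODE_GROUPS.get(c, 0) for c in data.columns},
        technique=data.technique,
        selected_lambda=sel_lam,
        ebic_value=float(best_ebic),
        gamma=float(gamma),
    )
    return network, trace


def _loglik(theta: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    return 0.5 * n * (logdet - float(np.trace(S @ theta)))


def _betas_from(sol) -> np.ndarray:
    """Regression coefficients implied by a solution, for warm starts."""
    theta = sol.precision
    p = theta.shape[0]
    B = np.empty((p - 1, p))
    for j in range(p):
        idx = np.delete(np.arange(p), j)
        B[:, j] = -theta[idx, j] / theta[j, j]
    return B


# ---------------------------------------------------------------------------
# export


def write_weight_matrix(network: PartialCorrelationNetwork, path, decimals: int = 2) -> None:
    """Lower-triangle labeled CSV of the weight matrix, rounded for display."""
    p = len(network.nodes)
    W = network.weights
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node"] + network.nodes)
        for i in range(p):
            row = [network.nodes[i]]
            for j in range(p):
                row.append(f"{W[i, j]:.{decimals}f}" if j < i else ("0" if j == i else ""))
            writer.writerow(row)


def write_weight_matrix_full(network: PartialCorrelationNetwork, path) -> None:
    """Full-precision symmetric weight matrix as labeled CSV."""
    df = pd.DataFrame(network.weights, index=network.nodes, columns=network.nodes)
    df.to_csv(path, index_label="node", float_format="%.12g")


def write_edge_list(network: PartialCorrelationNetwork, path) -> None:
    """Edge-list CSV: node_a, node_b, weight, sign (positive/negative)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_a", "node_b", "weight", "sign"])
        p = len(network.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                w = float(network.weights[i, j])
                if abs(w) > 1e-8:
                    writer.writerow(
                        [network.nodes[i], network.nodes[j], f"{w:.12g}",
                         "positive" if w > 0 else "negative"]
                    )


def write_graphml(network: PartialCorrelationNetwork, path) -> None:
    """GraphML export with the group node attribute."""
    nx.write_graphml(network.to_graph(), path)


def write_ebic_trace(trace: EbicTrace, path) -> None:
    df = pd.DataFrame(
        {
            "lambda": trace.lambdas,
            "n_edges": trace.edge_counts,
            "loglik": trace.logliks,
            "ebic": trace.ebics,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_weight_matrix_full(path) -> Tuple[np.ndarray, List[str]]:
    """Read back a full-precision weight matrix CSV; returns (W, node names)."""
    df = pd.read_csv(path, index_col="node")
    return df.to_numpy(dtype=float), list(df.columns)
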