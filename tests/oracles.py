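"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
code under test: the maturity regression is re-derived bracket by bracket,
correlations use an explicit two-pass sum, and the centrality oracle
enumerates every simple path instead of running a shortest-path algorithm.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

EDGE_EPS = 1e-8


def maturity_offset_termwise(sex: str, age: float, height: float,
                             sitting_height: float, body_mass: float) -> float:
    """Second, bracket-by-bracket evaluation of the sex-specific
    maturity-offset regressions."""
    ll = height - sitting_height
    if sex == "M":
        term1 = 0.0002708 * (ll * sitting_height)
        term2 = 0.001663 * (age * ll)
        term3 = 0.007216 * (age * sitting_height)
        term4 = 0.02292 * ((body_mass / height) * 100.0)
        return -9.236 + term1 - term2 + term3 + term4
    term1 = 0.0001882 * (ll * sitting_height)
    term2 = 0.0022 * (age * ll)
    term3 = 0.005847 * (age * sitting_height)
    term4 = 0.002658 * (age * body_mass)
    term5 = 0.07693 * ((body_mass / height) * 100.0)
    return -9.376 + term1 + term2 + term3 - term4 + term5


def correlation_two_pass(X: np.ndarray) -> np.ndarray:
    """Textbook two-pass covariance/correlation computation."""
    n, p = X.shape
    means = [sum(X[:, j]) / n for j in range(p)]
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            cov[i, j] = sum(
                (X[r, i] - means[i]) * (X[r, j] - means[j]) for r in range(n)
            ) / (n - 1)
    corr = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            corr[i, j] = cov[i, j] / math.sqrt(cov[i, i] * cov[j, j])
    return corr


def centrality_by_enumeration(W: np.ndarray, tie_tol: float = 1e-12) -> Tuple[np.ndarray, np.ndarray]:
    """Betweenness and closeness by exhaustive simple-path enumeration.

    Path length is the sum of 1/|w| over traversed edges; tied shortest
    paths share betweenness credit fractionally. Only feasible for small
    graphs.
    """
    p = W.shape[0]
    inf = math.inf
    neighbors = [
        [j for j in range(p) if j != i and abs(W[i, j]) > EDGE_EPS] for i in range(p)
    ]

    best_len = {}
    best_paths = {}
    for s in range(p):
        for t in range(s + 1, p):
            blen, bpaths = inf, []
            stack = [(s, (s,), 0.0)]
            while stack:
                node, path, dist = stack.pop()
                if node == t:
                    if dist < blen - tie_tol:
                        blen, bpaths = dist, [path]
                    elif abs(dist - blen) <= tie_tol:
                        bpaths.append(path)
                    continue
                for nb in neighbors[node]:
                    if nb not in path:
                        stack.append((nb, path + (nb,), dist + 1.0 / abs(W[node, nb])))
            best_len[(s, t)] = blen
            best_paths[(s, t)] = bpaths

    closeness = np.zeros(p)
    for i in range(p):
        total = 0.0
        reachable = True
        for j in range(p):
            if j == i:
                continue
            d = best_len[(min(i, j), max(i, j))]
            if d == inf:
                reachable = False
                break
            total += d
        if reachable and total > 0:
            closeness[i] = 1.0 / total

    betweenness = np.zeros(p)
    for (s, t), paths in best_paths.items():
        if not paths:
            continue
        for i in range(p):
            if i in (s, t):
                continue
            through = sum(1 for path in paths if i in path)
            betweenness[i] += through / len(paths)
    return betweenness, closeness


def random_weight_matrix(rng: np.random.Generator, p: int, edge_prob: float = 0.5) -> np.ndarray:
    """Random symmetric signed weight matrix with zero diagonal."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                w = rng.uniform(0.2, 0.9) * rng.choice([-1.0, 1.0])
                W[i, j] = W[j, i] = w
    return W
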