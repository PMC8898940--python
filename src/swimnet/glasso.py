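"""Graphical lasso and EBIC model selection for sparse partial-correlation
networks.

The estimator maximizes the L1-penalized Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |theta_ij|

over positive-definite precision matrices Theta, with the penalty on the
off-diagonal entries only (the convention of the network-psychometrics
software stack this mirrors). The solver is Friedman's block coordinate
descent: each column of the working covariance W is updated by solving a
lasso regression with an inner coordinate-descent loop, cycling until the
mean absolute change of W falls below a tolerance scaled by the mean
absolute off-diagonal of S.

Model selection follows the extended Bayesian information criterion,

    EBIC(Theta) = -2 l(Theta) + E log(n) + 4 E gamma log(p),

with l = (n/2)(log det Theta - tr(S Theta)) (the additive -(np/2)log(2 pi)
constant cancels across a common lambda path and is omitted) and E the
number of nonzero upper-triangle off-diagonals. gamma in [0, 0.5] controls
parsimony; 0 recovers ordinary BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConvergenceError, DegenerateInputError

EDGE_EPS = 1e-8  # |partial correlation| above this counts as an edge


@dataclass
class GlassoSolution:
    """One penalized fit: penalty, precision matrix, and solver diagnostics."""

    lam: float
    precision: np.ndarray
    covariance: np.ndarray
    converged: bool
    iterations: int


@dataclass
class EbicTrace:
    """(lambda, edge count, log-likelihood, EBIC) along the penalty path."""

    lambdas: List[float] = field(default_factory=list)
    edge_counts: List[int] = field(default_factory=list)
    logliks: List[float] = field(default_factory=list)
    ebics: List[float] = field(default_factory=list)

    def append(self, lam: float, edges: int, loglik: float, ebic: float) -> None:
        self.lambdas.append(float(lam))
        self.edge_counts.append(int(edges))
        self.logliks.append(float(loglik))
        self.ebics.append(float(ebic))


def lambda_path(S: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty sequence from lambda_max = max|S_ij|
    (i != j) down to lambda_max * min_ratio."""
    S = np.asarray(S, dtype=float)
    if n_lambda < 2:
        raise ValueError(f"n_lambda must be >= 2, got {n_lambda}")
    if not 0 < min_ratio < 1:
        raise ValueError(f"min_ratio must be in (0, 1), got {min_ratio}")
    off = S[~np.eye(S.shape[0], dtype=bool)]
    lam_max = float(np.max(np.abs(off))) if off.size else 0.0
    if lam_max <= 0:
        raise DegenerateInputError("all off-diagonal associations are zero; no path")
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _lasso_cd(
    W11: np.ndarray, s12: np.ndarray, lam: float, beta: np.ndarray,
    tol: float, max_iter: int = 2000,
) -> np.ndarray:
    """Coordinate descent for min_b  0.5 b'W11 b - s12'b + lam ||b||_1."""
    q = s12.size
    for _ in range(max_iter):
        max_step = 0.0
        for k in range(q):
            # partial residual: gradient of the smooth part w.r.t. b_k at b_k = 0
            r = s12[k] - W11[k] @ beta + W11[k, k] * beta[k]
            new = np.sign(r) * max(abs(r) - lam, 0.0) / W11[k, k]
            step = abs(new - beta[k])
            if step > 0:
                beta[k] = new
                if step > max_step:
                    max_step = step
        if max_step <= tol:
            break
    return beta


def glasso_fit(
    S: np.ndarray,
    lam: float,
    *,
    max_sweeps: int = 10_000,
    tol_scale: float = 1e-4,
    inner_tol: float = 1e-9,
    warm: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> GlassoSolution:
    """Penalized precision estimate at one penalty value.

    ``warm`` is an optional (W, B) pair from a neighbouring fit (warm start
    along a decreasing path). The returned precision is exactly symmetric.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise DegenerateInputError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if p == 1:
        theta = np.array([[1.0 / S[0, 0]]])
        return GlassoSolution(lam, theta, S.copy(), True, 0)

    mask = ~np.eye(p, dtype=bool)
    mean_off = float(np.mean(np.abs(S[mask])))
    tol = tol_scale * max(mean_off, 1e-12)

    if warm is not None:
        W = warm[0].copy()
        B = warm[1].copy()
    else:
        W = S.copy()
        B = np.zeros((p - 1, p))
    # diagonal is unpenalized: W_ii = S_ii throughout
    np.fill_diagonal(W, np.diag(S))

    idxs = [np.delete(np.arange(p), j) for j in range(p)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        W_prev = W.copy()
        for j in range(p):
            idx = idxs[j]
            W11 = W[np.ix_(idx, idx)]
            beta = _lasso_cd(W11, S[idx, j], lam, B[:, j], inner_tol)
            B[:, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if float(np.mean(np.abs(W - W_prev))) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_sweeps} sweeps (lambda={lam:g})",
            trace={"lam": lam, "sweeps": sweeps, "last_delta": float(np.mean(np.abs(W - W_prev)))},
        )

    theta = np.empty((p, p))
    for j in range(p):
        idx = idxs[j]
        beta = B[:, j]
        denom = W[j, j] - W[idx, j] @ beta
        theta_jj = 1.0 / denom
        theta[j, j] = theta_jj
        theta[idx, j] = -beta * theta_jj
    theta = 0.5 * (theta + theta.T)
    return GlassoSolution(lam, theta, W, converged, sweeps)


def ebic_score(theta: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """EBIC of a precision estimate under sample covariance S at sample size n."""
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    p = theta.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0 or np.any(np.diag(theta) <= 0):
        raise DegenerateInputError("precision matrix must be positive definite")
    loglik = 0.5 * n * (logdet - float(np.trace(S @ theta)))
    pcor = precision_to_partial(theta)
    iu = np.triu_indices(p, k=1)
    E = int(np.sum(np.abs(pcor[iu]) > EDGE_EPS))
    return -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix:
    w_ij = -theta_ij / sqrt(theta_ii theta_jj), zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise DegenerateInputError("precision diagonal must be positive")
    scale = 1.0 / np.sqrt(d)
    W = -theta * np.outer(scale, scale)
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def count_edges(weights: np.ndarray, eps: float = EDGE_EPS) -> int:
    """Number of nonzero upper-triangle entries of a weight matrix."""
    iu = np.triu_indices(weights.shape[0], k=1)
    return int(np.sum(np.abs(np.asarray(weights)[iu]) > eps))
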