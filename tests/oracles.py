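"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP / DP / power-iteration code paths:
SBM scores come from dense grid search over the lambda simplex, natural
breaks from exhaustive partition enumeration, and long-run distributions
from eigen decompositions or absorption closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np


def simplex_grid(n: int, steps: int) -> np.ndarray:
    """All lambda vectors on the n-simplex with coordinates j/steps."""
    pts = []
    for comp in itertools.combinations_with_replacement(range(n), steps):
        lam = np.bincount(comp, minlength=n) / steps
        pts.append(lam)
    return np.array(pts)


def sbm_grid_oracle(X, Y, k, *, vrs=True, steps=60) -> float:
    """SBM score of DMU k by dense search over lambda.

    Under CRS the simplex grid is additionally scanned over scale factors.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    lams = simplex_grid(n, steps)
    if not vrs:
        scales = np.linspace(0.0, 3.0, 181)[1:]
        lams = np.concatenate([lams * s for s in scales])
    xk, yk = X[k], Y[k]
    xl = lams @ X
    yl = lams @ Y
    feas = (xl <= xk + 1e-12).all(axis=1) & (yl >= yk - 1e-12).all(axis=1)
    s_in = np.clip(xk - xl[feas], 0, None)
    s_out = np.clip(yl[feas] - yk, 0, None)
    rho = (1 - (s_in / xk).mean(axis=1)) / (1 + (s_out / yk).mean(axis=1))
    return float(rho.min())


def super_sbm_grid_oracle(X, Y, k, *, vrs=True, steps=60) -> float:
    """Super-efficiency SBM score of DMU k by dense search over lambda
    (reference set excludes k); targets are the implied componentwise
    optima x_bar = max(X'lam, x_k), y_bar = min(Y'lam, y_k)."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    peers = [j for j in range(n) if j != k]
    lams = simplex_grid(len(peers), steps)
    if not vrs:
        scales = np.linspace(0.0, 4.0, 241)[1:]
        lams = np.concatenate([lams * s for s in scales])
    xk, yk = X[k], Y[k]
    xl = lams @ X[peers]
    yl = lams @ Y[peers]
    xbar = np.maximum(xl, xk)
    ybar = np.minimum(yl, yk)
    ok = (ybar > 1e-12).all(axis=1)
    delta = (xbar[ok] / xk).mean(axis=1) / (ybar[ok] / yk).mean(axis=1)
    return float(delta.min())


def jenks_exhaustive_oracle(values, k) -> tuple[float, tuple[int, ...]]:
    """Optimal within-class SSD by enumerating all contiguous partitions.

    Returns (cost, class start indices of classes 2..k) with ties broken
    toward the lexicographically smallest boundary tuple.
    """
    x = np.sort(np.asarray(values, float))
    n = len(x)
    best = (np.inf, None)
    for bounds in itertools.combinations(range(1, n), k - 1):
        edges = (0, *bounds, n)
        cost = sum(
            float(((x[a:b] - x[a:b].mean()) ** 2).sum())
            for a, b in zip(edges, edges[1:])
        )
        if cost < best[0] - 1e-12:
            best = (cost, bounds)
    return best


def stationary_eig_oracle(P) -> np.ndarray:
    """Stationary distribution from the left eigenvector at eigenvalue 1."""
    P = np.asarray(P, float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def absorption_oracle(P, pi0, absorbing) -> np.ndarray:
    """Limit of pi0 P^n for a chain whose recurrent states are absorbing.

    Uses the fundamental matrix N = (I - Q)^{-1}: absorption probabilities
    B = N R, so the limit places pi0's transient mass according to B.
    """
    P = np.asarray(P, float)
    pi0 = np.asarray(pi0, float)
    n = P.shape[0]
    transient = [i for i in range(n) if i not in absorbing]
    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, list(absorbing))]
    B = np.linalg.solve(np.eye(len(transient)) - Q, R)
    out = np.zeros(n)
    for j, a in enumerate(absorbing):
        out[a] = pi0[a] + pi0[transient] @ B[:, j]
    return out
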