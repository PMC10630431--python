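"""Simplex-constrained least squares and archetype (simplex) fitting.

Both primitives underlie niche discovery: archetype analysis fits a
p-vertex simplex tightly to a point cloud, and the constrained
least-squares projection expresses a composition vector as a convex
combination of niche compositions (``c = B @ alpha`` with ``alpha >= 0``
and ``sum(alpha) == 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["simplex_lstsq", "project_rows_to_simplex", "ArchetypeFit", "fit_archetypes"]

_MAX_ENUM_VERTICES = 14


def _support_solution(B_s: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Equality-constrained least squares on one support.

    Minimises ``||c - B_s a||^2`` subject to ``sum(a) == 1`` (sign
    unconstrained) for every row ``c`` of ``C``; returns ``a`` of shape
    (k, n_points).
    """
    k = B_s.shape[1]
    G = B_s.T @ B_s
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = G
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.empty((k + 1, C.shape[0]))
    rhs[:k] = B_s.T @ C.T
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    return sol[:k]


def simplex_lstsq(B: np.ndarray, C: np.ndarray, *, feas_tol: float = 1e-10) -> np.ndarray:
    """Project points onto the simplex spanned by the columns of ``B``.

    Solves, for every row ``c`` of ``C``::

        minimise ||c - B @ alpha||^2   s.t.  alpha >= 0,  sum(alpha) == 1

    exactly, by enumerating active supports: the optimum restricted to
    its own support satisfies the equality-constrained normal equations,
    so the best non-negative candidate over all supports is the global
    optimum of this convex program.

    Parameters
    ----------
    B
        (m, p) matrix whose columns are the simplex vertices.
    C
        (n, m) points (a single vector is also accepted).

    Returns
    -------
    (n, p) array of weights, rows on the probability simplex.
    """
    B = np.asarray(B, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m, p = B.shape
    if C.shape[1] != m:
        raise ValueError(f"point dimension {C.shape[1]} != vertex dimension {m}")
    if p > _MAX_ENUM_VERTICES:
        raise ValueError(f"support enumeration supports at most {_MAX_ENUM_VERTICES} vertices")
    n = C.shape[0]
    if p == 1:
        return np.ones((n, 1))

    Ct = C.T  # (m, n)
    cn2 = np.einsum("ij,ij->j", Ct, Ct)
    best_obj = np.full(n, np.inf)
    best_alpha = np.zeros((n, p))
    for k in range(1, p + 1):
        for support in combinations(range(p), k):
            S = list(support)
            Bs = B[:, S]
            K = np.zeros((k + 1, k + 1))
            K[:k, :k] = Bs.T @ Bs
            K[:k, k] = 1.0
            K[k, :k] = 1.0
            try:
                Kinv = np.linalg.inv(K)
            except np.linalg.LinAlgError:
                a = _support_solution(Bs, C)
            else:
                # solution is affine in c: a = P @ c + q
                a = (Kinv[:k, :k] @ Bs.T) @ Ct + Kinv[:k, k][:, None]
            feas = (a >= -feas_tol).all(axis=0)
            if not feas.any():
                continue
            t = Bs @ a  # (m, n)
            obj = cn2 - 2.0 * np.einsum("ij,ij->j", Ct, t) + np.einsum("ij,ij->j", t, t)
            better = feas & (obj < best_obj)
            if better.any():
                best_obj[better] = obj[better]
                best_alpha[better] = 0.0
                best_alpha[np.ix_(better, S)] = a[:, better].T
    np.clip(best_alpha, 0.0, None, out=best_alpha)
    best_alpha /= best_alpha.sum(axis=1, keepdims=True)
    return best_alpha


def project_rows_to_simplex(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of every row of ``Y`` onto the probability simplex."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, d = Y.shape
    s = np.sort(Y, axis=1)[:, ::-1]
    css = np.cumsum(s, axis=1) - 1.0
    j = np.arange(1, d + 1)
    cond = s - css / j > 0
    rho = d - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.clip(Y - theta[:, None], 0.0, None)


@dataclass
class ArchetypeFit:
    """Result of fitting a p-vertex simplex to points in R^d."""

    vertices: np.ndarray  # (d, p), columns are simplex vertices
    weights: np.ndarray  # (n, p), convex-combination weights per point
    rss: float
    n_iter: int
    converged: bool
    restart_rss: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]


def _rss(X, A, Z):
    resid = X - A @ Z
    return float(np.einsum("ij,ij->", resid, resid))


def _furthest_points(X, p, rng):
    """Greedy max-min-distance point selection, seeded at the point
    furthest from the centroid; picks near-vertex points on simplex data."""
    n = X.shape[0]
    start = int(np.argmax(((X - X.mean(axis=0)) ** 2).sum(axis=1)))
    idx = [start]
    d2 = ((X - X[start]) ** 2).sum(axis=1)
    for _ in range(p - 1):
        nxt = int(np.argmax(d2))
        idx.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return np.asarray(idx)


def _single_fit(X, p, rng, tolerance, max_iter, rss_floor, init):
    """One principal-convex-hull style run.

    Archetypes are convex combinations of the data rows, ``Z = C @ X``
    with the rows of ``C`` on the probability simplex (so archetypes stay
    in the convex hull of the data).  Alternates an exact
    simplex-least-squares weight step with a projected-gradient,
    backtracking-line-search step on ``C``.
    """
    n, d = X.shape
    if init == "furthest":
        idx = _furthest_points(X, p, rng)
    else:
        idx = rng.choice(n, size=p, replace=False)
    C = np.zeros((p, n))
    C[np.arange(p), idx] = 1.0
    Z = C @ X  # (p, d) archetypes as rows
    A = simplex_lstsq(Z.T, X)
    rss_prev = _rss(X, A, Z)
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # C step: a few projected-gradient descents with backtracking
        rss_c = _rss(X, A, Z)
        for _ in range(8):
            G = 2.0 * (A.T @ (A @ Z - X)) @ X.T  # (p, n)
            if not np.abs(G).max() > 0:
                break
            for _ in range(20):
                C_new = project_rows_to_simplex(C - step * G)
                Z_new = C_new @ X
                rss_new = _rss(X, A, Z_new)
                if rss_new <= rss_c:
                    C, Z, rss_c = C_new, Z_new, rss_new
                    step *= 1.5
                    break
                step *= 0.5
        # A step: exact projection of each point onto the simplex
        A = simplex_lstsq(Z.T, X)
        rss = _rss(X, A, Z)
        if rss <= rss_floor or rss_prev - rss <= tolerance * max(rss_prev, 1e-300):
            rss_prev = rss
            converged = True
            break
        rss_prev = rss
    return Z.T, A, rss_prev, it, converged


def fit_archetypes(
    X: np.ndarray,
    p: int,
    *,
    tolerance: float = 1e-4,
    max_iter: int = 200,
    restarts: int = 30,
    seed: int | np.random.Generator | None = 0,
) -> ArchetypeFit:
    """Fit ``p`` archetypes to points ``X`` (n, d) by alternating optimisation.

    Convex-combination weights are recomputed by exact simplex-constrained
    least squares; archetypes, parameterised as convex combinations of
    data points, by projected gradient descent.  The best of ``restarts``
    random initialisations (archetypes seeded at random data points) is
    returned; restarts stop early once a fit explains the data to machine
    precision.  With ``p == 1`` the single archetype is the centroid.

    ``tolerance`` is the relative decrease of the residual sum of squares
    between outer iterations below which a run is considered converged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > n:
        raise ValueError(f"cannot fit {p} archetypes to {n} points")
    if p == 1:
        z = X.mean(axis=0, keepdims=True).T
        rss = float(((X - z.T) ** 2).sum())
        return ArchetypeFit(z, np.ones((n, 1)), rss, 0, True, np.array([rss]))

    rng = np.random.default_rng(seed)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    rss_floor = 1e-12 * max(tss, 1e-300)
    best = None
    rss_log = []
    # first run starts from greedily chosen extreme points, the rest from
    # random data points
    inits = ["furthest"] + ["random"] * (max(1, restarts) - 1)
    for init in inits:
        Z, A, rss, it, conv = _single_fit(X, p, rng, tolerance, max_iter, rss_floor, init)
        rss_log.append(rss)
        if best is None or rss < best[2]:
            best = (Z, A, rss, it, conv)
        if best[2] <= rss_floor:
            break  # perfect fit; further restarts cannot improve
    Z, A, rss, it, conv = best
    return ArchetypeFit(Z, A, rss, it, conv, np.asarray(rss_log))
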