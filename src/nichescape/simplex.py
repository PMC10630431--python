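"""Niche identification: PCA, simplex (archetype) fitting and model diagnostics.

Local cellular composition of sites does not form clusters but a
continuum bounded by a simplex: each site is a weighted average of a few
*niches*, the simplex endpoints.  Fitting proceeds in two steps —
centered, unscaled PCA of the site composition matrix, then archetype
analysis in the first ``d = p - 1`` components — and endpoints are
back-projected to cell-type space as ``b = c0 + U @ b'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from sklearn.cluster import KMeans

from .archetypes import ArchetypeFit, fit_archetypes, simplex_lstsq

__all__ = [
    "PCModel",
    "fit_pca",
    "NicheModel",
    "fit_niches",
    "explained_variance_niches",
    "select_n_niches",
    "kmeans_variance",
    "TRatioResult",
    "t_ratio_test",
    "project_faces",
]


def _as_matrix(X):
    comp = getattr(X, "comp", X)
    return np.atleast_2d(np.asarray(comp, dtype=float))


def _cell_types(X, m):
    types = getattr(X, "cell_types", None)
    return list(types) if types is not None else [f"type_{i}" for i in range(m)]


@dataclass
class PCModel:
    """Centered, unscaled PCA of a site composition matrix."""

    mean: np.ndarray  # (m,) average composition c0
    loadings: np.ndarray  # (m, d), orthonormal columns
    explained_variance: np.ndarray  # (d,)
    explained_variance_ratio: np.ndarray  # (d,)
    cell_types: list[str]

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X) -> np.ndarray:
        return (_as_matrix(X) - self.mean) @ self.loadings

    def inverse_transform(self, scores) -> np.ndarray:
        return self.mean + np.asarray(scores) @ self.loadings.T


def fit_pca(X, d: int) -> PCModel:
    """Centered, unscaled PCA keeping ``d`` components.

    The composition matrix is mean-subtracted but not scaled to unit
    variance — all columns carry the same (density) units.  Loading
    signs are fixed so each component's largest-magnitude loading is
    positive, making runs comparable.
    """
    M = _as_matrix(X)
    n, m = M.shape
    if d > m:
        raise ValueError(f"d={d} exceeds the number of cell types {m}")
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} sites, got {n}")
    c0 = M.mean(axis=0)
    Xc = M - c0
    _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2
    if var.sum() <= 0:
        raise ValueError("composition matrix is constant; PCA undefined")
    U = Vt[:d].T  # (m, d)
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    U = U * flip
    return PCModel(c0, U, var[:d] / max(n - 1, 1), var[:d] / var.sum(), _cell_types(X, m))


@dataclass
class NicheModel:
    """A fitted p-niche simplex.

    ``endpoints_pc`` holds the simplex vertices in PC space (d × p);
    ``endpoints_celltype`` the same vertices back-projected to cell-type
    density space (m × p).  Back-projection can produce small negative
    densities; they are reported raw and should be clipped only for
    display.  ``site_weights`` rows lie on the probability simplex.
    """

    p: int
    endpoints_pc: np.ndarray  # (d, p)
    endpoints_celltype: np.ndarray  # (m, p)
    site_weights: np.ndarray  # (n, p)
    pca: PCModel
    niche_names: list[str]
    meta: dict = dc_field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.endpoints_pc.shape[0]

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "endpoints_pc": self.endpoints_pc.tolist(),
            "endpoints_celltype": self.endpoints_celltype.tolist(),
            "site_weights": self.site_weights.tolist(),
            "pca": {
                "mean": self.pca.mean.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "cell_types": self.pca.cell_types,
            },
            "niche_names": self.niche_names,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NicheModel":
        pca = PCModel(
            np.array(d["pca"]["mean"]),
            np.array(d["pca"]["loadings"]),
            np.array(d["pca"]["explained_variance"]),
            np.array(d["pca"]["explained_variance_ratio"]),
            list(d["pca"]["cell_types"]),
        )
        return cls(
            d["p"],
            np.array(d["endpoints_pc"]),
            np.array(d["endpoints_celltype"]),
            np.array(d["site_weights"]),
            pca,
            list(d["niche_names"]),
            dict(d.get("meta", {})),
        )

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.site_weights, columns=self.niche_names)


def fit_niches(
    X,
    p: int,
    *,
    d: int | None = None,
    tolerance: float = 1e-4,
    max_iter: int = 200,
    restarts: int = 30,
    seed: int | np.random.Generator | None = 0,
    niche_names: list[str] | None = None,
) -> NicheModel:
    """PCA + archetype fitting: the standard niche-identification pipeline.

    ``d`` defaults to ``p - 1``.  Returns the best of ``restarts``
    archetype initialisations; site weights are the convex-combination
    coefficients of each site with respect to the fitted endpoints.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    d = p - 1 if d is None else d
    M = _as_matrix(X)
    if p == 1:
        # degenerate simplex: the single endpoint is the mean composition
        c0 = M.mean(axis=0)
        pca = fit_pca(X, min(1, M.shape[1]))
        return NicheModel(
            1,
            np.zeros((1, 1)),
            c0[:, None],
            np.ones((M.shape[0], 1)),
            pca,
            niche_names or ["niche_1"],
            {"rss": float(((M - c0) ** 2).sum()), "converged": True},
        )
    pca = fit_pca(X, d)
    scores = pca.transform(X)
    fit: ArchetypeFit = fit_archetypes(
        scores, p, tolerance=tolerance, max_iter=max_iter, restarts=restarts, seed=seed
    )
    B_pc = fit.vertices  # (d, p)
    B_ct = pca.mean[:, None] + pca.loadings @ B_pc
    names = niche_names or [f"niche_{i + 1}" for i in range(p)]
    return NicheModel(
        p,
        B_pc,
        B_ct,
        fit.weights,
        pca,
        names,
        {"rss": fit.rss, "n_iter": fit.n_iter, "converged": fit.converged},
    )


def explained_variance_niches(X, model: NicheModel) -> float:
    """Fraction of inter-site variance in composition explained by the niches.

    Per-site weights are refit by constrained least squares in PC space
    (the best-fitted composition), and the residual is evaluated in full
    cell-type space:  ``1 - Σ ε² / Σ (c - c0)²`` with
    ``ε_k = c_k - c0 - U B α_k``.
    """
    M = _as_matrix(X)
    c0 = M.mean(axis=0)
    Xc = M - c0
    tss = float((Xc**2).sum())
    if tss <= 0:
        raise ValueError("composition matrix has zero total sum of squares")
    scores = (M - model.pca.mean) @ model.pca.loadings
    alpha = simplex_lstsq(model.endpoints_pc, scores)
    fitted = (model.pca.loadings @ model.endpoints_pc @ alpha.T).T + model.pca.mean
    resid = M - fitted
    return 1.0 - float((resid**2).sum()) / tss


def select_n_niches(
    X,
    p_range,
    *,
    restarts: int = 10,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, int]:
    """Explained-variance curve over candidate niche counts, with an elbow suggestion.

    For each ``p`` the simplex is fitted with ``d = p - 1`` and the
    explained variance recorded.  The suggested elbow is the ``p`` with
    the largest second difference of the curve; ties within 1% resolve
    to the smallest ``p``.  The final choice is left to the user.
    """
    p_range = sorted(p_range)
    rows = []
    for p in p_range:
        model = fit_niches(X, p, restarts=restarts, seed=seed)
        rows.append({"p": p, "explained_variance": explained_variance_niches(X, model)})
    curve = pd.DataFrame(rows)
    if len(curve) < 3:
        return curve, int(curve["p"].iloc[0])
    ev = curve["explained_variance"].to_numpy()
    second = ev[:-2] - 2 * ev[1:-1] + ev[2:]  # concavity at interior points
    best = second.max()
    ok = np.flatnonzero(second >= best - 0.01 * abs(best))
    elbow = int(curve["p"].iloc[ok[0] + 1])
    return curve, elbow


def kmeans_variance(X, p: int, seed: int | None = 0, n_init: int = 10) -> float:
    """Variance in site composition explained by ``p`` k-means clusters.

    Computed as one minus the ratio of the within-cluster sum of squares
    to the total sum of squares of the raw composition matrix.
    """
    M = _as_matrix(X)
    if p > M.shape[0]:
        raise ValueError("more clusters than sites")
    tss = float(((M - M.mean(axis=0)) ** 2).sum())
    if tss <= 0:
        raise ValueError("composition matrix has zero total sum of squares")
    km = KMeans(n_clusters=p, n_init=n_init, random_state=seed).fit(M)
    return 1.0 - km.inertia_ / tss


def _simplex_volume(vertices: np.ndarray) -> float:
    """Volume of the simplex with columns of ``vertices`` (d, d+1) as corners."""
    d = vertices.shape[0]
    E = vertices[:, 1:] - vertices[:, [0]]
    from math import factorial

    return abs(np.linalg.det(E)) / factorial(d)


def _hull_volume(points: np.ndarray) -> float:
    d = points.shape[1]
    if d == 1:
        return float(points.max() - points.min())
    return float(ConvexHull(points).volume)


def _enclosing_dilation(vertices: np.ndarray, points: np.ndarray) -> float:
    """Smallest dilation about the centroid making the simplex contain all points."""
    p = vertices.shape[1]
    A = np.vstack([vertices, np.ones((1, p))])
    b = np.vstack([points.T, np.ones((1, points.shape[0]))])
    lam = np.linalg.solve(A, b)  # barycentric coordinates, columns per point
    lam_min = lam.min()
    return float(max(1.0, 1.0 - p * lam_min))


def _t_ratio_once(M, p, seed, restarts, tolerance, max_iter):
    pca = fit_pca(M, p - 1)
    scores = pca.transform(M)
    fit = fit_archetypes(
        scores, p, restarts=restarts, seed=seed, tolerance=tolerance, max_iter=max_iter
    )
    hull = _hull_volume(scores)
    if hull <= 0:
        raise ValueError("degenerate convex hull (zero volume); t-ratio undefined")
    s = _enclosing_dilation(fit.vertices, scores)
    return s ** (p - 1) * _simplex_volume(fit.vertices) / hull


@dataclass
class TRatioResult:
    """Simplex-fit significance by comparison of enclosing-simplex and hull volumes.

    The t-ratio is the volume of the minimal simplex enclosing the data
    (the fitted simplex, minimally dilated about its centroid so that it
    contains every site) divided by the volume of the data's convex
    hull; it is >= 1, and approaches 1 when sites fill a simplex.  The
    null distribution is built by independently permuting each cell-type
    column across sites, which preserves marginals but destroys the
    covariance that creates the simplex; significance is the one-sided
    probability of a null t-ratio as small as observed.
    """

    t_ratio: float
    null_t_ratios: np.ndarray
    p_value: float
    null_ci: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def t_ratio_test(
    X,
    p: int,
    *,
    n_shuffles: int = 100,
    seed: int | None = 0,
    restarts: int = 5,
    tolerance: float = 1e-4,
    max_iter: int = 100,
) -> TRatioResult:
    """T-ratio test of the statistical significance of the simplex fit."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a p-value resolution of 0.01")
    M = _as_matrix(X)
    rng = np.random.default_rng(seed)
    observed = _t_ratio_once(M, p, rng, restarts, tolerance, max_iter)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = np.column_stack([rng.permutation(M[:, j]) for j in range(M.shape[1])])
        null[i] = _t_ratio_once(perm, p, rng, restarts, tolerance, max_iter)
    p_value = (1 + int((null <= observed).sum())) / (1 + n_shuffles)
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    return TRatioResult(observed, null, p_value, ci)


@dataclass
class FaceProjection:
    positions: np.ndarray  # (n_kept, 2)
    kept: np.ndarray  # indices of retained sites
    endpoint_xy: dict  # face endpoint -> 2-D position


def project_faces(
    model: NicheModel,
    face: tuple[int, int, int],
    *,
    min_weight: float = 0.5,
) -> FaceProjection:
    """Project sites onto one triangular face of a high-dimensional simplex.

    Only sites whose combined weight on the three face endpoints is at
    least ``min_weight`` are kept.  The face triangle is laid out in an
    orthonormal in-face basis with endpoint ``i`` at the origin, and a
    site maps to ``α_i (0,0) + α_j (x_j,y_j) + α_k (x_k,y_k)``.
    """
    i, j, k = face
    if len({i, j, k}) != 3:
        raise ValueError("face endpoints must be distinct")
    if model.p < 3:
        raise ValueError("face projection needs at least 3 endpoints")
    V = model.endpoints_pc
    e1 = V[:, j] - V[:, i]
    n1 = np.linalg.norm(e1)
    u1 = e1 / n1
    e2 = V[:, k] - V[:, i]
    e2o = e2 - (e2 @ u1) * u1
    n2 = np.linalg.norm(e2o)
    u2 = e2o / n2
    xy = {
        i: np.zeros(2),
        j: np.array([n1, 0.0]),
        k: np.array([e2 @ u1, n2]),
    }
    A = model.site_weights
    kept = np.flatnonzero(A[:, [i, j, k]].sum(axis=1) >= min_weight)
    pos = A[kept][:, [j, k]] @ np.vstack([xy[j], xy[k]])
    return FaceProjection(pos, kept, xy)
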