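"""Cross-scale analysis: incidence mapping, macro simplex fit, in-silico dissection.

If tumors from different patients are built from the same niches, a
patient's macroscopic cell-type composition — the spatial average of
the local composition ``c(x) = B α(x)`` — is ``C = B θ`` with
``θ = <α>`` on the probability simplex: inter-patient variation must be
bounded by the simplex whose endpoints are the microscopic niches.
This module maps cell-type vocabularies between datasets through a 0/1
incidence matrix, fits the macro simplex, verifies containment, and
mathematically dissects a designated endpoint (e.g. healthy tissue) out
of bulk samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .archetypes import simplex_lstsq
from .simplex import NicheModel, fit_niches

__all__ = [
    "IncidenceMap",
    "build_incidence",
    "project_composition",
    "MacroModel",
    "macro_simplex_fit",
    "dissect_endpoint",
    "simplex_containment_check",
]


@dataclass
class IncidenceMap:
    """Cell-type correspondence between two datasets.

    ``G`` is the 0/1 incidence matrix (rows: dataset-A types, columns:
    dataset-B types); ``projector_a`` and ``projector_b`` map each
    dataset's composition onto the shared, least-granular vocabulary by
    right multiplication.
    """

    G: pd.DataFrame
    projector_a: pd.DataFrame  # (types_a × shared)
    projector_b: pd.DataFrame  # (types_b × shared)

    @property
    def shared_types(self) -> list[str]:
        return list(self.projector_a.columns)


def _least_granular(G: pd.DataFrame) -> pd.DataFrame:
    """Keep, per multi-mapped row, only the first 1-column, renamed to the row.

    Rows whose sum exceeds 1 correspond to types mapped at finer
    granularity on the other side; retaining a single column per such
    row keeps the least granular shared type.
    """
    out = G.copy().astype(float)
    renames = {}
    for row in out.index:
        cols = out.columns[out.loc[row] > 0]
        if len(cols) > 1:
            out.loc[row, cols[1:]] = 0.0
            renames[cols[0]] = row
    out = out.rename(columns=renames)
    return out.loc[:, (out > 0).any(axis=0)]


def build_incidence(
    pairs,
    vocab_a,
    vocab_b,
    *,
    shared_names: dict | None = None,
    unmatched: str = "drop",
) -> IncidenceMap:
    """Assemble the incidence matrix and the two shared-vocabulary projectors.

    ``pairs`` lists (type_a, type_b) declarations of identical cell
    types; a type may appear in several pairs when the two datasets
    differ in granularity.  ``unmatched`` controls types with no pair:
    ``"drop"`` removes them from the shared space (row sums are then not
    preserved for samples containing them) and ``"other"`` pools them
    into a shared ``"other"`` type.  ``shared_names`` optionally renames
    shared types afterwards.
    """
    vocab_a, vocab_b = list(vocab_a), list(vocab_b)
    G = pd.DataFrame(0.0, index=vocab_a, columns=vocab_b)
    for a, b in pairs:
        if a not in G.index:
            raise ValueError(f"unknown dataset-A type {a!r}")
        if b not in G.columns:
            raise ValueError(f"unknown dataset-B type {b!r}")
        G.loc[a, b] = 1.0

    proj_a = _least_granular(G)
    proj_b = _least_granular(G.T)
    # the two procedures must agree on the shared vocabulary, up to
    # which side lent the name to each merged type; align b to a by
    # the incidence components
    rename_b = {}
    for col_b in proj_b.columns:
        members_b = set(proj_b.index[proj_b[col_b] > 0])
        for col_a in proj_a.columns:
            rows_a = set(proj_a.index[proj_a[col_a] > 0])
            linked = G.loc[list(rows_a)].sum(axis=0)
            if members_b & set(linked.index[linked > 0]) or col_a == col_b:
                rename_b[col_b] = col_a
                break
    proj_b = proj_b.rename(columns=rename_b)
    shared = [c for c in proj_a.columns]
    proj_b = proj_b.reindex(columns=shared, fill_value=0.0)

    if unmatched == "other":
        for proj, vocab in ((proj_a, vocab_a), (proj_b, vocab_b)):
            missing = [t for t in vocab if proj.loc[t].sum() == 0]
            proj["other"] = 0.0
            proj.loc[missing, "other"] = 1.0
        shared = shared + ["other"]
    elif unmatched != "drop":
        raise ValueError("unmatched must be 'drop' or 'other'")

    if shared_names:
        proj_a = proj_a.rename(columns=shared_names)
        proj_b = proj_b.rename(columns=shared_names)
    return IncidenceMap(G, proj_a, proj_b)


def project_composition(X: pd.DataFrame, projector: pd.DataFrame) -> pd.DataFrame:
    """Project a samples × types composition onto the shared vocabulary.

    Plain matrix product ``Y = X G``; when every type maps somewhere,
    proportion rows keep their row sums.
    """
    missing = [t for t in projector.index if t not in X.columns]
    if missing:
        raise ValueError(f"composition table lacks types: {missing}")
    return X[projector.index] @ projector


@dataclass
class MacroModel:
    """Macro-scale simplex fit of sample compositions."""

    endpoints: pd.DataFrame  # shared types × endpoints (full compositions)
    theta: pd.DataFrame  # samples × endpoints, rows on the simplex
    mean: pd.Series  # μ, average proportions
    residual: pd.DataFrame  # samples × shared types, out-of-simplex PC remainder
    niche_model: NicheModel

    @property
    def endpoint_names(self) -> list[str]:
        return list(self.theta.columns)


def macro_simplex_fit(
    C: pd.DataFrame,
    n_endpoints: int = 4,
    *,
    d: int | None = None,
    endpoint_names: list[str] | None = None,
    restarts: int = 30,
    seed: int | None = 0,
) -> MacroModel:
    """Fit a simplex to macroscopic (bulk) sample compositions.

    Centered, unscaled PCA of the proportions followed by archetype
    fitting in the first ``d = n_endpoints - 1`` components.  θ are the
    per-sample endpoint weights; the residual stores each sample's
    component outside the d-dimensional simplex plane (the ``Σ u_i v_i``
    remainder), so that ``C = μ + Σθ_j b_j + residual`` exactly.
    """
    if len(C) < n_endpoints:
        raise ValueError("need at least as many samples as endpoints")
    d = n_endpoints - 1 if d is None else d
    model = fit_niches(
        C.to_numpy(float), n_endpoints, d=d, restarts=restarts, seed=seed,
        niche_names=endpoint_names,
    )
    names = endpoint_names or model.niche_names
    mean = pd.Series(model.pca.mean, index=C.columns, name="mean")
    scores = (C.to_numpy(float) - model.pca.mean) @ model.pca.loadings
    theta = simplex_lstsq(model.endpoints_pc, scores)
    in_plane = scores @ model.pca.loadings.T
    residual = C.to_numpy(float) - model.pca.mean - in_plane
    endpoints = pd.DataFrame(model.endpoints_celltype, index=C.columns, columns=names)
    return MacroModel(
        endpoints,
        pd.DataFrame(theta, index=C.index, columns=names),
        mean,
        pd.DataFrame(residual, index=C.index, columns=C.columns),
        model,
    )


def dissect_endpoint(
    model: MacroModel,
    dissect: int | str,
    *,
    max_weight: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove one endpoint's contribution from every sample composition.

    The remaining endpoint weights are renormalised,
    ``γ_j = θ_j / Σ_{k≠dissect} θ_k``, and the dissected composition is
    rebuilt as ``C_d = Σ γ_j b_j + residual + μ`` (the endpoint
    compositions ``b_j`` here being centred on μ).  Samples where the
    dissected endpoint weighs more than ``max_weight`` are discarded
    (dissection would amplify their reconstruction error); the returned
    mask flags them.
    """
    names = model.endpoint_names
    j = names.index(dissect) if isinstance(dissect, str) else int(dissect)
    theta = model.theta.to_numpy(float)
    rest = theta.sum(axis=1) - theta[:, j]
    discarded = pd.Series(theta[:, j] > max_weight, index=model.theta.index, name="discarded")
    discarded |= rest <= 0
    gamma = np.delete(theta, j, axis=1)
    safe = np.where(rest > 0, rest, 1.0)
    gamma = gamma / safe[:, None]
    b_centered = model.endpoints.to_numpy(float) - model.mean.to_numpy(float)[:, None]
    b_rest = np.delete(b_centered, j, axis=1)
    C_d = gamma @ b_rest.T + model.residual.to_numpy(float) + model.mean.to_numpy(float)
    out = pd.DataFrame(C_d, index=model.theta.index, columns=model.endpoints.index)
    out[discarded.to_numpy()] = np.nan
    return out, discarded


def simplex_containment_check(
    C: pd.DataFrame,
    B: np.ndarray,
    *,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Is each macroscopic composition inside the niche simplex?

    Projects every sample onto the simplex spanned by the columns of
    ``B`` by constrained least squares and reports the residual norm
    (the Euclidean distance to the simplex); a sample is contained when
    the residual is below ``tol``.
    """
    B = np.asarray(B, dtype=float)
    M = C.to_numpy(float) if isinstance(C, pd.DataFrame) else np.atleast_2d(np.asarray(C, float))
    theta = simplex_lstsq(B, M)
    resid = np.linalg.norm(M - theta @ B.T, axis=1)
    idx = C.index if isinstance(C, pd.DataFrame) else pd.RangeIndex(len(M))
    out = pd.DataFrame({"residual": resid, "contained": resid <= tol}, index=idx)
    for k in range(B.shape[1]):
        out[f"theta_{k + 1}"] = theta[:, k]
    return out
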