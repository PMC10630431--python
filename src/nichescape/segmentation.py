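"""Mapping fitted niches back onto tissue: per-cell weights, interfaces, mixing.

Niche weights of individual cells are obtained by centring a sampling
site on each cell, estimating its kernel composition ``c`` and solving
``c = B α`` under simplex constraints by quadratic programming.  The
product of two niche weights scores interface regions; the mixing score
summarises tumor-immune interleaving per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .archetypes import simplex_lstsq
from .io import UNIDENTIFIED, CellTable
from .sites import site_composition

__all__ = [
    "CellNicheWeights",
    "cell_niche_weights",
    "interface_score",
    "density_excluded_weights",
    "mixing_score",
    "mixing_scores_by_sample",
    "lowest_density_niche",
    "segment_map",
    "niche_blend_image",
]


def _endpoints(model_or_B):
    """Accept a NicheModel, a NicheBank or a raw (m, p) matrix."""
    B = getattr(model_or_B, "endpoints_celltype", None)
    if B is None:
        B = getattr(model_or_B, "B", model_or_B)
    names = getattr(model_or_B, "niche_names", None)
    B = np.asarray(B, dtype=float)
    if names is None:
        names = [f"niche_{i + 1}" for i in range(B.shape[1])]
    return B, list(names)


@dataclass
class CellNicheWeights:
    """Per-cell niche weights α (rows on the probability simplex)."""

    alpha: np.ndarray  # (n_cells, p)
    niche_names: list[str]
    cells: CellTable

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    def interface(self, i: int, j: int) -> np.ndarray:
        return interface_score(self.alpha, i, j)

    def to_frame(self, include_interfaces: bool = True) -> pd.DataFrame:
        df = self.cells.cells[["sample_id", "x", "y", "cell_type"]].copy()
        for k, name in enumerate(self.niche_names):
            df[f"alpha_{name}"] = self.alpha[:, k]
        if include_interfaces:
            from itertools import combinations

            for i, j in combinations(range(self.p), 2):
                df[f"interface_{self.niche_names[i]}x{self.niche_names[j]}"] = self.interface(i, j)
        return df

    def phenomapping_mask(self) -> np.ndarray:
        """Cells eligible for niche-phenotype mapping: typed within the
        vocabulary and not labelled Unidentified."""
        ct = self.cells.cells["cell_type"]
        return (ct.isin(self.cells.vocabulary) & (ct != UNIDENTIFIED)).to_numpy()


def cell_niche_weights(
    cells: CellTable,
    model_or_B,
    r: float = 25.0,
    *,
    normalization: str = "as_paper",
) -> CellNicheWeights:
    """Niche weights of every cell, by centring a site on each cell.

    No edge exclusion is applied — every cell receives weights.  If the
    niche composition matrix is rank deficient the exact solver still
    applies (it never inverts ``B`` itself), but a warning is emitted
    because weights may not be unique.
    """
    B, names = _endpoints(model_or_B)
    if np.linalg.matrix_rank(np.vstack([B, np.ones(B.shape[1])])) < B.shape[1]:
        import warnings

        warnings.warn("niche composition matrix is rank deficient; weights may be non-unique")
    centers = cells.cells[["x", "y"]].to_numpy(float)
    comp = site_composition(
        cells, centers, r, sample_ids=cells.cells["sample_id"].to_numpy(), normalization=normalization
    )
    alpha = simplex_lstsq(B, comp.comp)
    return CellNicheWeights(alpha, names, cells)


def interface_score(alpha, i: int, j: int) -> np.ndarray:
    """Interface score α_i·α_j — maximal (1/4) where both niches weigh 1/2."""
    if i == j:
        raise ValueError("interface requires two distinct niches")
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    return alpha[:, i] * alpha[:, j]


def density_excluded_weights(alpha, excluded: int) -> tuple[np.ndarray, np.ndarray]:
    """Remove one niche's weight and renormalise the rest to sum to 1.

    Used to score interfaces independently of cellular density by
    excluding the low-density (fibrotic) niche.  Returns the
    renormalised weights and a mask of cells where the operation is
    undefined (the excluded niche held all the weight); those cells are
    flagged and should be dropped from interface maps.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float)).copy()
    rest = alpha.sum(axis=1) - alpha[:, excluded]
    undefined = rest <= 0
    alpha[:, excluded] = 0.0
    safe = np.where(undefined, 1.0, rest)
    alpha /= safe[:, None]
    alpha[undefined] = np.nan
    return alpha, undefined


def mixing_score(alpha, tls: int = 0, inflammatory: int = 1, cancer: int = 2) -> float:
    """Tumor-immune mixing score of one sample.

    ``m = <α_c (α_t + α_i)> / (<α_t> + <α_i>)`` with averages over the
    sample's sites; α_t, α_i, α_c are the TLS, inflammatory and cancer
    niche weights.  Samples without immune niches (denominator 0) are
    "cold" and get ``nan``; they are excluded from mixed-versus-
    compartmentalized ranking.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    a_t, a_i, a_c = alpha[:, tls], alpha[:, inflammatory], alpha[:, cancer]
    denom = a_t.mean() + a_i.mean()
    if denom <= 0:
        return float("nan")
    return float((a_c * (a_t + a_i)).mean() / denom)


def mixing_scores_by_sample(
    site_weights: np.ndarray,
    sample_ids,
    tls: int = 0,
    inflammatory: int = 1,
    cancer: int = 2,
) -> pd.Series:
    """Mixing score per sample from per-site niche weights; cold samples are nan."""
    sample_ids = np.asarray(sample_ids)
    out = {}
    for sid in pd.unique(sample_ids):
        out[sid] = mixing_score(site_weights[sample_ids == sid], tls, inflammatory, cancer)
    return pd.Series(out, name="mixing_score")


def lowest_density_niche(model_or_B) -> int:
    """Index of the niche with the lowest total cell density (the
    fibrotic niche in tumor data), used for density-excluded interfaces."""
    B, _ = _endpoints(model_or_B)
    return int(B.sum(axis=0).argmin())


def segment_map(
    cells: CellTable,
    model_or_B,
    sample_id,
    *,
    grid_step: float = 16.0,
    r: float = 25.0,
    normalization: str = "as_paper",
):
    """Niche weights on a regular lattice over one sample, for rendering.

    Evaluates the same centred-site quadratic program on grid centres;
    every returned weight vector sums to 1.

    Returns ``(xs, ys, alpha)`` with ``alpha`` of shape (ny, nx, p).
    """
    B, names = _endpoints(model_or_B)
    Lx, Ly = cells.extents[sample_id]
    xs = np.arange(grid_step / 2, Lx, grid_step)
    ys = np.arange(grid_step / 2, Ly, grid_step)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    sub = cells.subset(cells.cells["sample_id"] == sample_id)
    comp = site_composition(sub, centers, r, normalization=normalization)
    alpha = simplex_lstsq(B, comp.comp)
    return xs, ys, alpha.reshape(len(ys), len(xs), B.shape[1])


def niche_blend_image(alpha_lattice: np.ndarray, colors=None) -> np.ndarray:
    """RGB image from a lattice of niche weights by colour blending."""
    ny, nx, p = alpha_lattice.shape
    if colors is None:
        from matplotlib import colormaps

        cmap = colormaps["tab10"]
        colors = np.array([cmap(i)[:3] for i in range(p)])
    colors = np.asarray(colors, dtype=float)[:p]
    return np.clip(alpha_lattice @ colors, 0.0, 1.0)
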