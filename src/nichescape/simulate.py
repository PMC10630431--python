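"""Reaction-diffusion tissue simulator and rare-niche power analysis.

Niche-weight fields α_i(x, y) evolve on a periodic lattice under

    dα_i/dt = β α_i (α_i⁴/(α_i⁵ + K⁵) − 1/(2K)) + D ∇²α_i

a competition-diffusion system whose reaction term has two stable fixed
points (α = 0: niche absent; α ≈ 1.9276 K: niche present) so that,
started from a random one-hot field, locally one niche wins while
diffusion smooths domain boundaries into realistic contiguous niches.
Converged fields are normalised to the simplex and turned into
synthetic multiplex-histology data: site compositions ``X = B A`` for a
niche composition bank ``B``, or full synthetic cell tables with
planted niche-phenotype marker associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import brentq, linear_sum_assignment

from .archetypes import simplex_lstsq
from .io import CellTable
from .simplex import NicheModel, fit_niches

__all__ = [
    "TissueField",
    "init_field",
    "reaction_rate",
    "reaction_fixed_point",
    "simulate_tissue",
    "niche_prevalence",
    "interpolate_weights",
    "NicheBank",
    "default_niche_bank",
    "n_sites_for_images",
    "sample_sites_from_field",
    "recovery_error",
    "power_curve",
    "capture_threshold",
    "sampling_intensity_error",
    "PlantedMarker",
    "synth_cells_from_field",
]

#: capture threshold on the niche-composition RMSE ε; tied to the scale
#: of the bundled niche bank (see default_niche_bank)
EPSILON_CAPTURE = 4.5e-4


@dataclass
class TissueField:
    """Lattice of niche-weight fields α_i(x, y) with periodic boundaries."""

    alpha: np.ndarray  # (n_niches, g, g)
    L: float = 800.0  # domain size, μm
    beta: float = 1.0  # 1/day
    D: float = 40.0  # μm²/day
    t: float = 0.0  # integration time reached, days
    converged: bool = False
    normalized: bool = False

    @property
    def n_niches(self) -> int:
        return self.alpha.shape[0]

    @property
    def grid(self) -> int:
        return self.alpha.shape[1]

    @property
    def dx(self) -> float:
        return self.L / self.grid

    @property
    def K(self) -> float:
        return 1.0 / self.n_niches


def init_field(
    n_niches: int = 4,
    f: float = 0.25,
    *,
    grid: int = 50,
    L: float = 800.0,
    seed: int | np.random.Generator | None = None,
) -> TissueField:
    """One-hot initial condition with rare-niche fraction ``f``.

    At every lattice point exactly one niche has weight 1: niche 1 with
    probability ``f``, each other niche with probability
    ``(1 - f)/(n - 1)``.
    """
    if not 0 < f <= 1:
        raise ValueError("rare-niche fraction f must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.full(n_niches, (1.0 - f) / max(n_niches - 1, 1))
    probs[0] = f
    labels = rng.choice(n_niches, size=(grid, grid), p=probs)
    alpha = np.zeros((n_niches, grid, grid))
    for i in range(n_niches):
        alpha[i][labels == i] = 1.0
    return TissueField(alpha, L=L)


def reaction_rate(a, beta: float, K: float):
    """Cooperative-growth/decay reaction term of the niche dynamics."""
    a = np.asarray(a, dtype=float)
    return beta * a * (a**4 / (a**5 + K**5) - 1.0 / (2.0 * K))


def reaction_fixed_point(K: float) -> float:
    """The positive stable fixed point of the reaction term, ≈ 1.9276 K.

    Non-zero fixed points satisfy 2Kα⁴ = α⁵ + K⁵, i.e. c⁵ − 2c⁴ + 1 = 0
    with c = α/K; besides the marginal root c = 1 there is a stable root
    near c ≈ 1.9276, found here numerically.
    """
    c = brentq(lambda c: c**5 - 2 * c**4 + 1, 1.5, 2.0)
    return c * K


def _rhs(a, beta, K, D, dx):
    lap = (
        np.roll(a, 1, axis=1)
        + np.roll(a, -1, axis=1)
        + np.roll(a, 1, axis=2)
        + np.roll(a, -1, axis=2)
        - 4.0 * a
    ) / dx**2
    return beta * a * (a**4 / (a**5 + K**5) - 1.0 / (2.0 * K)) + D * lap


def simulate_tissue(
    field: TissueField,
    *,
    beta: float | None = None,
    D: float | None = None,
    t_max: float = 5000.0,
    tol: float = 1e-6,
    dt: float = 0.1,
    check_every: float = 1.0,
    negativity_tol: float = -1e-9,
) -> TissueField:
    """Integrate the reaction-diffusion system to its stationary pattern.

    Method-of-lines integration with a periodic 5-point Laplacian and
    classical fixed-step RK4 (the step is well inside the stability
    region of both reaction and diffusion at the default lattice), run
    until ``max |dα/dt| < tol`` (1/day).  At convergence the weights are
    normalised to sum to 1 at every lattice point.

    Raises if the integration undershoots below ``negativity_tol``
    (mass positivity is a property of the dynamics and of the scheme).
    """
    beta = field.beta if beta is None else beta
    D = field.D if D is None else D
    K = field.K
    dx = field.dx
    a = field.alpha.copy()
    t = field.t
    steps_per_check = max(1, int(round(check_every / dt)))
    converged = False
    step = 0
    while t < t_max:
        k1 = _rhs(a, beta, K, D, dx)
        k2 = _rhs(a + 0.5 * dt * k1, beta, K, D, dx)
        k3 = _rhs(a + 0.5 * dt * k2, beta, K, D, dx)
        k4 = _rhs(a + dt * k3, beta, K, D, dx)
        a += (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        step += 1
        if step % steps_per_check == 0:
            if a.min() < negativity_tol:
                raise FloatingPointError(
                    f"niche weight went negative ({a.min():.2e}) during integration"
                )
            if np.abs(_rhs(a, beta, K, D, dx)).max() < tol:
                converged = True
                break
    total = a.sum(axis=0)
    if (total <= 0).any():
        raise FloatingPointError("zero total weight at some lattice point; cannot normalize")
    return replace(
        field,
        alpha=a / total,
        beta=beta,
        D=D,
        t=t,
        converged=converged,
        normalized=True,
    )


def niche_prevalence(field: TissueField, i: int | None = None):
    """Prevalence of niche i: the lattice mean of α_i (spatial average).

    Returns the full vector when ``i`` is None; prevalences of a
    normalised field sum to 1.
    """
    prev = field.alpha.mean(axis=(1, 2))
    return prev if i is None else float(prev[i])


def interpolate_weights(field: TissueField, points: np.ndarray) -> np.ndarray:
    """Bilinear, periodic interpolation of α at arbitrary positions.

    Returns an (n_niches, n_points) matrix ``A``; columns of a
    normalised field sum to 1 (bilinear interpolation preserves the
    simplex constraint).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = (pts / field.dx) % field.grid  # lattice nodes at i·dx, wrap
    return np.stack(
        [
            map_coordinates(field.alpha[i], coords.T, order=1, mode="grid-wrap")
            for i in range(field.n_niches)
        ]
    )


@dataclass
class NicheBank:
    """A cell-type × niche density matrix used to synthesise compositions."""

    B: np.ndarray  # (m, p), non-negative
    cell_types: list[str]
    niche_names: list[str]

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if (self.B < 0).any():
            raise ValueError("niche bank densities must be non-negative")
        p = self.B.shape[1]
        for i in range(p):
            for j in range(i + 1, p):
                if np.allclose(self.B[:, i], self.B[:, j]):
                    raise ValueError(f"niches {i} and {j} are duplicated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=self.cell_types, columns=self.niche_names)


_BANK_CELL_TYPES = [
    "Tumor",
    "Keratin+ tumor",
    "Mesenchymal-like",
    "Endothelial",
    "Fibroblast",
    "Macrophage",
    "Monocyte",
    "Neutrophil",
    "Mono/Neu",
    "DC",
    "DC/Mono",
    "NK",
    "CD8-T",
    "CD4-T",
    "Treg",
    "B",
    "Other immune",
]

_BANK_NICHES = ["cancer", "fibrotic", "inflammatory", "TLS"]

# Densities in the units produced by the site kernel (summed 1/(2πr)
# weights): a uniform cell density λ yields a total of λ·r per site, so
# these columns correspond to roughly 130-650 cells per 800×800 μm image
# depending on the niche.  The qualitative structure: a tumor-cell-
# dominated cancer niche, a sparse fibrotic/necrotic niche, a myeloid/
# CD8-rich inflammatory niche and a B/CD4/DC tertiary lymphoid structure.
# The overall scale is calibrated so that the capture threshold
# EPSILON_CAPTURE separates accurate from failed recovery of a niche
# column (see docs/methods.md).
_BANK_B = 0.1 * np.array(
    [
        # cancer fibrotic inflam  TLS
        [0.115, 0.004, 0.010, 0.002],  # Tumor
        [0.060, 0.002, 0.004, 0.001],  # Keratin+ tumor
        [0.002, 0.012, 0.002, 0.001],  # Mesenchymal-like
        [0.004, 0.008, 0.004, 0.003],  # Endothelial
        [0.001, 0.006, 0.002, 0.001],  # Fibroblast
        [0.006, 0.006, 0.050, 0.005],  # Macrophage
        [0.001, 0.001, 0.020, 0.002],  # Monocyte
        [0.001, 0.001, 0.015, 0.001],  # Neutrophil
        [0.001, 0.001, 0.010, 0.001],  # Mono/Neu
        [0.001, 0.000, 0.004, 0.020],  # DC
        [0.001, 0.001, 0.008, 0.003],  # DC/Mono
        [0.002, 0.000, 0.004, 0.002],  # NK
        [0.003, 0.001, 0.030, 0.015],  # CD8-T
        [0.002, 0.001, 0.012, 0.050],  # CD4-T
        [0.003, 0.000, 0.008, 0.008],  # Treg
        [0.001, 0.000, 0.001, 0.080],  # B
        [0.001, 0.002, 0.008, 0.003],  # Other immune
    ]
)


def default_niche_bank() -> NicheBank:
    """The bundled synthetic 17-cell-type × 4-niche composition matrix."""
    return NicheBank(_BANK_B.copy(), list(_BANK_CELL_TYPES), list(_BANK_NICHES))


def n_sites_for_images(n_images: float, L: float = 800.0, r: float = 25.0) -> int:
    """Sites needed to cover the area of ``n_images`` L×L images: n_i L²/(πr²)."""
    return int(round(n_images * L**2 / (np.pi * r**2)))


def sample_sites_from_field(
    field: TissueField,
    bank: NicheBank,
    *,
    n_images: float = 1.0,
    r: float = 25.0,
    seed: int | np.random.Generator | None = None,
):
    """Synthetic site composition matrix ``X = B A`` from a converged field.

    Sites are placed uniformly on [0, L]² (the domain is periodic, so no
    edge exclusion applies); per-site niche weights come from bilinear
    interpolation of the field.

    Returns ``(X, A, centers)`` with ``X`` (n_s × m), ``A`` (p × n_s).
    """
    if not field.normalized:
        raise ValueError("field must be simulated to convergence and normalised first")
    rng = np.random.default_rng(seed)
    n_s = n_sites_for_images(n_images, field.L, r)
    centers = rng.uniform(0.0, field.L, size=(n_s, 2))
    A = interpolate_weights(field, centers)
    X = (bank.B @ A).T
    return X, A, centers


def recovery_error(B_hat: np.ndarray, b_target: np.ndarray) -> float:
    """RMSE between a target niche composition and its best-matching estimate.

    ``ε = sqrt(min_i ||b̂_i − b_target||² / m)``; the minimum over
    estimated niches makes the error invariant to niche relabelling.
    """
    B_hat = np.atleast_2d(np.asarray(B_hat, dtype=float))
    b = np.asarray(b_target, dtype=float)
    if B_hat.shape[0] != b.shape[0]:
        raise ValueError("cell-type dimension mismatch between estimate and target")
    d2 = ((B_hat - b[:, None]) ** 2).sum(axis=0)
    return float(np.sqrt(d2.min() / b.shape[0]))


def _fit_bank_estimate(X, p, seed, restarts, max_iter) -> np.ndarray:
    model: NicheModel = fit_niches(X, p, restarts=restarts, max_iter=max_iter, seed=seed)
    return model.endpoints_celltype


def default_f_grid(n: int = 9, lo: float = 0.04, hi: float = 0.25) -> np.ndarray:
    """Rare-niche initial fractions: ``n`` logarithmic steps from lo to hi."""
    return np.exp(np.linspace(np.log(lo), np.log(hi), n))


def power_curve(
    f_values=None,
    n_images_values=(1,),
    *,
    reps: int = 25,
    eps_threshold: float = EPSILON_CAPTURE,
    seed: int | None = 0,
    bank: NicheBank | None = None,
    n_niches: int = 4,
    grid: int = 50,
    L: float = 800.0,
    r: float = 25.0,
    restarts: int = 3,
    max_iter: int = 150,
    progress: bool = False,
) -> pd.DataFrame:
    """Probability of capturing the rare niche versus prevalence and data size.

    Full pipeline per replicate: one-hot init at rare fraction f →
    reaction-diffusion to convergence → uniform sites with bilinearly
    interpolated weights → ``X = B A`` → PCA(p−1) + p archetypes →
    recovery error ε of the rare niche (column 1 of the bank) → capture
    iff ε < ``eps_threshold``.  Fields are shared across data sizes
    within a replicate.  A failed archetype fit counts as non-capture.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bank = bank or default_niche_bank()
    f_values = default_f_grid() if f_values is None else np.asarray(f_values, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for f in f_values:
        prevs = np.empty(reps)
        eps = {ni: np.empty(reps) for ni in n_images_values}
        for rep in range(reps):
            field = simulate_tissue(init_field(n_niches, f, grid=grid, L=L, seed=rng))
            prevs[rep] = niche_prevalence(field, 0)
            for ni in n_images_values:
                X, _, _ = sample_sites_from_field(field, bank, n_images=ni, r=r, seed=rng)
                try:
                    B_hat = _fit_bank_estimate(X, n_niches, rng, restarts, max_iter)
                    eps[ni][rep] = recovery_error(B_hat, bank.B[:, 0])
                except (ValueError, np.linalg.LinAlgError):
                    eps[ni][rep] = np.inf
        for ni in n_images_values:
            rows.append(
                {
                    "f": float(f),
                    "n_images": ni,
                    "prevalence": float(prevs.mean()),
                    "prevalence_sd": float(prevs.std()),
                    "capture_prob": float((eps[ni] < eps_threshold).mean()),
                    "eps_median": float(np.median(eps[ni])),
                }
            )
        if progress:
            print(f"f={f:.3f} done")
    return pd.DataFrame(rows)


def capture_threshold(power_df: pd.DataFrame, min_prob: float = 0.5) -> pd.Series:
    """Smallest reliably-captured prevalence per data size.

    For each ``n_images``, the smallest mean prevalence whose capture
    probability reaches ``min_prob``; NaN when no condition qualifies.
    """
    out = {}
    for ni, grp in power_df.groupby("n_images"):
        ok = grp[grp["capture_prob"] >= min_prob]
        out[ni] = float(ok["prevalence"].min()) if len(ok) else float("nan")
    return pd.Series(out, name="capture_threshold_prevalence")


def sampling_intensity_error(
    field: TissueField,
    bank: NicheBank,
    intensities,
    *,
    reps: int = 10,
    reference_intensity: float = 10.0,
    r: float = 25.0,
    seed: int | None = 0,
    restarts: int = 3,
) -> pd.DataFrame:
    """Niche-composition RMSE as a function of sampling intensity.

    Reference niches are fitted once from heavily over-sampled sites
    (default 1000% of the tissue area); each intensity is then resampled
    ``reps`` times, niches re-fitted, matched to the reference by
    minimal-distance assignment, and the RMSE of their compositions
    averaged over repeats.
    """
    if max(intensities) > 10.0:
        import warnings

        warnings.warn("sampling intensity above 1000% of the tissue area")
    rng = np.random.default_rng(seed)
    area_images = lambda intensity: intensity  # n_i L²/(πr²) sites ≙ intensity·area
    X_ref, _, _ = sample_sites_from_field(
        field, bank, n_images=area_images(reference_intensity), r=r, seed=rng
    )
    p = bank.B.shape[1]
    B_ref = _fit_bank_estimate(X_ref, p, rng, restarts, 150)
    rows = []
    for intensity in intensities:
        errs = np.empty(reps)
        for rep in range(reps):
            X, _, _ = sample_sites_from_field(
                field, bank, n_images=area_images(intensity), r=r, seed=rng
            )
            B_hat = _fit_bank_estimate(X, p, rng, restarts, 150)
            cost = ((B_hat[:, :, None] - B_ref[:, None, :]) ** 2).sum(axis=0)
            ri, ci = linear_sum_assignment(cost)
            errs[rep] = np.sqrt(cost[ri, ci].sum() / B_ref.size)
        rows.append({"intensity": float(intensity), "rmse": float(errs.mean())})
    return pd.DataFrame(rows)


@dataclass
class PlantedMarker:
    """A planted monotone marker-context dependence for one cell type.

    The marker value of a cell of ``cell_type`` is
    ``baseline + slope · w + N(0, noise_sd)`` where ``w`` is the weight
    of the context (niche index, or a pair for an interface) at the
    cell's position; for cells of other types the marker is baseline
    plus noise.
    """

    cell_type: str
    marker: str
    context: tuple  # ("niche", i) or ("interface", i, j)
    slope: float = 1.0
    noise_sd: float = 0.1
    baseline: float = 0.0


def synth_cells_from_field(
    field: TissueField,
    bank: NicheBank,
    *,
    planted: list[PlantedMarker] = (),
    extra_markers: list[str] = (),
    cells_target: int | None = None,
    kernel_r: float = 25.0,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> tuple[CellTable, pd.DataFrame]:
    """Synthetic per-cell table with planted niche-phenotype associations.

    Cells are placed by an inhomogeneous Poisson process whose
    type-specific intensity is proportional to ``(B α)(x, y)``.  By
    default the absolute density is the one the bank implies (its
    entries are kernel-density units λ·r, so λ = B α / ``kernel_r``),
    which keeps per-cell niche weights consistent with the bank; pass
    ``cells_target`` to rescale the expected total instead.  Phenotypic
    marker values follow the planted monotone models (plus pure-noise
    markers from ``extra_markers``).  Returns the table and a
    ground-truth frame recording the planted associations for test
    assertions.
    """
    if not field.normalized:
        raise ValueError("field must be converged and normalised")
    rng = np.random.default_rng(seed)
    g = field.grid
    lam = np.einsum("mp,pxy->mxy", bank.B, field.alpha)  # type intensity per lattice cell
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total intensity; cannot place cells")
    if cells_target == 0:
        empty = pd.DataFrame(columns=["sample_id", "x", "y", "cell_type"])
        return (
            CellTable(
                empty,
                marker_roles={"lineage": [], "phenotypic": []},
                vocabulary=list(bank.cell_types),
                extents={"sim": (field.L, field.L)},
            ),
            pd.DataFrame(),
        )
    if cells_target is None:
        counts = rng.poisson(lam / kernel_r * field.dx**2)
    else:
        counts = rng.poisson(lam / total * cells_target)
    m_types = len(bank.cell_types)
    rows_type, rows_xy = [], []
    for ti in range(m_types):
        nz = np.argwhere(counts[ti] > 0)
        for ix, iy in nz:
            k = counts[ti, ix, iy]
            # lattice node (ix, iy) represents the patch centred on it
            xy = (np.array([ix, iy]) + rng.uniform(-0.5, 0.5, size=(k, 2))) * field.dx
            rows_xy.append(xy % field.L)
            rows_type.extend([ti] * k)
    pos = np.vstack(rows_xy) if rows_xy else np.empty((0, 2))
    types = np.asarray(rows_type)
    A = interpolate_weights(field, pos)  # (p, n)

    df = pd.DataFrame(
        {
            "sample_id": "sim",
            "x": pos[:, 0],
            "y": pos[:, 1],
            "cell_type": [bank.cell_types[t] for t in types],
        }
    )
    marker_names = sorted({pm.marker for pm in planted} | set(extra_markers))
    truth_rows = []
    for name in marker_names:
        vals = rng.normal(0.0, noise_sd, size=len(df))
        for pm in (p for p in planted if p.marker == name):
            sel = types == bank.cell_types.index(pm.cell_type)
            if pm.context[0] == "niche":
                w = A[pm.context[1], sel]
            else:
                w = A[pm.context[1], sel] * A[pm.context[2], sel]
            vals[sel] = pm.baseline + pm.slope * w + rng.normal(0.0, pm.noise_sd, size=sel.sum())
            truth_rows.append(
                {
                    "cell_type": pm.cell_type,
                    "marker": pm.marker,
                    "context": pm.context,
                    "slope": pm.slope,
                }
            )
        df[name] = vals
    table = CellTable(
        df,
        marker_roles={"lineage": [], "phenotypic": marker_names},
        vocabulary=list(bank.cell_types),
        extents={"sim": (field.L, field.L)},
    )
    return table, pd.DataFrame(truth_rows)
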