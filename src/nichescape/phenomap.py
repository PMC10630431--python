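"""Niche-phenotype mapping: marker-niche association, FDR, architecture table.

For every (cell type, phenotypic marker, context) triplet — a context
being a niche or a pairwise interface — the Spearman rank correlation ρ
between marker intensity and context weight is computed across the
cells of that type.  Only contexts with at least one cell of the type
located mostly there are eligible (α_i > 1/2 for niches,
α_i·α_j > 1/8 for interfaces).  After joint FDR control, discoveries
are pruned for niche/interface redundancy and summarised into a tissue
architecture table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .io import UNIDENTIFIED, CellTable
from .segmentation import CellNicheWeights

__all__ = [
    "context_name",
    "context_weight",
    "eligible_contexts",
    "spearman_association",
    "associations",
    "estimate_pi0",
    "qvalues",
    "fdr_filter",
    "apply_marker_exclusions",
    "summarize_architecture",
    "robust_cell_types",
    "rho_matrix",
    "niche_contribution",
    "phenotype_clusters",
]

NICHE_THRESHOLD = 0.5  # a cell is "mostly in" a niche when α_i > 1/2
INTERFACE_THRESHOLD = 0.125  # = (1/2)·(1/2)², half the maximal product


def context_name(ctx: tuple, niche_names: list[str]) -> str:
    if ctx[0] == "niche":
        return niche_names[ctx[1]]
    return "x".join(niche_names[i] for i in ctx[1:])


def context_weight(alpha: np.ndarray, ctx: tuple) -> np.ndarray:
    """Weight of a context per cell: α_i for a niche, Πα for an interface."""
    if ctx[0] == "niche":
        return alpha[:, ctx[1]]
    w = alpha[:, ctx[1]].copy()
    for i in ctx[2:]:
        w = w * alpha[:, i]
    return w


def all_contexts(p: int, include_higher_order: bool = False) -> list[tuple]:
    out = [("niche", i) for i in range(p)]
    out += [("interface", i, j) for i, j in combinations(range(p), 2)]
    if include_higher_order:
        for order in range(3, p + 1):
            out += [("interface", *c) for c in combinations(range(p), order)]
    return out


def eligible_contexts(alpha: np.ndarray, p: int | None = None, include_higher_order: bool = False) -> list[tuple]:
    """Contexts testable for one cell type, given that type's cell weights.

    A niche is eligible iff some cell of the type has α_i > 1/2; an
    interface iff some cell has α_i·α_j > 1/8 (strict inequalities).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    p = alpha.shape[1] if p is None else p
    keep = []
    for ctx in all_contexts(p, include_higher_order):
        w = context_weight(alpha, ctx)
        if ctx[0] == "niche":
            thr = NICHE_THRESHOLD
        else:
            # half the maximal product (1/o)^o for an order-o interface;
            # 1/8 for the pairwise case
            o = len(ctx) - 1
            thr = 0.5 * (1.0 / o) ** o
        if len(w) and w.max() > thr:
            keep.append(ctx)
    return keep


def spearman_association(marker: np.ndarray, weight: np.ndarray) -> tuple[float, float]:
    """Spearman ρ (mid-rank ties) with a two-sided asymptotic t-test p-value.

    Degenerate inputs (a constant vector) make the correlation
    undefined; such associations are recorded as ρ = 0, p = 1 so they
    can never become discoveries.
    """
    marker = np.asarray(marker, dtype=float)
    weight = np.asarray(weight, dtype=float)
    n = len(marker)
    if n < 4:
        raise ValueError("need at least 4 cells for a Spearman association")
    if np.unique(marker).size < 2 or np.unique(weight).size < 2:
        return 0.0, 1.0
    rho = stats.spearmanr(marker, weight).statistic
    if not np.isfinite(rho):
        return 0.0, 1.0
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-12:  # perfectly monotone up to rounding
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def associations(
    cells: CellTable,
    weights: CellNicheWeights,
    *,
    markers: list[str] | None = None,
    include_higher_order: bool = False,
    min_cells: int = 4,
) -> pd.DataFrame:
    """Spearman associations for all (cell type, marker, eligible context) triplets.

    Cells labelled Unidentified (or typed outside the vocabulary) are
    discarded.  Returns one row per tested triplet with columns
    ``cell_type, marker, context, context_label, rho, p, n``.
    """
    markers = markers if markers is not None else cells.phenotypic_markers
    if not markers:
        raise ValueError("no phenotypic markers declared")
    mask = weights.phenomapping_mask()
    ct_col = cells.cells["cell_type"].to_numpy()
    rows = []
    for ct in np.unique(ct_col[mask]):
        sel = mask & (ct_col == ct)
        if sel.sum() < min_cells:
            continue
        alpha = weights.alpha[sel]
        ctxs = eligible_contexts(alpha, weights.p, include_higher_order)
        sub = cells.cells.loc[sel, markers]
        for ctx in ctxs:
            w = context_weight(alpha, ctx)
            for m in markers:
                rho, p = spearman_association(sub[m].to_numpy(float), w)
                rows.append(
                    {
                        "cell_type": ct,
                        "marker": m,
                        "context": ctx,
                        "context_label": context_name(ctx, weights.niche_names),
                        "rho": rho,
                        "p": p,
                        "n": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)


def estimate_pi0(pvals: np.ndarray) -> float:
    """Estimate of the null proportion π0 from the p-value distribution.

    Uses the standard smoother: the natural estimate
    ``#{p > λ} / (m(1-λ))`` over a λ grid, smoothed by a cubic
    polynomial and evaluated at the largest λ.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > v).sum() / (m * (1 - v)) for v in lam])
    coef = np.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lam[-1]))
    return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))


def qvalues(pvals: np.ndarray, *, method: str = "qvalue") -> np.ndarray:
    """Tail-area false-discovery-rate q-values.

    ``method="qvalue"`` computes ``q_(i) = π0 · m · p_(i) / i`` with a
    monotonicity correction from the largest p-value down;
    ``method="bh"`` is Benjamini–Hochberg (π0 = 1).
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.empty(0)
    pi0 = 1.0 if method == "bh" else estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def fdr_filter(
    assoc: pd.DataFrame,
    q_max: float = 0.01,
    rho_min: float = 0.3,
) -> pd.DataFrame:
    """Joint FDR over all tested triplets; retain q < q_max and ρ ≥ rho_min.

    With fewer than 100 p-values the π0 estimate is unreliable and the
    filter falls back to Benjamini–Hochberg.
    """
    assoc = assoc.copy()
    if len(assoc) < 100:
        warnings.warn("fewer than 100 p-values; falling back to Benjamini-Hochberg FDR")
        assoc["q"] = multipletests(assoc["p"].to_numpy(), method="fdr_bh")[1] if len(assoc) else []
    else:
        assoc["q"] = qvalues(assoc["p"].to_numpy())
    return assoc[(assoc["q"] < q_max) & (assoc["rho"] >= rho_min)].reset_index(drop=True)


def apply_marker_exclusions(assoc: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Drop associations matching an exclusion list before summarisation.

    Each exclusion is a dict with keys ``marker``, ``niche`` (niche
    index or name), optional ``include_interfaces`` (default True: the
    niche and every interface bordering it) and optional ``cell_type``.
    Used e.g. to remove markers subject to spatial signal spill-over
    from a dominant cell population.  Unknown markers produce a warning
    and are ignored.
    """
    if not exclusions:
        return assoc
    keep = np.ones(len(assoc), dtype=bool)
    known_markers = set(assoc["marker"].unique())
    for exc in exclusions:
        marker = exc["marker"]
        if marker not in known_markers:
            warnings.warn(f"exclusion names unknown marker {marker!r}; ignored")
            continue
        niche = exc["niche"]
        if isinstance(niche, str):
            labels = assoc["context_label"]
            if exc.get("include_interfaces", True):
                in_ctx = labels.str.split("x").apply(lambda parts: niche in parts)
            else:
                in_ctx = labels == niche
        else:
            in_ctx = assoc["context"].apply(
                lambda c: niche in c[1:] if exc.get("include_interfaces", True) else c == ("niche", niche)
            )
        hit = (assoc["marker"] == marker) & in_ctx
        if "cell_type" in exc and exc["cell_type"] is not None:
            hit &= assoc["cell_type"] == exc["cell_type"]
        keep &= ~hit.to_numpy()
    return assoc[keep].reset_index(drop=True)


@dataclass
class ArchitectureTable:
    """Pruned niche/interface → (cell type, marker) association summary."""

    table: pd.DataFrame  # columns context_label, cell_type, marker, rho, q
    robust_presence: pd.DataFrame | None = None  # columns context_label, cell_type

    def to_csv(self, path, overwrite: bool = False):
        from .io import save_table

        save_table(self.table, path, overwrite)


def _borders(ctx_a: tuple, ctx_b: tuple) -> bool:
    """True when a niche borders an interface (shares an index)."""
    if ctx_a[0] == ctx_b[0]:
        return False
    niche = ctx_a if ctx_a[0] == "niche" else ctx_b
    iface = ctx_b if ctx_a[0] == "niche" else ctx_a
    return niche[1] in iface[1:]


def summarize_architecture(discoveries: pd.DataFrame, niche_names: list[str] | None = None) -> ArchitectureTable:
    """Redundancy-pruned architecture table.

    For every (cell type, marker) reported both in a niche and in an
    interface bordering it, only the context with the larger ρ is kept
    (on an exact tie the niche wins, as the more parsimonious context,
    and the tie is logged).
    """
    if discoveries.empty:
        return ArchitectureTable(discoveries.copy())
    keep = np.ones(len(discoveries), dtype=bool)
    for _, grp in discoveries.groupby(["cell_type", "marker"], observed=True):
        if len(grp) < 2:
            continue
        for ia, ib in combinations(grp.index, 2):
            ca, cb = discoveries.at[ia, "context"], discoveries.at[ib, "context"]
            if not _borders(ca, cb):
                continue
            ra, rb = discoveries.at[ia, "rho"], discoveries.at[ib, "rho"]
            if ra == rb:
                loser = ia if ca[0] == "interface" else ib
                warnings.warn(
                    f"exact rho tie for {discoveries.at[ia, 'cell_type']}/"
                    f"{discoveries.at[ia, 'marker']}; keeping the niche"
                )
            else:
                loser = ia if ra < rb else ib
            keep[discoveries.index.get_loc(loser)] = False
    pruned = discoveries[keep].reset_index(drop=True)
    cols = [c for c in ["context_label", "cell_type", "marker", "rho", "q"] if c in pruned.columns]
    order = pruned["context"].apply(lambda c: (0 if c[0] == "niche" else 1, c[1:]))
    pruned = pruned.loc[order.sort_values(kind="mergesort").index, cols + ["context"]]
    return ArchitectureTable(pruned.reset_index(drop=True))


def robust_cell_types(
    site_comp,
    site_alpha: np.ndarray,
    niche: int,
    top_fraction: float = 0.01,
) -> list[str]:
    """Cell types robustly present in a niche.

    Among the ``top_fraction`` of sites with the highest weight for the
    niche, a cell type is reported when its mean abundance is at least
    one standard deviation away from zero (mean/SD ≥ 1; a positive mean
    with zero SD also qualifies).
    """
    comp = np.asarray(getattr(site_comp, "comp", site_comp), dtype=float)
    types = getattr(site_comp, "cell_types", [f"type_{i}" for i in range(comp.shape[1])])
    n = comp.shape[0]
    k = max(1, int(round(top_fraction * n)))
    top = np.argsort(-np.asarray(site_alpha)[:, niche], kind="mergesort")[:k]
    sub = comp[top]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    out = []
    for t, mu, s in zip(types, mean, sd):
        if s == 0:
            if mu > 0:
                out.append(t)
        elif mu / s >= 1.0:
            out.append(t)
    return out


def rho_matrix(assoc: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready matrix of ρ: rows contexts, columns cell_type:marker.

    Untested (ineligible) combinations appear as 0, as in the standard
    heatmap convention.
    """
    if assoc.empty:
        return pd.DataFrame()
    df = assoc.copy()
    df["col"] = df["cell_type"].astype(str) + ":" + df["marker"].astype(str)
    return df.pivot_table(index="context_label", columns="col", values="rho", fill_value=0.0)


def niche_contribution(rho_mat: pd.DataFrame) -> pd.Series:
    """Per-context contribution to phenotypic structure: Σρ² over its row."""
    return (rho_mat**2).sum(axis=1).rename("sum_rho2")


@dataclass
class PhenotypeClusterResult:
    labels: np.ndarray  # cluster id per cell (1..k)
    cluster_metrics: pd.DataFrame  # cluster × niche sensitivity/specificity
    predictor_auc: dict  # niche index -> ROC AUC of the linear predictor
    predictor_coefs: dict  # niche index -> OLS coefficients over markers


def phenotype_clusters(
    markers_df: pd.DataFrame,
    alpha: np.ndarray,
    k: int = 10,
    *,
    niche_membership: float = 0.5,
    niche_names: list[str] | None = None,
) -> PhenotypeClusterResult:
    """Spatially-agnostic phenotype clustering and its niche predictiveness.

    Marker intensities (cells of one type) are Z-scored, clustered
    hierarchically (Euclidean distance, Ward linkage) and cut into ``k``
    groups.  A cell belongs to a niche when its weight is at least
    ``niche_membership``; each cluster's sensitivity and specificity in
    predicting each niche are tabulated.  As an upper bound, a linear
    predictor of the niche weight from all markers is trained and its
    ROC AUC against niche membership reported.
    """
    X = markers_df.to_numpy(float)
    n, _ = X.shape
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} cells")
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    p = alpha.shape[1]
    names = niche_names or [f"niche_{i + 1}" for i in range(p)]
    sd = X.std(axis=0, ddof=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    labels = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    member = alpha >= niche_membership
    rows = []
    for c in range(1, labels.max() + 1):
        in_c = labels == c
        for i in range(p):
            tp = int((in_c & member[:, i]).sum())
            fn = int((~in_c & member[:, i]).sum())
            fp = int((in_c & ~member[:, i]).sum())
            tn = int((~in_c & ~member[:, i]).sum())
            rows.append(
                {
                    "cluster": c,
                    "niche": names[i],
                    "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                    "specificity": tn / (tn + fp) if tn + fp else np.nan,
                }
            )
    metrics = pd.DataFrame(rows)

    from sklearn.metrics import roc_auc_score

    Zd = np.column_stack([np.ones(n), Z])
    auc, coefs = {}, {}
    for i in range(p):
        beta, *_ = np.linalg.lstsq(Zd, alpha[:, i], rcond=None)
        coefs[i] = beta
        pred = Zd @ beta
        if member[:, i].any() and not member[:, i].all():
            auc[i] = float(roc_auc_score(member[:, i], pred))
        else:
            auc[i] = np.nan
    return PhenotypeClusterResult(labels, metrics, auc, coefs)
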