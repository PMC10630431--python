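"""Cell tables, run configuration and result serialization.

The central input is a per-cell table from segmented multiplex imaging:
sample id, (x, y) centroid in μm, an assigned cell type from a fixed
vocabulary, and marker intensities.  Markers are partitioned into
*lineage* markers (used upstream to call cell types) and *phenotypic*
markers (correlated with niches downstream); mixing the two would bias
niche-phenotype mapping, so the partition is validated explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CellTable",
    "load_cell_table",
    "validate_marker_partition",
    "MarkerPartitionReport",
    "RunConfig",
    "save_json",
    "load_json",
    "save_table",
]

#: cells with this type label are retained in the table but excluded
#: from niche-phenotype mapping
UNIDENTIFIED = "Unidentified"

DEFAULT_SCHEMA = {
    "sample_id": "SampleID",
    "x": "cell_x",
    "y": "cell_y",
    "cell_type": "Group",
}


class SchemaError(ValueError):
    """A mandatory column is missing or mis-declared."""


@dataclass
class CellTable:
    """Validated per-cell table for one or more samples.

    ``cells`` holds the canonical columns ``sample_id, x, y, cell_type``
    plus one column per marker.  ``vocabulary`` fixes the cell-type set
    (identical across samples of a run); cells typed outside it are
    retained but flagged via :meth:`in_vocabulary`.
    """

    cells: pd.DataFrame
    marker_roles: dict = dc_field(default_factory=lambda: {"lineage": [], "phenotypic": []})
    vocabulary: list[str] | None = None
    extents: dict | None = None

    def __post_init__(self):
        required = ["sample_id", "x", "y", "cell_type"]
        for col in required:
            if col not in self.cells.columns:
                raise SchemaError(f"cell table is missing mandatory column {col!r}")
        if self.vocabulary is None:
            self.vocabulary = sorted(
                t for t in self.cells["cell_type"].unique() if t != UNIDENTIFIED
            )
        self.marker_roles = {
            "lineage": list(self.marker_roles.get("lineage", [])),
            "phenotypic": list(self.marker_roles.get("phenotypic", [])),
        }
        if self.extents is None:
            self.extents = {
                sid: (float(np.ceil(g["x"].max())), float(np.ceil(g["y"].max())))
                for sid, g in self.cells.groupby("sample_id", observed=True)
            }
        for sid, g in self.cells.groupby("sample_id", observed=True):
            Lx, Ly = self.extents[sid]
            if (g["x"] < 0).any() or (g["y"] < 0).any() or (g["x"] > Lx).any() or (g["y"] > Ly).any():
                raise ValueError(f"sample {sid!r} has cells outside its declared extent {(Lx, Ly)}")

    @property
    def markers(self) -> list[str]:
        meta = {"sample_id", "x", "y", "cell_type"}
        return [c for c in self.cells.columns if c not in meta]

    @property
    def phenotypic_markers(self) -> list[str]:
        return list(self.marker_roles["phenotypic"])

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def in_vocabulary(self) -> pd.Series:
        """Boolean mask of cells whose type belongs to the vocabulary."""
        return self.cells["cell_type"].isin(self.vocabulary)

    def sample_ids(self):
        return list(self.cells["sample_id"].unique())

    def subset(self, mask) -> "CellTable":
        return CellTable(
            self.cells[mask].reset_index(drop=True),
            marker_roles=self.marker_roles,
            vocabulary=self.vocabulary,
            extents=self.extents,
        )


def load_cell_table(
    path,
    schema: dict | None = None,
    *,
    marker_columns: list[str] | None = None,
    marker_roles: dict | None = None,
    vocabulary: list[str] | None = None,
    extents: dict | None = None,
) -> CellTable:
    """Read a per-cell CSV into a validated :class:`CellTable`.

    ``schema`` maps canonical names (``sample_id, x, y, cell_type``) to
    the file's column names; the default follows common segmented-data
    exports.  ``marker_columns`` defaults to every remaining column.
    Cells typed outside the vocabulary are kept but flagged; they are
    dropped only where a downstream step requires it.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [k for k, v in schema.items() if v not in df.columns]
    if missing:
        names = ", ".join(f"{k!r} (column {schema[k]!r})" for k in missing)
        raise SchemaError(f"missing mandatory column(s): {names}")
    out = pd.DataFrame(
        {k: df[v] for k, v in schema.items()}
    )
    for coord in ("x", "y"):
        vals = pd.to_numeric(out[coord], errors="coerce")
        bad = vals.isna() & out[coord].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric {coord!r} coordinate at row {row}")
        out[coord] = vals
    out["cell_type"] = out["cell_type"].astype(str)
    if marker_columns is None:
        marker_columns = [c for c in df.columns if c not in set(schema.values())]
    for m in marker_columns:
        out[m] = pd.to_numeric(df[m], errors="coerce")
    return CellTable(
        out,
        marker_roles=marker_roles or {"lineage": [], "phenotypic": list(marker_columns)},
        vocabulary=vocabulary,
        extents=extents,
    )


@dataclass
class MarkerPartitionReport:
    ok: bool
    overlap: list[str]
    unassigned: list[str]

    def __str__(self):
        if self.ok and not self.unassigned:
            return "marker partition OK"
        parts = []
        if self.overlap:
            parts.append(f"markers in both roles: {', '.join(self.overlap)}")
        if self.unassigned:
            parts.append(f"markers with no role: {', '.join(self.unassigned)}")
        return "; ".join(parts)


def validate_marker_partition(table: CellTable) -> MarkerPartitionReport:
    """Check that lineage and phenotypic marker sets partition the markers.

    Overlap between the two roles is an error (the same signal would
    both define cell types and be tested for niche association);
    markers present in the table but assigned to neither role produce a
    warning only.
    """
    lineage = set(table.marker_roles["lineage"])
    pheno = set(table.marker_roles["phenotypic"])
    overlap = sorted(lineage & pheno)
    unassigned = sorted(set(table.markers) - lineage - pheno)
    report = MarkerPartitionReport(ok=not overlap, overlap=overlap, unassigned=unassigned)
    if unassigned:
        warnings.warn(f"markers with no declared role: {', '.join(unassigned)}")
    return report


@dataclass
class RunConfig:
    """Parameters of one analysis run, serializable to YAML.

    ``pca_dims_d`` defaults to ``n_niches_p - 1``: p − 1 dimensions are
    generally needed to describe a simplex with p endpoints.
    """

    site_radius_r: float = 25.0
    sites_per_sample: int | None = 100
    sampling_intensity: float | None = None
    n_niches_p: int = 4
    pca_dims_d: int | None = None
    rng_seed: int = 0
    kernel_normalization: str = "as_paper"
    thresholds: dict = dc_field(
        default_factory=lambda: {
            "rho_min": 0.3,
            "q_max": 0.01,
            "niche_membership": 0.5,
            "interface_membership": 0.125,
        }
    )
    marker_exclusions: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.pca_dims_d is None:
            self.pca_dims_d = self.n_niches_p - 1
        for name, v in self.thresholds.items():
            if not 0 < v <= 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1]")

    @property
    def d(self) -> int:
        return self.pca_dims_d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path, overwrite: bool = False):
        _check_overwrite(path, overwrite)
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def _check_overwrite(path, overwrite: bool):
    if Path(path).exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")


def save_json(obj: dict, path, overwrite: bool = False):
    """Write a JSON artifact (e.g. a serialized niche model), refusing to
    overwrite unless asked."""
    _check_overwrite(path, overwrite)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_table(df: pd.DataFrame, path, overwrite: bool = False):
    """Write a tabular artifact as CSV, refusing to overwrite unless asked."""
    _check_overwrite(path, overwrite)
    df.to_csv(path, index=False)
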