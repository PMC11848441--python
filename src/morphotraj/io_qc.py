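"""Feature-table I/O, quality control and profile aggregation.

The universal currency of the pipeline is a *feature table*: one row per
segmented cell, a block of metadata columns (plate / well / field / role /
compound / dose / timepoint / replicate plus the two area measurements used
for cell-level QC) and a block of named numeric morphology features.
Tables are plain delimited text (comma or tab, sniffed on read) so that
CellProfiler-style exports and the synthetic generator share one format.

Quality control happens at two scopes, mirroring standard high-content
practice: whole images (fields of view) are dropped on per-image summary
metrics (cell count, a designated intensity median, a focus proxy), and
individual cells are dropped on nuclear / whole-cell area bounds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "ROLES",
    "FeatureTable",
    "QcRule",
    "load_feature_table",
    "load_plate_map",
    "compute_image_metrics",
    "apply_image_qc",
    "apply_cell_qc",
    "default_area_bounds",
    "aggregate_profiles",
]

METADATA_COLUMNS = [
    "cell_id",
    "plate",
    "well",
    "field",
    "role",
    "compound",
    "dose",
    "timepoint",
    "replicate",
    "nuclear_area",
    "cell_area",
]

#: Controlled vocabulary for the ``role`` column.
ROLES = frozenset(
    {
        "progenitor_control",
        "undifferentiated_control",
        "differentiated_control",
        "treatment",
        "sample",
    }
)

PLATE_MAP_COLUMNS = ["well", "role", "compound", "dose", "timepoint", "replicate"]

WELL_ROWS = "ABCDEFGHIJKLMNOP"


def normalize_well(well: str) -> str:
    """Canonicalise a 384-well name: rows A-P, columns 1-24, case-insensitive.

    ``a01`` and ``A1`` both map to ``A1``.
    """
    w = str(well).strip().upper()
    row, col = w[0], w[1:]
    if row not in WELL_ROWS or not col.isdigit() or not 1 <= int(col) <= 24:
        raise ValueError(f"not a valid 384-well name: {well!r}")
    return f"{row}{int(col)}"


class FeatureTable:
    """Cells-by-features table with per-cell metadata.

    Parameters
    ----------
    data
        DataFrame containing every column in :data:`METADATA_COLUMNS`
        followed by numeric feature columns.  Feature columns are every
        column not in the metadata block, unless ``feature_names`` is given.
    """

    def __init__(self, data: pd.DataFrame, feature_names: Sequence[str] | None = None):
        missing = [c for c in METADATA_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing metadata column(s): {missing}")
        if feature_names is None:
            feature_names = [c for c in data.columns if c not in METADATA_COLUMNS]
        if not feature_names:
            raise ValueError("feature table has no feature columns")
        if data["cell_id"].duplicated().any():
            dup = data.loc[data["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        bad_roles = set(data["role"].dropna().unique()) - ROLES
        if bad_roles:
            raise ValueError(f"unknown role value(s): {sorted(bad_roles)}")
        for c in feature_names:
            if not pd.api.types.is_numeric_dtype(data[c]):
                raise ValueError(f"feature column {c!r} is not numeric")
        self.data = data.reset_index(drop=True)
        self.feature_names = list(feature_names)

    # -- accessors ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[METADATA_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def X(self) -> np.ndarray:
        """Feature block as a float ndarray (cells x features)."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def image_ids(self) -> pd.Series:
        d = self.data
        return (
            d["plate"].astype(str) + ":" + d["well"].astype(str) + ":" + d["field"].astype(str)
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.feature_names)

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].reset_index(drop=True), self.feature_names)

    def with_features(self, X: np.ndarray) -> "FeatureTable":
        """Return a copy whose feature block is replaced by ``X`` (same shape)."""
        out = self.data.copy()
        out[self.feature_names] = np.asarray(X, dtype=float)
        return FeatureTable(out, self.feature_names)

    # -- I/O ---------------------------------------------------------------
    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FeatureTable {self.n_cells} cells x {len(self.feature_names)} features>"


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate map: well, role, compound, dose, timepoint, replicate."""
    pm = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in PLATE_MAP_COLUMNS if c not in pm.columns]
    if missing:
        raise ValueError(f"plate map missing column(s): {missing}")
    pm = pm.copy()
    pm["well"] = pm["well"].map(normalize_well)
    if pm["well"].duplicated().any():
        dup = pm.loc[pm["well"].duplicated(), "well"].iloc[0]
        raise ValueError(f"plate map lists well {dup} more than once")
    return pm


def load_feature_table(path: str | Path, plate_map_path: str | Path | None = None) -> FeatureTable:
    """Load a delimited per-cell feature file, optionally joining a plate map.

    Without a plate map the file itself must carry the full metadata block.
    With one, the file needs only cell_id / plate / well / field /
    nuclear_area / cell_area and the features; role, compound, dose,
    timepoint and replicate are taken from the plate map.  Every well in the
    file must appear in the plate map.
    """
    sep = _sniff_sep(path)
    data = pd.read_csv(path, sep=sep)
    if plate_map_path is not None:
        pm = load_plate_map(plate_map_path)
        base_cols = ["cell_id", "plate", "well", "field", "nuclear_area", "cell_area"]
        missing = [c for c in base_cols if c not in data.columns]
        if missing:
            raise ValueError(f"feature file missing column(s): {missing}")
        data = data.drop(columns=[c for c in PLATE_MAP_COLUMNS[1:] if c in data.columns])
        data["well"] = data["well"].map(normalize_well)
        unmatched = sorted(set(data["well"]) - set(pm["well"]))
        if unmatched:
            raise ValueError(f"well(s) absent from plate map: {unmatched}")
        data = data.merge(pm, on="well", how="left")
    order = METADATA_COLUMNS + [c for c in data.columns if c not in METADATA_COLUMNS]
    return FeatureTable(data[order])


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcRule:
    """Interval filter on a QC metric; observations outside [lower, upper] fail."""

    metric: str
    lower: float = -np.inf
    upper: float = np.inf
    scope: str = "image"

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"QcRule bounds inverted: {self.lower} > {self.upper}")
        if self.scope not in {"image", "cell"}:
            raise ValueError(f"unknown QC scope {self.scope!r}")


def compute_image_metrics(table: FeatureTable, intensity_feature: str | None = None) -> pd.DataFrame:
    """Per-image robust summary metrics used by image-level QC.

    Metrics per field of view: ``n_cells``; ``median_intensity`` (median of
    a designated intensity feature, default the first feature column); and
    ``focus_proxy`` (median across features of the per-feature variance in
    the image — defocused or empty fields collapse feature variance).
    """
    if intensity_feature is None:
        intensity_feature = table.feature_names[0]
    if intensity_feature not in table.feature_names:
        raise ValueError(f"unknown intensity feature {intensity_feature!r}")
    d = table.data.copy()
    d["_image"] = table.image_ids()
    grouped = d.groupby("_image", sort=True)
    n = grouped.size().rename("n_cells")
    med = grouped[intensity_feature].median().rename("median_intensity")
    var = grouped[table.feature_names].var(ddof=0)
    focus = var.median(axis=1).fillna(0.0).rename("focus_proxy")
    return pd.concat([n, med, focus], axis=1).reset_index(names="image_id")


def apply_image_qc(
    table: FeatureTable,
    rules: Iterable[QcRule],
    intensity_feature: str | None = None,
) -> tuple[FeatureTable, list[str]]:
    """Remove all cells of images failing any image-scope rule.

    Returns the filtered table and the sorted list of removed image ids.
    Idempotent: re-applying the same rules is the identity.
    """
    rules = list(rules)
    if not rules:
        return table.copy(), []
    metrics = compute_image_metrics(table, intensity_feature)
    failing: set[str] = set()
    for rule in rules:
        if rule.scope != "image":
            raise ValueError(f"apply_image_qc got a {rule.scope}-scope rule")
        if rule.metric not in metrics.columns:
            raise ValueError(f"rule references unknown image metric {rule.metric!r}")
        vals = metrics[rule.metric]
        bad = metrics.loc[(vals < rule.lower) | (vals > rule.upper), "image_id"]
        failing.update(bad)
    keep = ~table.image_ids().isin(failing)
    return table.subset(keep.to_numpy()), sorted(failing)


def default_area_bounds(
    table: FeatureTable,
    roles: Sequence[str] = ("progenitor_control", "undifferentiated_control", "differentiated_control"),
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> dict[str, tuple[float, float]]:
    """Percentile area bounds estimated from control cells (defaults: [1st, 99th])."""
    ctrl = table.data[table.data["role"].isin(roles)]
    if ctrl.empty:
        ctrl = table.data
    out = {}
    for col in ("nuclear_area", "cell_area"):
        lo, hi = np.percentile(ctrl[col].to_numpy(dtype=float), [lower_pct, upper_pct])
        out[col] = (float(lo), float(hi))
    return out


def apply_cell_qc(
    table: FeatureTable,
    area_bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[FeatureTable, list]:
    """Drop cells whose nuclear or whole-cell area is outside the bounds.

    ``area_bounds`` maps ``nuclear_area`` / ``cell_area`` to (lower, upper);
    when None the [1st, 99th] percentile bounds of control cells are used.
    """
    if area_bounds is None:
        area_bounds = default_area_bounds(table)
    keep = np.ones(table.n_cells, dtype=bool)
    for col, (lo, hi) in area_bounds.items():
        if lo > hi:
            raise ValueError(f"area bounds inverted for {col}: {lo} > {hi}")
        v = table.data[col].to_numpy(dtype=float)
        keep &= (v >= lo) & (v <= hi)
    removed = table.data.loc[~keep, "cell_id"].tolist()
    return table.subset(keep), removed


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_WELL_META = ["plate", "well", "role", "compound", "dose", "timepoint", "replicate"]


def aggregate_profiles(table: FeatureTable, level: str = "well") -> pd.DataFrame:
    """Aggregate per-cell features to image- or well-level profiles.

    image level
        per-feature median and sample standard deviation (SD of a single
        observation is defined as 0), so 1004 input features yield 2008
        profile columns; ``n_cells`` recorded.
    well level
        per-feature median over the well's cells plus ``n_cells``.
    """
    if table.n_cells == 0:
        raise ValueError("cannot aggregate an empty table")
    d = table.data
    if level == "image":
        keys = ["plate", "well", "field"]
        g = d.groupby(keys, sort=True)
        med = g[table.feature_names].median()
        med.columns = [f"{c}_median" for c in med.columns]
        sd = g[table.feature_names].std(ddof=1).fillna(0.0)
        sd.columns = [f"{c}_sd" for c in sd.columns]
        prof = pd.concat([med, sd], axis=1)
        prof["n_cells"] = g.size()
        meta = g[[c for c in _WELL_META if c not in keys]].first()
        return pd.concat([meta, prof], axis=1).reset_index()
    if level == "well":
        keys = ["plate", "well"]
        g = d.groupby(keys, sort=True)
        prof = g[table.feature_names].median()
        prof["n_cells"] = g.size()
        meta = g[[c for c in _WELL_META if c not in keys]].first()
        return pd.concat([meta, prof], axis=1).reset_index()
    raise ValueError(f"unknown aggregation level {level!r}")
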