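"""Synthetic bifurcating-differentiation generator with ground truth.

Emulates the statistical structure of a high-content (Cell Painting style)
liver-progenitor differentiation experiment: single cells move along a
latent differentiation time ``t`` and, past a branch time ``t_b``, commit to
one of two morphologically distinct fates — hepatocyte-like (larger cell and
nuclear area, brighter mitochondrial-intensity analog) or biliary-like
(smaller, dimmer).  Features follow

    x = W_pre . phi(t) + D_branch . max(0, t - t_b) + eps,

where ``phi`` is a fixed 3-component monotone (degree-1 I-spline) basis in
``t``, ``W_pre`` is shared by all branches, the divergence loadings
``D_hep`` / ``D_bil`` are branch specific and linear in ``t - t_b`` (so the
true branch point is identifiable), and ``eps ~ N(0, noise_sd^2 I)``.
Designated marker features track the cell-area / nuclear-area /
mitochondrial analogs deterministically so lineages can be identified the
way a biologist would, from known morphological markers.

Two experiment designs are generated on top of this latent model:

* a 20-timepoint differentiation *atlas* time course (one plate per
  timepoint, equal cells per timepoint, timepoint-1 cells doubling as
  progenitor anchors), and
* a 384-well screening *plate* with 16 wells per control class, 4 images
  per well, compound treatments whose realized effect follows a 4PL curve
  in log-dose, spiked-in progenitor anchors, injected doublets and
  QC-failing images.

Every draw is deterministic given the config seed, and each emitted table
is paired with a :class:`SyntheticTruth` carrying the latent state — the
oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_qc import FeatureTable, METADATA_COLUMNS, WELL_ROWS

__all__ = [
    "T_MAX",
    "AtlasSimConfig",
    "PlateSimConfig",
    "CompoundEffect",
    "Treatment",
    "SyntheticTruth",
    "monotone_basis",
    "simulate_atlas",
    "simulate_plate",
    "inject_doublets",
    "four_pl_fraction",
]

#: Span of the latent differentiation time axis (arbitrary units).  The
#: atlas time course samples 20 equally spaced timepoints on [0, T_MAX].
T_MAX = 10.0

# Loadings are drawn once from a fixed generator so that atlas and screen
# simulations share one feature geometry (a prerequisite for merging them),
# independent of the per-run sampling seed.
_STRUCTURE_SEED = 20240101

# Latent area / intensity model (squared pixels; arbitrary intensity units).
_CELL_AREA_0, _CELL_AREA_SLOPE = 400.0, 30.0
_NUC_AREA_0, _NUC_AREA_SLOPE = 120.0, 8.0
_MITO_0, _MITO_SLOPE = 1.0, 0.05
_HEP_CELL_GAIN, _BIL_CELL_LOSS = 60.0, 20.0
_HEP_NUC_GAIN, _BIL_NUC_LOSS = 15.0, 5.0
_HEP_MITO_GAIN, _BIL_MITO_LOSS = 0.30, 0.05


@dataclass(frozen=True)
class AtlasSimConfig:
    """Conditions of the simulated differentiation time course."""

    n_timepoints: int = 20
    cells_per_timepoint: int = 500
    n_features: int = 788
    t_branch_true: float = 3.0
    p_hep: float = 0.5
    noise_sd: float = 0.8
    divergence_sd: float = 0.3
    #: biological asynchrony: cells imaged at one timepoint spread around the
    #: nominal latent time, so the population forms a continuum rather than
    #: discrete beads (differentiating cultures are never synchronized)
    t_jitter_sd: float = 0.4
    marker_indices: tuple[int, int, int] = (0, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 2 or self.cells_per_timepoint < 1:
            raise ValueError("counts must be positive (n_timepoints >= 2)")
        if self.n_features < 10:
            raise ValueError("n_features must be >= 10")
        if not 0.0 <= self.p_hep <= 1.0:
            raise ValueError("p_hep must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        mk = self.marker_indices
        if len(set(mk)) != len(mk) or any(not 0 <= m < self.n_features for m in mk):
            raise ValueError("marker_indices must be distinct and < n_features")


@dataclass(frozen=True)
class CompoundEffect:
    """Latent effect of a compound at saturating dose.

    delta_p_hep shifts the hepatocyte commitment probability (realized value
    clipped to [0, 1]); ``accel`` multiplies the differentiation drive (1 =
    as fast as the differentiated control, >1 faster); ``ec50`` / ``hill``
    place the 4PL dose-effect curve; ``toxicity`` is the cell-loss fraction
    at saturating dose.
    """

    delta_p_hep: float = 0.0
    accel: float = 0.0
    ec50: float = 1.0
    hill: float = 1.0
    toxicity: float = 0.0

    def __post_init__(self):
        if self.accel < 0:
            raise ValueError("accel must be >= 0")
        if not 0.0 <= self.toxicity <= 1.0:
            raise ValueError("toxicity must lie in [0, 1]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")


@dataclass(frozen=True)
class Treatment:
    compound: str
    dose: float
    effect: CompoundEffect
    n_wells: int = 1
    cells_per_well: int | None = None  # override of the plate-wide default


@dataclass(frozen=True)
class PlateSimConfig:
    """Conditions of the simulated 384-well screening plate."""

    plate: str = "SCREEN1"
    n_control_wells_per_class: int = 16
    images_per_well: int = 4
    cells_per_well: int = 100
    treatments: tuple[Treatment, ...] = ()
    doublet_rate: float = 0.0
    qc_fail_rate: float = 0.0
    t_progenitor: float = 0.15
    t_undifferentiated: float = 1.0
    t_differentiated: float = 5.0
    t_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for r in (self.doublet_rate, self.qc_fail_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.cells_per_well < 1 or self.images_per_well < 1:
            raise ValueError("counts must be positive")
        if self.n_control_wells_per_class < 1 or self.n_control_wells_per_class > 16:
            raise ValueError("n_control_wells_per_class must be in 1..16")


@dataclass
class SyntheticTruth:
    """Ground truth aligned row-for-row with the emitted feature table.

    ``cells`` carries cell_id, latent t, true branch (pre/hep/bil) and the
    doublet flag; ``images`` the per-image qc_fail flag; ``wells`` the
    realized per-well effect parameters.
    """

    cells: pd.DataFrame
    images: pd.DataFrame | None = None
    wells: pd.DataFrame | None = None
    t_branch_true: float = 3.0

    def write(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Latent model
# ---------------------------------------------------------------------------


def monotone_basis(t: np.ndarray) -> np.ndarray:
    """Fixed monotone degree-1 I-spline basis, 3 components, knots at T_MAX/3.

    Each component is non-decreasing in ``t`` and scaled to [0, 1] at T_MAX.
    """
    s = np.asarray(t, dtype=float) / T_MAX
    return np.stack([s, np.maximum(0.0, s - 1 / 3), np.maximum(0.0, s - 2 / 3)], axis=-1)


def _latent_loadings(n_features: int, divergence_sd: float):
    rng = np.random.default_rng(_STRUCTURE_SEED)
    w_pre = rng.normal(0.0, 1.0, size=(n_features, 3))
    d_hep = rng.normal(0.0, divergence_sd, size=n_features)
    d_bil = rng.normal(0.0, divergence_sd, size=n_features)
    return w_pre, d_hep, d_bil


def _latent_areas(t: np.ndarray, branch: np.ndarray, t_b: float):
    dt = np.maximum(0.0, t - t_b)
    hep = branch == "hep"
    bil = branch == "bil"
    cell = _CELL_AREA_0 + _CELL_AREA_SLOPE * t + np.where(hep, _HEP_CELL_GAIN * dt, 0.0)
    cell = np.maximum(150.0, cell - np.where(bil, _BIL_CELL_LOSS * dt, 0.0))
    nuc = _NUC_AREA_0 + _NUC_AREA_SLOPE * t + np.where(hep, _HEP_NUC_GAIN * dt, 0.0)
    nuc = np.maximum(50.0, nuc - np.where(bil, _BIL_NUC_LOSS * dt, 0.0))
    mito = _MITO_0 + _MITO_SLOPE * t + np.where(hep, _HEP_MITO_GAIN * dt, 0.0)
    mito = np.maximum(0.2, mito - np.where(bil, _BIL_MITO_LOSS * dt, 0.0))
    return cell, nuc, mito


def latent_expectation(config: AtlasSimConfig, t: np.ndarray, branch: np.ndarray) -> np.ndarray:
    """Noise-free feature matrix for cells at latent state (t, branch)."""
    t = np.asarray(t, dtype=float)
    branch = np.asarray(branch)
    w_pre, d_hep, d_bil = _latent_loadings(config.n_features, config.divergence_sd)
    x = monotone_basis(t) @ w_pre.T
    dt = np.maximum(0.0, t - config.t_branch_true)[:, None]
    x = x + np.where((branch == "hep")[:, None], dt * d_hep[None, :], 0.0)
    x = x + np.where((branch == "bil")[:, None], dt * d_bil[None, :], 0.0)
    cell, nuc, mito = _latent_areas(t, branch, config.t_branch_true)
    m0, m1, m2 = config.marker_indices
    x[:, m0] = (cell - _CELL_AREA_0) / 100.0
    x[:, m1] = (nuc - _NUC_AREA_0) / 30.0
    x[:, m2] = mito
    return x


def _feature_names(n_features: int) -> list[str]:
    return [f"f_{i:04d}" for i in range(n_features)]


def _emit_cells(
    config: AtlasSimConfig,
    rng: np.random.Generator,
    t: np.ndarray,
    branch: np.ndarray,
    meta: dict,
) -> pd.DataFrame:
    """Build a metadata+feature frame for cells at latent states (t, branch)."""
    n = len(t)
    x = latent_expectation(config, t, branch)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    cell, nuc, mito = _latent_areas(t, branch, config.t_branch_true)
    area_noise = 0.125 * config.noise_sd  # lognormal sd on areas, 0 when noise-free
    if area_noise > 0:
        cell = cell * np.exp(rng.normal(0.0, area_noise, size=n))
        nuc = nuc * np.exp(rng.normal(0.0, area_noise, size=n))
        mito = mito * np.exp(rng.normal(0.0, area_noise, size=n))
    m0, m1, m2 = config.marker_indices
    x[:, m0] = (cell - _CELL_AREA_0) / 100.0
    x[:, m1] = (nuc - _NUC_AREA_0) / 30.0
    x[:, m2] = mito
    frame = pd.DataFrame(meta)
    frame["nuclear_area"] = nuc
    frame["cell_area"] = cell
    feats = pd.DataFrame(x, columns=_feature_names(config.n_features))
    return pd.concat([frame, feats], axis=1)


def _draw_branch(rng: np.random.Generator, t: np.ndarray, t_b: float, p_hep) -> np.ndarray:
    branch = np.full(len(t), "pre", dtype=object)
    post = t > t_b
    u = rng.random(len(t))
    branch[post & (u < p_hep)] = "hep"
    branch[post & (u >= p_hep)] = "bil"
    return branch


# ---------------------------------------------------------------------------
# Atlas time course
# ---------------------------------------------------------------------------


def simulate_atlas(config: AtlasSimConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate the differentiation time-course atlas.

    One plate per timepoint, ``cells_per_timepoint`` cells spread over 16
    wells x 4 fields.  Timepoint-1 cells (t = 0) carry the
    ``progenitor_control`` role and double as anchors for cross-dataset
    standardization; later timepoints are ``sample``.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.linspace(0.0, T_MAX, config.n_timepoints)
    frames, truths = [], []
    for k, t_k in enumerate(grid, start=1):
        n = config.cells_per_timepoint
        t = np.full(n, t_k)
        if config.t_jitter_sd > 0:
            t = np.clip(t + rng.normal(0.0, config.t_jitter_sd, size=n), 0.0, T_MAX)
        branch = _draw_branch(rng, t, config.t_branch_true, config.p_hep)
        idx = np.arange(n)
        meta = {
            "cell_id": [f"tc{k:02d}_{i:06d}" for i in idx],
            "plate": f"TC{k:02d}",
            "well": [WELL_ROWS[i % 16] + "1" for i in idx],
            "field": (idx // 16) % 4 + 1,
            "role": "progenitor_control" if k == 1 else "sample",
            "compound": "none",
            "dose": 0.0,
            "timepoint": k,
            "replicate": 1,
        }
        frames.append(_emit_cells(config, rng, t, branch, meta))
        truths.append(
            pd.DataFrame(
                {
                    "cell_id": meta["cell_id"],
                    "t": t,
                    "branch": branch,
                    "doublet": False,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    order = METADATA_COLUMNS + _feature_names(config.n_features)
    return (
        FeatureTable(data[order]),
        SyntheticTruth(cells=truth, t_branch_true=config.t_branch_true),
    )


# ---------------------------------------------------------------------------
# Screening plate
# ---------------------------------------------------------------------------


def four_pl_fraction(dose: float, ec50: float, hill: float) -> float:
    """Fractional effect in [0, 1] of a dose under a 4PL curve (bottom 0, top 1)."""
    if dose <= 0:
        return 0.0
    return float(1.0 / (1.0 + 10.0 ** ((np.log10(ec50) - np.log10(dose)) * hill)))


def default_layout(plate_config: PlateSimConfig) -> pd.DataFrame:
    """Default 384-well layout: controls in columns 22-24, treatments row-major
    from A1.  Returns well / role / compound / dose / replicate."""
    rows = []
    ctrl_cols = {"differentiated_control": 22, "undifferentiated_control": 23, "progenitor_control": 24}
    for role, col in ctrl_cols.items():
        for i in range(plate_config.n_control_wells_per_class):
            rows.append((f"{WELL_ROWS[i]}{col}", role, "none", 0.0, i + 1))
    free = [f"{r}{c}" for c in range(1, 22) for r in WELL_ROWS]
    pos = 0
    for trt in plate_config.treatments:
        for rep in range(trt.n_wells):
            if pos >= len(free):
                raise ValueError("treatment list does not fit on a 384-well plate")
            rows.append((free[pos], "treatment", trt.compound, trt.dose, rep + 1))
            pos += 1
    return pd.DataFrame(rows, columns=["well", "role", "compound", "dose", "replicate"])


def simulate_plate(
    atlas_config: AtlasSimConfig, plate_config: PlateSimConfig
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a screening plate in the atlas feature space.

    Per-well latent time centers: progenitor controls near 0, undifferentiated
    controls at a small drift, differentiated controls at an intermediate
    (partially differentiated) time.  A treatment's realized effect is its
    :class:`CompoundEffect` scaled by the 4PL fraction ``f`` of its dose:
    the latent center moves ``f * accel`` of the way from the
    undifferentiated toward the differentiated center (and beyond for
    accel > 1), the hepatocyte commitment probability shifts by
    ``f * delta_p_hep``, and the well loses ``f * toxicity`` of its cells.
    QC-failing images are truncated to 2 cells (an empty/failed field).
    """
    rng = np.random.default_rng(plate_config.seed)
    layout = default_layout(plate_config)
    effects = {t.compound: t.effect for t in plate_config.treatments}
    n_override = {t.compound: t.cells_per_well for t in plate_config.treatments}
    t_b = atlas_config.t_branch_true

    frames, cell_truths, image_truths, well_truths = [], [], [], []
    cid = 0
    for _, wrow in layout.iterrows():
        well, role, compound, dose, rep = (
            wrow["well"], wrow["role"], wrow["compound"], wrow["dose"], wrow["replicate"],
        )
        if role == "progenitor_control":
            center, p_hep, f, tox = plate_config.t_progenitor, atlas_config.p_hep, 0.0, 0.0
        elif role == "undifferentiated_control":
            center, p_hep, f, tox = plate_config.t_undifferentiated, atlas_config.p_hep, 0.0, 0.0
        elif role == "differentiated_control":
            center, p_hep, f, tox = plate_config.t_differentiated, atlas_config.p_hep, 0.0, 0.0
        else:
            eff = effects[compound]
            f = four_pl_fraction(dose, eff.ec50, eff.hill)
            shift = f * eff.accel * (plate_config.t_differentiated - plate_config.t_undifferentiated)
            center = plate_config.t_undifferentiated + shift
            p_hep = float(np.clip(atlas_config.p_hep + f * eff.delta_p_hep, 0.0, 1.0))
            tox = f * eff.toxicity
        base_n = plate_config.cells_per_well
        if role == "treatment" and n_override.get(compound):
            base_n = n_override[compound]
        n_cells = max(1, int(round(base_n * (1.0 - tox))))
        t = np.clip(rng.normal(center, plate_config.t_sd, size=n_cells), 0.0, T_MAX)
        branch = _draw_branch(rng, t, t_b, p_hep)
        fields = np.arange(n_cells) % plate_config.images_per_well + 1

        # image-level QC failures: a failed field keeps only 2 cells
        keep = np.ones(n_cells, dtype=bool)
        for fld in range(1, plate_config.images_per_well + 1):
            fail = rng.random() < plate_config.qc_fail_rate
            image_truths.append(
                {"image_id": f"{plate_config.plate}:{well}:{fld}", "qc_fail": bool(fail)}
            )
            if fail:
                in_img = np.flatnonzero(fields == fld)
                keep[in_img[2:]] = False
        t, branch, fields = t[keep], branch[keep], fields[keep]
        n_cells = len(t)

        idx = np.arange(n_cells)
        meta = {
            "cell_id": [f"sc_{cid + i:07d}" for i in idx],
            "plate": plate_config.plate,
            "well": well,
            "field": fields,
            "role": role,
            "compound": compound,
            "dose": dose,
            "timepoint": 0,
            "replicate": rep,
        }
        cid += n_cells
        frames.append(_emit_cells(atlas_config, rng, t, branch, meta))
        cell_truths.append(
            pd.DataFrame({"cell_id": meta["cell_id"], "t": t, "branch": branch, "doublet": False})
        )
        well_truths.append(
            {
                "well": well, "role": role, "compound": compound, "dose": dose,
                "replicate": rep, "effect_fraction": f, "t_center": center,
                "p_hep_realized": p_hep,
            }
        )

    data = pd.concat(frames, ignore_index=True)
    order = METADATA_COLUMNS + _feature_names(atlas_config.n_features)
    table = FeatureTable(data[order])
    truth_cells = pd.concat(cell_truths, ignore_index=True)

    if plate_config.doublet_rate > 0:
        m0, m1, _ = atlas_config.marker_indices
        area_feats = [f"f_{m0:04d}", f"f_{m1:04d}"]
        table, flags = inject_doublets(
            table, plate_config.doublet_rate, seed=plate_config.seed + 1,
            area_features=area_feats,
        )
        truth_cells = truth_cells.copy()
        truth_cells["doublet"] = flags

    truth = SyntheticTruth(
        cells=truth_cells,
        images=pd.DataFrame(image_truths),
        wells=pd.DataFrame(well_truths),
        t_branch_true=t_b,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Doublet injection
# ---------------------------------------------------------------------------


def inject_doublets(
    table: FeatureTable,
    rate: float,
    seed: int,
    area_features: Sequence[str] = (),
) -> tuple[FeatureTable, np.ndarray]:
    """Turn a random fraction of cells into synthetic doublets.

    Each selected cell is merged with a random same-well partner: generic
    features become a convex combination with lambda ~ U(0.4, 0.6); area
    measurements (``nuclear_area``, ``cell_area`` and any feature named in
    ``area_features``) are summed, as two touching cells segmented as one
    object have additive area.  Returns the modified table and the aligned
    boolean flag vector.  rate = 0 returns the input unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("doublet rate must lie in [0, 1]")
    flags = np.zeros(table.n_cells, dtype=bool)
    if rate == 0.0 or table.n_cells == 0:
        return table.copy(), flags
    bad = set(area_features) - set(table.feature_names)
    if bad:
        raise ValueError(f"unknown area feature(s): {sorted(bad)}")

    rng = np.random.default_rng(seed)
    data = table.data.copy()
    flags = rng.random(table.n_cells) < rate
    well_groups = data.groupby(["plate", "well"]).indices
    feat_cols = [c for c in table.feature_names if c not in set(area_features)]
    area_cols = ["nuclear_area", "cell_area"] + list(area_features)
    x = data[feat_cols].to_numpy(dtype=float)
    a = data[area_cols].to_numpy(dtype=float)
    x_orig, a_orig = x.copy(), a.copy()  # partners are original singlets, never chained
    for i in np.flatnonzero(flags):
        key = (data.at[i, "plate"], data.at[i, "well"])
        members = well_groups[key]
        if len(members) < 2:
            flags[i] = False
            continue
        j = i
        while j == i:
            j = members[rng.integers(len(members))]
        lam = rng.uniform(0.4, 0.6)
        x[i] = lam * x_orig[i] + (1.0 - lam) * x_orig[j]
        a[i] = a_orig[i] + a_orig[j]
    data[feat_cols] = x
    data[area_cols] = a
    return FeatureTable(data, table.feature_names), flags
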