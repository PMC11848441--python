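"""Well-level screen analysis: robust-z normalization, feature selection,
distance-to-control hit calling, and assay QC (Z'-factor, CV, control
classifier).

This is the industry-standard aggregate analysis of a high-content screen.
Well profiles (per-feature medians from :func:`morphotraj.io_qc.aggregate_profiles`)
are normalized per plate with robust z-scores, redundant features are pruned,
and each well is scored by two distances to the positive-control
(differentiated) centroid:

* ``d_P`` — Pearson distance, 1 minus the Pearson correlation between the
  well profile and the median control profile (range [0, 2]);
* ``d_E`` — Euclidean distance to the control centroid in a PCA space
  retaining 90% of variance, expressed in units of the positive-control
  wells' own RMS scatter around that centroid.  A differentiated-like well
  therefore sits near 1 regardless of plate design or feature count, which
  is what makes a fixed threshold usable.

A well is a *hit* when both distances fall strictly below their thresholds
(defaults d_P < 0.9 and d_E < 1.7): it is morphologically closer to the
differentiated control than the bulk of treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split

__all__ = [
    "PROFILE_META",
    "NormalizationModel",
    "FeatureSelection",
    "AssayQc",
    "profile_feature_columns",
    "robust_z_normalize",
    "select_features",
    "distance_to_control",
    "call_hits",
    "zprime",
    "assay_qc",
]

PROFILE_META = ["plate", "well", "role", "compound", "dose", "timepoint", "replicate", "n_cells"]

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates sigma for a normal


def profile_feature_columns(profiles: pd.DataFrame) -> list[str]:
    return [c for c in profiles.columns if c not in PROFILE_META]


@dataclass
class NormalizationModel:
    """Per-plate, per-feature robust center/scale with drop log."""

    mode: str
    center: dict[str, pd.Series]
    scale: dict[str, pd.Series]
    dropped: list[str]


def robust_z_normalize(
    profiles: pd.DataFrame, mode: str = "all_samples"
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Robust z-score each feature per plate: z = (x - median) / (1.4826 MAD).

    ``mode`` selects the reference wells that define center and scale:
    ``all_samples`` (screening mode — every well on the plate) or
    ``negative_controls`` (validation mode — undifferentiated-control
    wells).  Features whose MAD is zero on any plate are dropped and
    recorded on the model.  Requires >= 4 reference wells per plate.
    """
    if mode not in {"all_samples", "negative_controls"}:
        raise ValueError(f"unknown normalization mode {mode!r}")
    feats = profile_feature_columns(profiles)
    out = []
    centers, scales = {}, {}
    dead: set[str] = set()
    for plate, block in profiles.groupby("plate", sort=True):
        if mode == "negative_controls":
            ref = block[block["role"] == "undifferentiated_control"]
        else:
            ref = block
        if len(ref) == 0:
            raise ValueError(f"plate {plate!r} has no reference wells for mode {mode!r}")
        if len(ref) < 4:
            raise ValueError(f"plate {plate!r} has only {len(ref)} reference wells (need >= 4)")
        center = ref[feats].median()
        mad = (ref[feats] - center).abs().median()
        scale = MAD_SCALE * mad
        dead.update(scale.index[scale == 0.0])
        z = block.copy()
        z[feats] = (block[feats] - center) / scale.replace(0.0, np.nan)
        out.append(z)
        centers[plate], scales[plate] = center, scale
    dropped = sorted(dead)
    normalized = pd.concat(out, ignore_index=True).drop(columns=dropped)
    return normalized, NormalizationModel(mode=mode, center=centers, scale=scales, dropped=dropped)


@dataclass
class FeatureSelection:
    """Retained feature names plus per-feature drop reasons."""

    retained: list[str]
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.retained:
            raise ValueError("feature selection retained no features")
        overlap = set(self.retained) & set(self.dropped)
        if overlap:
            raise ValueError(f"features both retained and dropped: {sorted(overlap)}")


def select_features(profiles_normalized: pd.DataFrame, corr_threshold: float = 0.9) -> FeatureSelection:
    """Drop missing/zero-variance features, then greedily prune correlated ones.

    Features are scanned in input order; a feature is dropped when its
    absolute Pearson correlation with an already-retained feature exceeds
    the threshold (the first of any such pair survives).
    """
    feats = profile_feature_columns(profiles_normalized)
    x = profiles_normalized[feats]
    dropped: dict[str, str] = {}
    alive = []
    for c in feats:
        if x[c].isna().any():
            dropped[c] = "missing"
        elif x[c].nunique() <= 1 or x[c].std(ddof=0) == 0.0:
            dropped[c] = "zero-variance"
        else:
            alive.append(c)
    if not alive:
        raise ValueError("all features dropped before correlation pruning")
    corr = np.corrcoef(x[alive].to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    kept_idx: list[int] = []
    for i, c in enumerate(alive):
        if any(abs(corr[i, j]) > corr_threshold for j in kept_idx):
            dropped[c] = "high-correlation"
        else:
            kept_idx.append(i)
    retained = [alive[i] for i in kept_idx]
    return FeatureSelection(retained=retained, dropped=dropped)


def distance_to_control(
    profiles_normalized: pd.DataFrame,
    selection: FeatureSelection,
    control_role: str = "differentiated_control",
    variance_target: float = 0.90,
    scale: str = "control_rms",
) -> pd.DataFrame:
    """Per-well Pearson and Euclidean distances to the control centroid.

    ``d_P = 1 - r(profile, median control profile)`` over the selected
    features; ``d_E`` is the Euclidean distance to the control centroid in a
    PCA basis fit on all wells and truncated at ``variance_target``
    cumulative explained variance.  ``scale`` sets the units of d_E:
    ``control_rms`` (default) divides by the RMS distance of the control
    wells themselves to the centroid, so on-phenotype wells sit near 1;
    ``sqrt_k`` divides by sqrt(n_components) instead.
    """
    if scale not in {"control_rms", "sqrt_k"}:
        raise ValueError(f"unknown d_E scale {scale!r}")
    feats = selection.retained
    if len(feats) < 2:
        raise ValueError("need at least 2 selected features for distances")
    ctrl = profiles_normalized[profiles_normalized["role"] == control_role]
    if ctrl.empty:
        raise ValueError(f"no wells with control role {control_role!r}")
    x = profiles_normalized[feats].to_numpy(dtype=float)
    centroid = ctrl[feats].median().to_numpy(dtype=float)

    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        well = profiles_normalized.iloc[flat[0]]["well"]
        raise ValueError(f"well {well!r} has a zero-variance profile; correlation undefined")
    c = centroid - centroid.mean()
    xm = x - x.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xm, axis=1) * np.linalg.norm(c)
    d_p = 1.0 - (xm @ c) / denom

    n_comp_max = min(len(profiles_normalized), len(feats))
    pca = PCA(n_components=n_comp_max, svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, scores.shape[1])
    c_scores = pca.transform(centroid[None, :])[0, :k]
    raw_d_e = np.linalg.norm(scores[:, :k] - c_scores, axis=1)
    if scale == "sqrt_k":
        d_e = raw_d_e / np.sqrt(k)
    else:
        is_ctrl = (profiles_normalized["role"] == control_role).to_numpy()
        rms = float(np.sqrt(np.mean(raw_d_e[is_ctrl] ** 2)))
        if rms == 0.0:
            raise ValueError("control wells have zero scatter; cannot scale d_E")
        d_e = raw_d_e / rms

    out = profiles_normalized[[c for c in PROFILE_META if c in profiles_normalized.columns]].copy()
    out["d_P"] = d_p
    out["d_E"] = d_e
    out.attrs["n_components"] = k
    return out


def call_hits(distances: pd.DataFrame, theta_p: float = 0.9, theta_e: float = 1.7) -> pd.DataFrame:
    """Hit = strict conjunction d_P < theta_p and d_E < theta_e."""
    out = distances.copy()
    out["theta_P"] = theta_p
    out["theta_E"] = theta_e
    out["is_hit"] = (out["d_P"] < theta_p) & (out["d_E"] < theta_e)
    return out


def zprime(positive: np.ndarray, negative: np.ndarray) -> float:
    """Z'-factor: 1 - 3(sigma_pos + sigma_neg) / |mu_pos - mu_neg|.

    Returns NaN when the means coincide (undefined window).
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    mu_p, mu_n = positive.mean(), negative.mean()
    if mu_p == mu_n:
        return float("nan")
    sd_p = positive.std(ddof=1) if positive.size > 1 else 0.0
    sd_n = negative.std(ddof=1) if negative.size > 1 else 0.0
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


@dataclass
class AssayQc:
    """Assay-quality report: per-plate Z', per-class CV% of d_P, and a
    held-out control-classifier report."""

    zprime_per_plate: dict[str, float]
    cv_percent: dict[str, float]
    classifier_accuracy: float
    classifier_report: pd.DataFrame
    flags: list[str] = field(default_factory=list)


CONTROL_CLASSES = ["progenitor_control", "undifferentiated_control", "differentiated_control"]


def assay_qc(
    distances: pd.DataFrame,
    profiles_normalized: pd.DataFrame,
    selection: FeatureSelection | None = None,
    test_size: float = 0.5,
    seed: int = 0,
) -> AssayQc:
    """Assay QC mirroring standard screen validation.

    Z' per plate is computed on the scalar Pearson distance of
    differentiated (positive) vs undifferentiated (negative) control wells;
    CV% = 100 sigma/mu of d_P per control class; and a three-class random
    forest is trained on the normalized control profiles and scored on a
    held-out stratified split (accuracy plus per-class precision/recall/F1).
    """
    flags = []
    zp = {}
    for plate, block in distances.groupby("plate", sort=True):
        pos = block.loc[block["role"] == "differentiated_control", "d_P"].to_numpy()
        neg = block.loc[block["role"] == "undifferentiated_control", "d_P"].to_numpy()
        if pos.size == 0 or neg.size == 0:
            flags.append(f"plate {plate}: missing control class for Z'")
            zp[plate] = float("nan")
            continue
        z = zprime(pos, neg)
        if np.isnan(z):
            flags.append(f"plate {plate}: Z' undefined (equal control means)")
        zp[plate] = z

    cv = {}
    for role, block in distances.groupby("role", sort=True):
        if role not in CONTROL_CLASSES:
            continue
        d = block["d_P"].to_numpy()
        mu = d.mean()
        if mu == 0:
            flags.append(f"class {role}: CV undefined (zero mean d_P)")
            cv[role] = float("nan")
        else:
            cv[role] = float(100.0 * (d.std(ddof=1) if d.size > 1 else 0.0) / abs(mu))

    ctrl = profiles_normalized[profiles_normalized["role"].isin(CONTROL_CLASSES)]
    feats = selection.retained if selection is not None else profile_feature_columns(profiles_normalized)
    x = ctrl[feats].to_numpy(dtype=float)
    y = ctrl["role"].to_numpy()
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    acc = float((pred == y_te).mean())
    prec, rec, f1, support = precision_recall_fscore_support(
        y_te, pred, labels=CONTROL_CLASSES, zero_division=0
    )
    report = pd.DataFrame(
        {"class": CONTROL_CLASSES, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    return AssayQc(
        zprime_per_plate=zp,
        cv_percent=cv,
        classifier_accuracy=acc,
        classifier_report=report,
        flags=flags,
    )
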