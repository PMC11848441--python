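"""Single-cell preprocessing: down-sampling, progenitor-anchor
standardization, doublet removal and the frozen atlas embedding.

Datasets acquired separately (the differentiation time course and the drug
screen) are merged by *anchor standardization*: each dataset carries
spiked-in progenitor-control cells in a shared biological state, and
robust-centering/scaling every feature on those anchors puts all datasets
into one comparable space without any graph-based batch correction.

The atlas embedding is PCA to 10 components followed by a 2-D UMAP.  The
frozen model maps *new* cells into the embedding without refitting via
k-nearest-neighbour barycentric interpolation in PC space against the
stored atlas: a deterministic, pure function of the model, which reproduces
the atlas's own coordinates exactly when given atlas cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from umap import UMAP

from .io_qc import FeatureTable
from .profiling import MAD_SCALE

__all__ = [
    "AnchorModel",
    "DoubletModel",
    "EmbeddingModel",
    "downsample_per_group",
    "anchor_standardize",
    "train_doublet_model",
    "classify_and_remove",
    "fit_embedding",
]

DOUBLET_CLASSES = ("Progenitor", "Doublet", "Inlier")


def downsample_per_group(
    table: FeatureTable,
    cap: int = 15000,
    seed: int = 0,
    keys: tuple[str, ...] = ("timepoint", "compound", "dose"),
) -> FeatureTable:
    """Uniformly down-sample each (timepoint | treatment) group to ``cap`` cells.

    Groups at or below the cap are untouched; larger ones are sampled
    without replacement, deterministically for a given seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep = []
    for _, idx in sorted(table.data.groupby(list(keys)).indices.items(), key=lambda kv: str(kv[0])):
        if len(idx) <= cap:
            keep.append(idx)
        else:
            keep.append(rng.choice(idx, size=cap, replace=False))
    mask = np.sort(np.concatenate(keep))
    return table.subset(mask)


@dataclass
class AnchorModel:
    """Per-dataset robust center/scale estimated on progenitor-control cells."""

    dataset: str
    center: pd.Series
    scale: pd.Series
    n_anchors: int


def anchor_standardize(
    tables: list[FeatureTable],
    dataset_names: list[str] | None = None,
    min_anchors: int = 200,
) -> tuple[FeatureTable, list[AnchorModel]]:
    """Standardize each dataset on its progenitor anchors, then merge.

    Per dataset and feature: center = median, scale = 1.4826 x MAD of the
    ``progenitor_control`` cells.  After the transform the anchor centroids
    of all datasets coincide at the origin, which is what allows time-course
    and screen data to share one space.  Cell ids are prefixed with the
    dataset name; a ``dataset`` column records provenance.
    """
    if not tables:
        raise ValueError("no datasets to merge")
    if dataset_names is None:
        dataset_names = [f"ds{i}" for i in range(len(tables))]
    feats = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != feats:
            raise ValueError("datasets disagree on feature names")
    models, frames = [], []
    for name, t in zip(dataset_names, tables):
        anchors = t.data[t.data["role"] == "progenitor_control"]
        if len(anchors) < min_anchors:
            raise ValueError(
                f"dataset {name!r} has {len(anchors)} progenitor-control cells "
                f"(need >= {min_anchors}) for anchor standardization"
            )
        center = anchors[feats].median()
        scale = MAD_SCALE * (anchors[feats] - center).abs().median()
        zero = scale.index[scale == 0.0].tolist()
        if zero:
            raise ValueError(f"dataset {name!r}: zero anchor MAD for feature(s) {zero[:5]}")
        d = t.data.copy()
        d[feats] = (d[feats] - center) / scale
        d["cell_id"] = name + ":" + d["cell_id"].astype(str)
        d = pd.concat([d, pd.Series(name, index=d.index, name="dataset")], axis=1)
        frames.append(d)
        models.append(AnchorModel(dataset=name, center=center, scale=scale, n_anchors=len(anchors)))
    merged = pd.concat(frames, ignore_index=True)
    return FeatureTable(merged, feats), models


def _doublet_matrix(table: FeatureTable) -> np.ndarray:
    """Classifier input: morphology features plus the two area channels
    (segmentation doublets betray themselves chiefly through summed areas)."""
    areas = table.data[["nuclear_area", "cell_area"]].to_numpy(dtype=float)
    return np.column_stack([table.X, areas])


@dataclass
class DoubletModel:
    """Balanced three-class (Progenitor / Doublet / Inlier) random forest."""

    classifier: RandomForestClassifier
    feature_names: list[str]
    class_counts: dict[str, int]
    holdout_metrics: pd.DataFrame


def train_doublet_model(
    table: FeatureTable,
    labels,
    seed: int = 0,
    n_estimators: int = 200,
    holdout: float = 0.3,
) -> DoubletModel:
    """Train the doublet-removal classifier on labelled cells.

    Labels must be in {Progenitor, Doublet, Inlier} (from synthetic truth
    or user annotation).  Training classes are balanced by down-sampling
    the majority classes; held-out per-class recall is recorded.
    """
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(DOUBLET_CLASSES)
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    counts = {c: int((labels == c).sum()) for c in DOUBLET_CLASSES}
    low = [c for c, n in counts.items() if n < 10]
    if low:
        raise ValueError(f"class(es) with < 10 labelled examples: {low}")
    rng = np.random.default_rng(seed)
    n_min = min(counts.values())
    sel = np.concatenate(
        [rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False) for c in DOUBLET_CLASSES]
    )
    x = _doublet_matrix(table)[sel]
    y = labels[sel]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    rows = []
    for c in DOUBLET_CLASSES:
        m = y_te == c
        recall = float((pred[m] == c).mean()) if m.any() else np.nan
        prec_den = (pred == c).sum()
        precision = float((y_te[pred == c] == c).mean()) if prec_den else np.nan
        rows.append({"class": c, "precision": precision, "recall": recall, "support": int(m.sum())})
    metrics = pd.DataFrame(rows)
    return DoubletModel(
        classifier=clf,
        feature_names=list(table.feature_names),
        class_counts={c: n_min for c in DOUBLET_CLASSES},
        holdout_metrics=metrics,
    )


def classify_and_remove(table: FeatureTable, model: DoubletModel) -> tuple[FeatureTable, list]:
    """Drop cells the model predicts as Doublet; keep Progenitor and Inlier."""
    if table.feature_names != model.feature_names:
        raise ValueError("table features do not match the doublet model")
    pred = model.classifier.predict(_doublet_matrix(table))
    removed = table.data.loc[pred == "Doublet", "cell_id"].tolist()
    return table.subset(pred != "Doublet"), removed


@dataclass
class EmbeddingModel:
    """Frozen atlas embedding: PCA(10) -> UMAP(2) with a k-NN out-of-sample map.

    ``transform`` is a pure function of the stored state — repeated calls
    agree bitwise, and atlas cells map back to their fitted coordinates.
    """

    pca: PCA
    atlas_scores: np.ndarray  # (n_atlas, n_pcs)
    atlas_embedding: np.ndarray  # (n_atlas, 2)
    n_neighbors: int
    min_dist: float
    seed: int
    transform_k: int = 10
    _nn: NearestNeighbors = field(default=None, repr=False)

    def __post_init__(self):
        if self._nn is None:
            self._nn = NearestNeighbors(n_neighbors=self.transform_k).fit(self.atlas_scores)

    def transform(self, table_or_X) -> np.ndarray:
        """Map cells (FeatureTable or raw standardized feature matrix) into
        the frozen 2-D embedding by inverse-distance-weighted interpolation
        of the ``transform_k`` nearest atlas cells in PC space.  An exact
        match inherits that atlas cell's coordinate."""
        x = table_or_X.X if isinstance(table_or_X, FeatureTable) else np.asarray(table_or_X, float)
        scores = self.pca.transform(x)
        dist, idx = self._nn.kneighbors(scores)
        out = np.empty((len(scores), 2))
        exact = dist[:, 0] < 1e-9  # an atlas cell maps to its own coordinate
        out[exact] = self.atlas_embedding[idx[exact, 0]]
        rest = ~exact
        if rest.any():
            w = 1.0 / dist[rest]
            w /= w.sum(axis=1, keepdims=True)
            out[rest] = np.einsum("nk,nkd->nd", w, self.atlas_embedding[idx[rest]])
        return out


def fit_embedding(
    table: FeatureTable,
    n_pcs: int = 10,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit the atlas embedding (PCA -> UMAP) on the merged standardized table.

    Returns the frozen model and the atlas cells' 2-D coordinates.  UMAP is
    run with a fixed random_state, so the embedding is deterministic.
    """
    if n_pcs > len(table.feature_names):
        raise ValueError("n_pcs exceeds the number of features")
    # full SVD: deterministic, and transform() round-trips fit_transform()
    # (the randomized solver's factorization error breaks that contract)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(table.X)
    um = UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed, n_jobs=1
    )
    emb = np.asarray(um.fit_transform(scores), dtype=float)
    model = EmbeddingModel(
        pca=pca,
        atlas_scores=scores,
        atlas_embedding=emb,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        seed=seed,
    )
    return model, emb
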