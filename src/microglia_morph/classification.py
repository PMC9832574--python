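"""Morphology classification by metric learning + density clustering.

Annotated cells are embedded into two dimensions with *supervised* UMAP:
class labels steer the layout so that morphology classes occupy separate
regions while the data's internal structure is preserved.  Unannotated cells
are projected through the learned transform, clusters are found in the 2-D
space with HDBSCAN, and every cluster inherits the most frequent annotation
among its annotated members (majority vote).  Cells in noise regions,
clusters without annotated members, or clusters with tied votes stay
``unassigned`` — predictions are deliberately conservative.

Features are z-scored per column on the training cells before embedding so
that UMAP distances weigh all features commensurably.  By default all base
and derived *shape* features enter the embedding; intensity summaries,
centroids and the border-contact count do not (they reflect acquisition, not
morphology).  The classifier is evaluated by stratified k-fold
cross-validation, reporting accuracy over assigned cells, the unassigned
fraction and a confusion matrix whose columns include ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .morphometry import BASE_FEATURES, DERIVED_FEATURES

__all__ = [
    "UNASSIGNED", "DEFAULT_FEATURES", "MorphologyModel", "fit_embedding",
    "project", "cluster", "vote", "classify_cells", "cross_validate",
    "CrossValidationResult", "save_model", "load_model",
]

UNASSIGNED = "unassigned"

#: Shape features used for embedding by default (no intensity summaries,
#: centroids or border-contact counts).
DEFAULT_FEATURES: tuple[str, ...] = tuple(
    f for f in BASE_FEATURES
    if f not in ("MeanIntensity", "MaxIntensity", "SumIntensity",
                 "StdIntensity", "CentroidRow_px", "CentroidCol_px")
) + DERIVED_FEATURES


@dataclass
class MorphologyModel:
    """Fitted supervised embedding plus scaling and clustering parameters."""

    feature_columns: tuple[str, ...]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    reducer: object                      # fitted umap.UMAP
    classes: tuple[str, ...]
    seed: int
    min_cluster_size: int = 10

    @property
    def training_embedding(self) -> np.ndarray:
        return np.asarray(self.reducer.embedding_)


def _feature_matrix(records: pd.DataFrame, columns, dropna: bool):
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise ValueError(f"records lack feature columns {missing}")
    X = records.loc[:, list(columns)].astype(float)
    if dropna:
        keep = ~X.isna().any(axis=1)
    else:
        keep = pd.Series(True, index=X.index)
        X = X.fillna(X.median())
    return X[keep].to_numpy(), keep


def fit_embedding(records: pd.DataFrame, annotations: pd.Series,
                  seed: int = 0, feature_columns=DEFAULT_FEATURES,
                  n_neighbors: int = 15, min_dist: float = 0.1,
                  target_weight: float = 0.6, min_cluster_size: int = 10,
                  ) -> MorphologyModel:
    """Fit the supervised 2-D embedding on annotated cells.

    ``annotations`` is aligned with ``records`` and must contain at least two
    classes, each with two or more members.  The fit is deterministic for a
    fixed ``seed``.
    """
    import umap  # deferred: heavy numba import

    annotations = annotations.reindex(records.index)
    if annotations.isna().any():
        raise ValueError("every training record needs an annotation")
    counts = annotations.value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"supervised embedding needs >= 2 classes, got only {counts.index[0]!r}"
        )
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"class {small.index[0]!r} has fewer than 2 annotated cells"
        )

    X, keep = _feature_matrix(records, feature_columns, dropna=False)
    y = annotations[keep]
    classes = tuple(sorted(y.unique()))
    codes = y.map({c: i for i, c in enumerate(classes)}).to_numpy()

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(Xs) - 1),
        min_dist=min_dist,
        random_state=int(seed),
        target_metric="categorical",
        target_weight=target_weight,
        n_jobs=1,
    )
    reducer.fit(Xs, y=codes)
    return MorphologyModel(
        feature_columns=tuple(feature_columns),
        scale_mean=mean, scale_std=std,
        reducer=reducer, classes=classes, seed=int(seed),
        min_cluster_size=min_cluster_size,
    )


def project(model: MorphologyModel, records: pd.DataFrame) -> np.ndarray:
    """Project cell records through the learned transform (no re-fitting)."""
    if len(records) == 0:
        return np.empty((0, 2))
    X, _ = _feature_matrix(records, model.feature_columns, dropna=False)
    Xs = (X - model.scale_mean) / model.scale_std
    return np.asarray(model.reducer.transform(Xs))


def cluster(coordinates: np.ndarray, min_cluster_size: int = 10) -> np.ndarray:
    """HDBSCAN on 2-D embedding coordinates; -1 marks noise points."""
    coordinates = np.asarray(coordinates, dtype=float)
    if len(coordinates) < min_cluster_size:
        return np.full(len(coordinates), -1, dtype=int)
    return HDBSCAN(min_cluster_size=min_cluster_size,
                   copy=True).fit_predict(coordinates)


def vote(cluster_ids: np.ndarray, annotations: pd.Series) -> pd.Series:
    """Per-cluster majority vote of the annotated members.

    Every member of a cluster inherits the cluster's winning class.  Noise
    points, clusters without annotated members and tied majorities all map to
    ``unassigned``.
    """
    cluster_ids = np.asarray(cluster_ids)
    annotations = annotations.reset_index(drop=True)
    if annotations.notna().sum() == 0:
        raise ValueError("majority voting needs at least one annotated cell")
    result = pd.Series(UNASSIGNED, index=annotations.index, dtype=object)
    for cid in np.unique(cluster_ids):
        if cid == -1:
            continue
        members = np.flatnonzero(cluster_ids == cid)
        ann = annotations.iloc[members].dropna()
        if len(ann) == 0:
            continue
        counts = ann.value_counts()
        top = counts[counts == counts.iloc[0]]
        if len(top) > 1:
            continue  # tied vote stays unassigned
        result.iloc[members] = top.index[0]
    return result


def classify_cells(records: pd.DataFrame, annotations: pd.Series,
                   seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """End-to-end assignment: fit on annotated cells, label every cell.

    ``annotations`` is aligned with ``records``; NaN marks unannotated
    cells.  Returns one row per input cell: embedding coordinates, cluster
    id, assigned class (or ``unassigned``) and the ``was_annotated`` flag.
    """
    annotations = annotations.reindex(records.index)
    annotated = records[annotations.notna()]
    model = fit_embedding(annotated, annotations.dropna(), seed=seed,
                          **fit_kwargs)
    coords = np.empty((len(records), 2))
    is_ann = annotations.notna().to_numpy()
    coords[is_ann] = model.training_embedding
    coords[~is_ann] = project(model, records[~is_ann])
    cluster_ids = cluster(coords, model.min_cluster_size)
    assigned = vote(cluster_ids, annotations)
    out = pd.DataFrame({
        "cell_id": records["cell_id"].to_numpy()
        if "cell_id" in records.columns else records.index.to_numpy(),
        "embedding_x": coords[:, 0],
        "embedding_y": coords[:, 1],
        "cluster_id": cluster_ids,
        "assigned_class": assigned.to_numpy(),
        "was_annotated": is_ann,
    })
    return out


@dataclass
class CrossValidationResult:
    accuracy: float                 # over assigned held-out cells
    unassigned_fraction: float
    confusion: pd.DataFrame         # rows: true class; cols: classes + unassigned
    per_fold_accuracy: list[float] = field(default_factory=list)


def cross_validate(records: pd.DataFrame, annotations: pd.Series, k: int = 5,
                   seed: int = 0, **fit_kwargs) -> CrossValidationResult:
    """Stratified k-fold evaluation of the full classify pipeline.

    Per fold the embedding is fitted on the training annotations only; the
    held-out cells are projected, the combined 2-D cloud is clustered, and
    held-out cells receive their cluster's majority class.  Accuracy counts
    correct predictions among held-out cells that received an assignment;
    the unassigned fraction is reported separately.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2 folds")
    annotations = annotations.reindex(records.index)
    if annotations.isna().any():
        raise ValueError("cross_validate expects fully annotated records")
    counts = annotations.value_counts()
    small = counts[counts < k]
    if len(small):
        raise ValueError(
            f"class {small.index[0]!r} has {small.iloc[0]} members, "
            f"fewer than k={k}"
        )
    records = records.reset_index(drop=True)
    annotations = annotations.reset_index(drop=True)
    classes = sorted(annotations.unique())

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    y_true_all, y_pred_all, fold_acc = [], [], []
    for fold, (train_idx, test_idx) in enumerate(
            skf.split(records, annotations)):
        train = records.iloc[train_idx]
        test = records.iloc[test_idx]
        model = fit_embedding(train, annotations.iloc[train_idx],
                              seed=int(seed) + fold, **fit_kwargs)
        coords = np.vstack([model.training_embedding, project(model, test)])
        cluster_ids = cluster(coords, model.min_cluster_size)
        masked = pd.concat([
            annotations.iloc[train_idx],
            pd.Series([np.nan] * len(test_idx)),
        ], ignore_index=True)
        assigned = vote(cluster_ids, masked)
        pred = assigned.iloc[len(train_idx):].to_numpy()
        truth = annotations.iloc[test_idx].to_numpy()
        y_true_all.append(truth)
        y_pred_all.append(pred)
        ok = pred != UNASSIGNED
        fold_acc.append(float((pred[ok] == truth[ok]).mean()) if ok.any() else 0.0)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    assigned_mask = y_pred != UNASSIGNED
    accuracy = (float((y_pred[assigned_mask] == y_true[assigned_mask]).mean())
                if assigned_mask.any() else 0.0)
    unassigned_fraction = float((~assigned_mask).mean())
    cm = _sk_confusion(y_true, y_pred, labels=classes + [UNASSIGNED])
    confusion = pd.DataFrame(cm[:len(classes)], index=classes,
                             columns=classes + [UNASSIGNED])
    return CrossValidationResult(
        accuracy=accuracy,
        unassigned_fraction=unassigned_fraction,
        confusion=confusion,
        per_fold_accuracy=fold_acc,
    )


def save_model(model: MorphologyModel, path) -> None:
    """Serialize a fitted model (joblib pickle)."""
    import joblib

    joblib.dump(model, path)


def load_model(path) -> MorphologyModel:
    import joblib

    return joblib.load(path)
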