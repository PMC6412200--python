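"""Relief-F ranking, weighted RBF-SVM training and dual-model prediction.

The training set (consistently oriented recordings) yields two classifiers:
the axis-dependent model on the full 254-feature space (top 10 features
after Relief-F ranking) and the rotation-invariant surrogate on the
90-feature space (top 40).  At prediction time the orientation module
routes each recording to one of the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .core_io import (
    ActivityLabel,
    AnnotationTrack,
    Recording,
    build_labels,
    segment_windows,
)
from .features import (
    AXIS_MANIFEST,
    ROTINV_MANIFEST,
    ScalerParams,
    apply_scaler,
    extract_matrix,
    fit_scaler,
    rotation_invariant_reduce,
)
from .harmonize import align_baseline
from .orientation import ModelChoice, ReferenceSpace, fit_reference_space, select_model
from .preprocess import compute_bundle
from .temporal import PredictionSeries

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)
DEFAULT_GAMMA_GRID = (0.1, 0.5, 1.0, 2.24, 3.12, 5.0)
N_SELECT_AXIS = 10
N_SELECT_ROTINV = 40
CV_FOLDS = 4
RELIEF_K = 10

LABEL_ORDER = [l.value for l in ActivityLabel]


@dataclass
class SvmConfig:
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    cv_folds: int = CV_FOLDS
    seed: int = 0


@dataclass
class TrainedModel:
    """Scaler, selected feature indices and fitted SVM for one feature space."""

    scaler: ScalerParams
    selected: np.ndarray
    svm: SVC
    C: float
    gamma: float
    cv_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = apply_scaler(X, self.scaler)[:, self.selected]
        return self.svm.predict(Z)


@dataclass
class ModelBundle:
    axis_model: TrainedModel
    rotinv_model: TrainedModel
    reference_space: ReferenceSpace
    manifest_digests: dict[str, str]
    version: str = _pkg_version

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError("file does not contain a ModelBundle")
        if bundle.manifest_digests != current_manifest_digests():
            raise RuntimeError(
                "model bundle was trained with different feature manifests"
            )
        return bundle


def current_manifest_digests() -> dict[str, str]:
    return {"AXIS_DEP": AXIS_MANIFEST.digest(), "ROT_INV": ROTINV_MANIFEST.digest()}


def class_weights(y: Sequence) -> dict:
    """Weights inverse-proportional to class counts, normalized to mean 1."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    inv = 1.0 / counts
    inv = inv / inv.mean()  # sum equals the number of classes
    return {c: float(w) for c, w in zip(classes, inv)}


def relief_f(
    X: np.ndarray,
    y: Sequence,
    k_neighbors: int = RELIEF_K,
    n_iter: Optional[int] = None,
) -> np.ndarray:
    """Multiclass Relief-F feature weights.

    Every instance (or the first ``n_iter``) contributes: for each feature,
    distances to its k nearest same-class hits decrease the weight, and
    distances to the k nearest misses of every other class increase it,
    scaled by the prior of the miss class relative to the complement of the
    instance's class.  Features are min-max scaled internally; instances are
    compared with Manhattan distance.  Ranking = descending weight, ties by
    feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("relief_f needs >= 2 classes")
    if k_neighbors >= counts.min():
        raise ValueError(
            f"k_neighbors={k_neighbors} must be below the smallest class size"
            f" ({counts.min()})"
        )
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    n_iter = n if n_iter is None else min(n_iter, n)

    # full pairwise Manhattan distances; ~20 MB at protocol-cohort scale
    from scipy.spatial.distance import cdist

    dist = cdist(Z, Z, metric="cityblock") if n * n * 8 < 5e8 else None
    W = np.zeros(d)
    for i in range(n_iter):
        if dist is None:
            di = np.abs(Z - Z[i]).sum(axis=1)
        else:
            di = dist[i]
        for c in classes:
            mask = y == c
            if c == y[i]:
                mask = mask.copy()
                mask[i] = False
            idx = np.flatnonzero(mask)
            order = idx[np.argsort(di[idx], kind="stable")][:k_neighbors]
            contrib = np.abs(Z[order] - Z[i]).sum(axis=0) / (k_neighbors * n_iter)
            if c == y[i]:
                W -= contrib
            else:
                W += priors[c] / (1.0 - priors[y[i]]) * contrib
    return W


def rank_features(weights: np.ndarray, n_select: int) -> np.ndarray:
    """Top-n feature indices by descending weight, ties by index."""
    order = np.lexsort((np.arange(len(weights)), -weights))
    return np.sort(order[:n_select])


def grid_search_svm(
    X: np.ndarray,
    y: Sequence,
    config: SvmConfig = SvmConfig(),
) -> tuple[float, float, float]:
    """Best (C, gamma, cv_accuracy) on a stratified 4-fold grid search.

    Ties resolved toward the smallest C, then the smallest gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not len(config.c_grid) or not len(config.gamma_grid):
        raise ValueError("empty parameter grid")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.cv_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than"
            f" cv_folds={config.cv_folds}"
        )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(cv.split(X, y))
    weights = class_weights(y)
    best = None
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            accs = []
            for tr, va in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weights(y[tr]))
                clf.fit(X[tr], y[tr])
                accs.append((clf.predict(X[va]) == y[va]).mean())
            acc = float(np.mean(accs))
            if best is None or acc > best[2]:
                best = (C, gamma, acc)
    logger.info("grid search best C=%g gamma=%g cv_acc=%.4f", *best)
    return best


def recording_features(
    rec: Recording, starts: np.ndarray, window_len: int
) -> np.ndarray:
    """Axis-dependent feature matrix for given window starts of a recording."""
    bundle = compute_bundle(rec.acc(), rec.sampling_rate_hz)
    return extract_matrix(bundle, starts, window_len, rec.sampling_rate_hz, AXIS_MANIFEST)


def build_training_matrix(
    recs: Sequence[Recording],
    tracks: Sequence[AnnotationTrack],
    *,
    merge_labels: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack labelled windows of all recordings.

    Returns (X_axis, y, subject_index); windows without a label are dropped.
    """
    mats, labels, subj = [], [], []
    for si, (rec, track) in enumerate(zip(recs, tracks)):
        merged = build_labels(track) if merge_labels else track
        ws = segment_windows(rec, merged)
        keep = [i for i, l in enumerate(ws.labels) if l is not None]
        X = recording_features(rec, ws.start_indices[keep], ws.window_len)
        mats.append(X)
        labels.extend(ws.labels[i].value for i in keep)
        subj.extend([si] * len(keep))
    return np.vstack(mats), np.asarray(labels), np.asarray(subj)


def _fit_space(
    X: np.ndarray, y: np.ndarray, n_select: int, config: SvmConfig
) -> TrainedModel:
    scaler = fit_scaler(X)
    Z = apply_scaler(X, scaler)
    counts = np.unique(y, return_counts=True)[1]
    k = min(RELIEF_K, counts.min() - 1)
    weights = relief_f(Z, y, k_neighbors=k)
    selected = rank_features(weights, n_select)
    C, gamma, cv_acc = grid_search_svm(Z[:, selected], y, config)
    svm = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weights(y))
    svm.fit(Z[:, selected], y)
    return TrainedModel(scaler, selected, svm, C, gamma, cv_acc)


def train_bundle(
    train_recs: Sequence[Recording],
    tracks: Sequence[AnnotationTrack],
    *,
    n_select_axis: int = N_SELECT_AXIS,
    n_select_rotinv: int = N_SELECT_ROTINV,
    config: Optional[SvmConfig] = None,
) -> ModelBundle:
    """Train the dual-model bundle from annotated reference recordings."""
    config = config or SvmConfig()
    space = fit_reference_space(train_recs)
    # features come from the baseline-corrected measurement space, exactly
    # as they will at prediction time
    aligned = [align_baseline(r, space.reference_baseline) for r in train_recs]
    X_axis, y, _ = build_training_matrix(aligned, tracks)
    missing = set(LABEL_ORDER) - set(y)
    if missing:
        raise ValueError(f"training cohort lacks class(es): {sorted(missing)}")
    logger.info("training windows=%d features=%d", *X_axis.shape)
    # the surrogate predicts on recordings as measured (no alignment is
    # possible in an unknown orientation), so it also trains on them
    X_axis_raw, y_raw, _ = build_training_matrix(train_recs, tracks)
    assert np.array_equal(y, y_raw)
    X_rot = rotation_invariant_reduce(X_axis_raw, ROTINV_MANIFEST)
    axis_model = _fit_space(X_axis, y, n_select_axis, config)
    rotinv_model = _fit_space(X_rot, y, n_select_rotinv, config)
    return ModelBundle(
        axis_model=axis_model,
        rotinv_model=rotinv_model,
        reference_space=space,
        manifest_digests=current_manifest_digests(),
    )


def predict_windows(
    rec: Recording,
    bundle: ModelBundle,
    *,
    force_model: Optional[ModelChoice] = None,
) -> PredictionSeries:
    """Route, align, extract features and classify every window."""
    choice = force_model or select_model(rec, bundle.reference_space)
    if choice is ModelChoice.AXIS_DEPENDENT:
        aligned = align_baseline(rec, bundle.reference_space.reference_baseline)
        ws = segment_windows(aligned)
        X_axis = recording_features(aligned, ws.start_indices, ws.window_len)
        pred = bundle.axis_model.predict(X_axis)
    else:
        # a per-axis shift has no meaning in an unknown orientation, and
        # aligning a rotated recording would inject a large non-rotational
        # offset; the invariant features need the recording as measured
        ws = segment_windows(rec)
        X_axis = recording_features(rec, ws.start_indices, ws.window_len)
        pred = bundle.rotinv_model.predict(
            rotation_invariant_reduce(X_axis, ROTINV_MANIFEST)
        )
    return PredictionSeries(
        window_start_s=ws.start_times_s(),
        raw_labels=[ActivityLabel(p) for p in pred],
        model_used=choice,
        hop_s=ws.hop / rec.sampling_rate_hz,
    )
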