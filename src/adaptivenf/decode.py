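"""Whole-brain brain-state classifier: training, hyperplane distances,
block-wise cross-validation, and forward-encoding maps.

The classifier is a support vector machine (RBF kernel, C = 1 by default,
libsvm via scikit-learn) trained on z-scored gray-matter voxel time courses
to separate attend-to-face TRs (+1) from attend-to-word TRs (-1); rest TRs
are censored out. The signed decision-function value of a new volume is its
hyperplane distance (HD): positive means the volume resembles the trained
attend-face state.

Classifier weights form a backward (decoding) model; to interpret them
spatially they are transformed into a forward encoding pattern
A = Cov(X) w / var(X w), which rescales each voxel by how much of the
decoded signal it actually expresses and suppresses voxels that enter the
decoder only to cancel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .preproc import FeatureMatrix

LABEL_FACE = 1
LABEL_WORD = -1
LABEL_REST = 0


@dataclass(frozen=True)
class ClassifierModel:
    """Trained SVM plus the feature-to-voxel map and training data."""

    svc: SVC
    kernel: str
    C: float
    X_train: np.ndarray
    y_train: np.ndarray
    voxel_indices: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]


@dataclass(frozen=True)
class HDTrace:
    """Per-TR signed hyperplane distances aligned to a run's TR grid.

    ``valid`` is False where no HD was emitted (warmup, or TRs excluded
    from prediction); invalid entries hold NaN.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if len(self.values) != len(self.valid):
            raise ValueError("values and valid must have equal length")


@dataclass(frozen=True)
class WeightMap:
    """Per-voxel weights, either the raw backward model or its forward transform."""

    values: np.ndarray  # one scalar per feature/voxel
    kind: str  # "backward" | "forward"
    voxel_indices: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def to_volume(self) -> np.ndarray:
        if self.voxel_indices is None or self.grid_shape is None:
            raise ValueError("weight map has no voxel geometry attached")
        vol = np.zeros(int(np.prod(self.grid_shape)))
        vol[self.voxel_indices] = self.values
        return vol.reshape(self.grid_shape)


def _as_array(features) -> tuple[np.ndarray, np.ndarray | None, tuple | None]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.voxel_indices, features.grid_shape
    return np.asarray(features, dtype=float), None, None


def train_classifier(
    features,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: str = "rbf",
    keep: np.ndarray | None = None,
    tol: float = 1e-8,
) -> ClassifierModel:
    """Fit the brain-state SVM on task TRs.

    ``labels`` holds +1 (attend-face), -1 (attend-word) or 0 (rest) per TR;
    rest TRs and TRs excluded by ``keep`` are censored out before fitting.
    The fit is deterministic given its inputs.
    """
    X, vidx, grid = _as_array(features)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length does not match feature rows")
    sel = labels != LABEL_REST
    if keep is not None:
        sel &= np.asarray(keep, dtype=bool)
    X, y = X[sel], labels[sel].astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need both classes to train; got only {classes}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"need >=2 TRs for class {c}")
    svc = SVC(kernel=kernel, C=C, gamma="scale", tol=tol)
    svc.fit(X, y)
    return ClassifierModel(
        svc=svc, kernel=kernel, C=C, X_train=X, y_train=y,
        voxel_indices=vidx, grid_shape=grid,
    )


def predict_hd(model: ClassifierModel, feature_vector: np.ndarray) -> float:
    """Signed decision-function value for one volume; positive = attend-face-like."""
    v = np.asarray(feature_vector, dtype=float)
    if v.ndim == 1:
        if len(v) != model.n_features:
            raise ValueError(
                f"feature vector length {len(v)} != model features {model.n_features}"
            )
        return float(model.svc.decision_function(v[None, :])[0])
    if v.shape[1] != model.n_features:
        raise ValueError("feature columns do not match model features")
    return model.svc.decision_function(v)


def _zscore_cols(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mean) / sd


def crossvalidate_blocks(
    features,
    labels: np.ndarray,
    block_ids: np.ndarray,
    valence: np.ndarray | None = None,
    valence_filter: str = "all",
    C: float = 1.0,
    kernel: str = "rbf",
    leakage_free_scaling: bool = True,
) -> float:
    """Leave-one-block-pair-out cross-validated accuracy.

    Each fold holds out one attend-to-word and one attend-to-face block
    jointly (the j-th of each in block-index order), retrains on the
    remaining blocks, and scores the held-out TRs; the returned accuracy is
    the mean per-fold proportion correct over all folds, so that every block
    serves once as test data. ``valence_filter`` restricts the blocks
    entering the analysis to trauma- or neutral-dominant ones. By default
    z-scoring statistics come from the training folds only; set
    ``leakage_free_scaling=False`` to standardize once on the full series
    before splitting.
    """
    X, _, _ = _as_array(features)
    labels = np.asarray(labels)
    block_ids = np.asarray(block_ids)

    sel = labels != LABEL_REST
    if valence_filter != "all":
        if valence is None:
            raise ValueError("valence vector required for a valence filter")
        want = {"trauma": 1, "neutral": -1}[valence_filter]
        sel &= np.asarray(valence) == want
    X, y, b = X[sel], labels[sel].astype(int), block_ids[sel]

    word_blocks = sorted(set(b[y == LABEL_WORD]))
    face_blocks = sorted(set(b[y == LABEL_FACE]))
    for name, blocks in (("attend_word", word_blocks), ("attend_face", face_blocks)):
        if len(blocks) < 2:
            raise ValueError(f"need >=2 {name} blocks after filtering, got {len(blocks)}")
    if len(word_blocks) != len(face_blocks):
        raise ValueError("unbalanced block counts between classes")

    if not leakage_free_scaling:
        X = _zscore_cols(X, X.mean(axis=0), X.std(axis=0))

    fold_acc = []
    for wb, fb in zip(word_blocks, face_blocks):
        test = (b == wb) | (b == fb)
        train = ~test
        Xtr, Xte = X[train], X[test]
        if leakage_free_scaling:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            Xtr = _zscore_cols(Xtr, mu, sd)
            Xte = _zscore_cols(Xte, mu, sd)
        svc = SVC(kernel=kernel, C=C, gamma="scale", tol=1e-8)
        svc.fit(Xtr, y[train])
        fold_acc.append(float((svc.predict(Xte) == y[test]).mean()))
    return float(np.mean(fold_acc))


def backward_weights(model: ClassifierModel) -> WeightMap:
    """Voxel-wise decoder weights.

    For a linear kernel these are the exact primal weights; for RBF the
    pre-image approximation w = sum_i alpha_i y_i x_i over support vectors is
    used (the spatial map of a nonlinear machine is not uniquely defined).
    """
    w = (model.svc.dual_coef_ @ model.svc.support_vectors_).ravel()
    return WeightMap(
        values=w, kind="backward",
        voxel_indices=model.voxel_indices, grid_shape=model.grid_shape,
    )


def forward_encode(model: ClassifierModel, features=None) -> WeightMap:
    """Transform backward weights into a forward encoding pattern.

    A = Cov(X) w / var(X w) over the training feature matrix X (or
    ``features`` if given), normalized to unit maximum absolute value. The
    forward pattern is the activation map of the decoded latent signal and,
    unlike the backward map, is interpretable voxel by voxel.
    """
    w = backward_weights(model).values
    X = model.X_train if features is None else _as_array(features)[0]
    if X.shape[1] != len(w):
        raise ValueError("features do not match the model's voxel set")
    Xc = X - X.mean(axis=0)
    proj = Xc @ w
    var = float(proj @ proj) / (len(proj) - 1)
    if var < 1e-24:
        raise ValueError("degenerate variance: X w is constant")
    A = (Xc.T @ proj) / (len(proj) - 1) / var
    A = A / np.abs(A).max()
    return WeightMap(
        values=A, kind="forward",
        voxel_indices=model.voxel_indices, grid_shape=model.grid_shape,
    )
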