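"""Multimodal QST classification network.

Three inputs are fused per case: the raw sagittal slice with the largest
tumor area, the one-hot encoded segmentation of that slice, and the 34
clinical knowledge-based features extracted from the full 3D label map.
A small residual CNN (the image branch) consumes the 8-channel stack
(1 intensity + 7 one-hot) and emits 32 depth features; these are
concatenated with the standardized clinical features into a 66-dimensional
vector and classified by a two-layer discriminator trained with 3-class
cross-entropy.

The image branch is desk-scale by default (it plays the role a large
pretrained backbone would at full scale — the architecture exercised here
is the fusion, not the backbone capacity); width and feature dimension are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .features import N_FEATURES, ClinicalFeatures, extract_features
from .label_schema import (
    N_CLASSES,
    LabelMap,
    MRIVolume,
    one_hot_encode,
    select_max_tumor_slice,
)
from .metrics import ClassificationReport, classification_report, make_cv_folds
from .nn.core import Module

__all__ = [
    "ClassifierConfig",
    "prepare_inputs",
    "assemble_inputs",
    "extract_depth_features",
    "fuse_and_classify",
    "FusionQSTClassifier",
    "train_classifier",
]

_TYPES = np.asarray(["Q", "S", "T"])


@dataclass
class ClassifierConfig:
    """Architecture and training settings for the fusion classifier."""

    image_width: int = 8
    depth_feature_dim: int = 32
    hidden: int = 32
    epochs: int = 20
    batch_size: int = 16
    lr: float = 2e-3
    seed: int = 0

    @property
    def fused_dim(self) -> int:
        return self.depth_feature_dim + N_FEATURES


def prepare_inputs(mri: MRIVolume, label_map: LabelMap):
    """(slice image, one-hot slice, ClinicalFeatures) for one case.

    The sagittal slice with the largest tumor area is selected; its labels
    are one-hot encoded (7 channels, background included); the clinical
    features come from the full 3D map.
    """
    if mri.shape != label_map.shape:
        raise ValueError("MRI and label map shapes differ")
    idx = select_max_tumor_slice(label_map)
    sl = mri.voxels[idx].astype(np.float64)
    onehot = one_hot_encode(label_map)[:, idx].astype(np.float64)
    feats = extract_features(label_map)
    return sl, onehot, feats


def assemble_inputs(cohort):
    """Stack prepared inputs for a cohort of (MRIVolume, LabelMap, ...) items.

    Returns ``(images, clinical, labels)``: images (n, 8, H, W) — the
    intensity slice stacked with its one-hot segmentation — clinical
    (n, 34) with NaN at missing entries, and the QST labels as strings
    (or None when the cohort carries no types).
    """
    images, clinical, labels = [], [], []
    for item in cohort:
        mri, lm = item[0], item[1]
        sl, onehot, feats = prepare_inputs(mri, lm)
        mu, sd = sl.mean(), max(sl.std(), 1e-6)
        images.append(np.concatenate([((sl - mu) / sd)[None], onehot], axis=0))
        vals = feats.values.copy()
        vals[feats.missing] = np.nan
        clinical.append(vals)
        if len(item) > 2:
            labels.append(str(item[2]))
    return (
        np.asarray(images),
        np.asarray(clinical),
        np.asarray(labels) if labels else None,
    )


class _ResBlock(Module):
    def __init__(self, c_in, c_out, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.act1 = nn.LeakyReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng)
        self.proj = nn.Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None
        self.act_out = nn.LeakyReLU()

    def forward(self, x):
        h = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.act_out.forward(h + s)

    def backward(self, g):
        g = self.act_out.backward(g)
        gx = self.conv1.backward(self.act1.backward(self.conv2.backward(g)))
        gx = gx + (self.proj.backward(g) if self.proj is not None else g)
        return gx


class _ImageBranch(Module):
    """Residual CNN mapping the (8, H, W) stack to the depth-feature vector."""

    def __init__(self, cfg: ClassifierConfig, rng):
        w = cfg.image_width
        self.conv_in = nn.Conv2d(1 + N_CLASSES, w, 3, rng)
        self.act_in = nn.LeakyReLU()
        self.pool1 = nn.MaxPool2()
        self.block1 = _ResBlock(w, w, rng)
        self.pool2 = nn.MaxPool2()
        self.block2 = _ResBlock(w, 2 * w, rng)
        self.pool3 = nn.MaxPool2()
        self.gap = nn.GlobalAvgPool()
        self.fc = None        # built lazily once spatial size is known
        self._rng = rng
        self._out_dim = cfg.depth_feature_dim
        self._gap_dim = 2 * w

    def forward(self, x):
        h = self.pool1.forward(self.act_in.forward(self.conv_in.forward(x)))
        h = self.pool2.forward(self.block1.forward(h))
        h = self.pool3.forward(self.block2.forward(h))
        h = self.gap.forward(h)
        if self.fc is None:
            self.fc = nn.Linear(self._gap_dim, self._out_dim, self._rng)
        return self.fc.forward(h)

    def backward(self, g):
        g = self.gap.backward(self.fc.backward(g))
        g = self.block2.backward(self.pool3.backward(g))
        g = self.block1.backward(self.pool2.backward(g))
        return self.conv_in.backward(self.act_in.backward(self.pool1.backward(g)))


class _Discriminator(Module):
    def __init__(self, cfg: ClassifierConfig, rng):
        self.fc1 = nn.Linear(cfg.fused_dim, cfg.hidden, rng)
        self.act = nn.LeakyReLU()
        self.fc2 = nn.Linear(cfg.hidden, 3, rng)

    def forward(self, x):
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, g):
        return self.fc1.backward(self.act.backward(self.fc2.backward(g)))


class FusionQSTClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator for the depth + clinical fusion network.

    ``fit(X, y)`` expects ``X = (images, clinical)`` as produced by
    :func:`assemble_inputs` and string labels ``y`` in {'Q','S','T'}.
    Clinical features are z-scored with the training statistics; missing
    entries (NaN) are imputed to the training mean.  ``predict_proba``
    returns the 3-class probability simplex.
    """

    def __init__(self, image_width=8, depth_feature_dim=32, hidden=32,
                 epochs=20, batch_size=16, lr=2e-3, random_state=0):
        self.image_width = image_width
        self.depth_feature_dim = depth_feature_dim
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            image_width=self.image_width, depth_feature_dim=self.depth_feature_dim,
            hidden=self.hidden, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, seed=self.random_state,
        )

    @staticmethod
    def _split_X(X):
        images, clinical = X
        images = np.asarray(images, dtype=np.float64)
        clinical = np.asarray(clinical, dtype=np.float64)
        if clinical.shape[1] != N_FEATURES:
            raise ValueError(f"clinical matrix must have {N_FEATURES} columns")
        if images.shape[1] != 1 + N_CLASSES:
            raise ValueError(f"images must have {1 + N_CLASSES} channels")
        return images, clinical

    def _standardize(self, clinical):
        z = (clinical - self.clinical_mean_) / self.clinical_std_
        return np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)

    def fit(self, X, y):
        images, clinical = self._split_X(X)
        y = np.asarray([str(t) for t in y])
        self.classes_ = _TYPES.copy()
        missing_class = set(self.classes_) - set(y)
        if missing_class:
            raise ValueError(f"training data lacks classes {sorted(missing_class)}")
        y_idx = np.searchsorted(self.classes_, y)

        self.clinical_mean_ = np.nanmean(clinical, axis=0)
        sd = np.nanstd(clinical, axis=0)
        self.clinical_std_ = np.where(sd > 1e-8, sd, 1.0)
        z = self._standardize(clinical)

        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        self.image_branch_ = _ImageBranch(cfg, rng)
        self.discriminator_ = _Discriminator(cfg, rng)
        # one forward builds the lazy fc layer so the optimizer sees it
        self.image_branch_.forward(images[:1])
        params = self.image_branch_.params() + self.discriminator_.params()
        opt = nn.Adam(params, lr=cfg.lr)

        n = images.shape[0]
        order_rng = np.random.default_rng(cfg.seed + 1)
        history = []
        for _ in range(cfg.epochs):
            order = order_rng.permutation(n)
            epoch_loss, n_b = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                depth = self.image_branch_.forward(images[idx])
                fused = np.concatenate([depth, z[idx]], axis=1)
                logits = self.discriminator_.forward(fused)
                loss, glog = nn.softmax_cross_entropy(logits, y_idx[idx])
                opt.zero_grad()
                gf = self.discriminator_.backward(glog)
                self.image_branch_.backward(gf[:, : cfg.depth_feature_dim])
                opt.step()
                epoch_loss += loss
                n_b += 1
            history.append(epoch_loss / n_b)
        self.loss_history_ = np.asarray(history)
        self.config_ = cfg
        return self

    def extract_depth_features(self, images) -> np.ndarray:
        """Depth-feature vectors (n, depth_feature_dim) from image stacks."""
        images = np.asarray(images, dtype=np.float64)
        out = []
        for start in range(0, images.shape[0], self.batch_size):
            out.append(self.image_branch_.forward(images[start : start + self.batch_size]))
        return np.concatenate(out, axis=0)

    def decision_function(self, X) -> np.ndarray:
        images, clinical = self._split_X(X)
        z = self._standardize(clinical)
        depth = self.extract_depth_features(images)
        fused = np.concatenate([depth, z], axis=1)
        if fused.shape[1] != self.config_.fused_dim:
            raise ValueError("fused dimension mismatch")
        return self.discriminator_.forward(fused)

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def extract_depth_features(network: FusionQSTClassifier, slice_image, onehot_slice) -> np.ndarray:
    """Depth features for one case from a fitted classifier."""
    sl = np.asarray(slice_image, dtype=np.float64)
    mu, sd = sl.mean(), max(sl.std(), 1e-6)
    stack = np.concatenate([((sl - mu) / sd)[None], np.asarray(onehot_slice, dtype=np.float64)])
    return network.extract_depth_features(stack[None])[0]


def fuse_and_classify(network: FusionQSTClassifier, depth: np.ndarray, clinical) -> np.ndarray:
    """Probability triple from a 32-vector of depth features + clinical features."""
    depth = np.asarray(depth, dtype=np.float64)
    if isinstance(clinical, ClinicalFeatures):
        vals = clinical.values.copy()
        vals[clinical.missing] = np.nan
    else:
        vals = np.asarray(clinical, dtype=np.float64)
    if depth.size + vals.size != network.config_.fused_dim:
        raise ValueError(
            f"fused length {depth.size + vals.size} != {network.config_.fused_dim}"
        )
    z = network._standardize(vals[None])
    fused = np.concatenate([depth[None], z], axis=1)
    logits = network.discriminator_.forward(fused)
    return nn.softmax(logits, axis=1)[0]


def train_classifier(images, clinical, y, n_folds: int = 5, seed: int = 0,
                     **estimator_params):
    """Stratified k-fold cross-validated training of the fusion classifier.

    Each fold trains a fresh network on the remaining folds; test
    predictions are aggregated over all folds (every sample predicted
    exactly once) and scored.  Returns ``(models, predictions, report)``.
    """
    y = np.asarray([str(t) for t in y])
    n = len(y)
    folds = make_cv_folds(n, n_folds, labels=y, seed=seed)
    models, preds = [], np.empty(n, dtype=object)
    proba = np.full((n, 3), np.nan)
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        est = FusionQSTClassifier(random_state=seed + f, **estimator_params)
        est.fit((images[train_mask], clinical[train_mask]), y[train_mask])
        p = est.predict_proba((images[test_idx], clinical[test_idx]))
        proba[test_idx] = p
        preds[test_idx] = est.classes_[np.argmax(p, axis=1)]
        models.append(est)
    preds = np.asarray([str(p) for p in preds])
    report = classification_report(y, preds)
    report.probabilities = proba
    return models, preds, report
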