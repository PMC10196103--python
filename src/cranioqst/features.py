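"""Clinical knowledge-based feature extraction from sellar label maps.

From one 7-class label map, 34 scalar features are computed:

* 18 — per-tissue diameters: the axis-aligned bounding-box extent along
  LR, AP and SI for each of the six labeled tissues (cm);
* 6  — per-tissue volumes (cm³);
* 3  — tumor position relative to the brain: centroid offset per axis,
  normalized by the brain's extent along that axis;
* 3  — tumor position relative to the sellar region: centroid offset from
  the tuberculum-sellae landmark, normalized by the tumor's own extent;
* 1  — relative SI location of the tumor's maximum transverse (AP)
  diameter, in [0, 1] (0 = inferior: "positive pyramid"; 1 = superior:
  "inverted pyramid");
* 1  — tumor volume in the pituitary fossa (below the tuberculum plane, cm³);
* 1  — tumor volume anterior to the tuberculum sellae (cm³);
* 1  — tumor aspect ratio AP/SI (dimensionless).

The tuberculum sellae is operationalized as the most superior sphenoid-sinus
voxel (ties: most anterior, then lowest slice index); the pituitary fossa as
the half-space strictly inferior to it, "anterior" as strictly anterior to
it.  Absent tissues report zero extents/volume and carry an explicit
missing flag — pituitary absence is itself diagnostic and must be
distinguishable from a tiny-but-present gland.  The LR components of the
two position features are reported as magnitudes: laterality carries no
diagnostic meaning in the sagittal QST assessment, and this makes every
feature invariant to a left-right mirror of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .label_schema import (
    BRAIN,
    LABELS,
    N_CLASSES,
    SPHENOID_SINUS,
    TUMOR,
    EmptyTumorError,
    LabelMap,
)

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "SellarLandmark",
    "ClinicalFeatures",
    "LandmarkUnavailableError",
    "tissue_volume",
    "tissue_extents",
    "locate_tuberculum",
    "tumor_fossa_volume",
    "tumor_anterior_volume",
    "relative_position",
    "widest_level_fraction",
    "aspect_ratio",
    "extract_features",
    "ClinicalFeatureExtractor",
]

N_FEATURES = 34

_AXES = ("lr", "ap", "si")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{LABELS[c]}_extent_{ax}_cm" for c in range(1, N_CLASSES) for ax in _AXES]
    + [f"{LABELS[c]}_volume_cm3" for c in range(1, N_CLASSES)]
    + [f"tumor_vs_brain_{ax}" for ax in _AXES]
    + [f"tumor_vs_sella_{ax}" for ax in _AXES]
    + ["widest_level_fraction", "fossa_volume_cm3", "anterior_volume_cm3", "aspect_ratio"]
)
assert len(FEATURE_NAMES) == N_FEATURES


class LandmarkUnavailableError(ValueError):
    """No sphenoid-sinus voxels: the tuberculum landmark cannot be placed."""


@dataclass(frozen=True)
class SellarLandmark:
    """Tuberculum-sellae surrogate: a voxel on the sphenoid sinus.

    ``k_ts`` (axis-2 index) defines the fossa plane — tumor strictly below
    it counts as intrasellar; ``j_ts`` (axis-1 index) the anterior plane.
    """

    index: tuple[int, int, int]

    @property
    def j_ts(self) -> int:
        return self.index[1]

    @property
    def k_ts(self) -> int:
        return self.index[2]

    def position_mm(self, spacing) -> np.ndarray:
        return (np.asarray(self.index) + 0.5) * np.asarray(spacing)


@dataclass
class ClinicalFeatures:
    """The 34-element feature vector with per-entry missing flags."""

    values: np.ndarray           # (34,) float64; 0 or stale where missing
    missing: np.ndarray          # (34,) bool
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != (N_FEATURES,) or self.missing.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features")

    def __len__(self) -> int:
        return N_FEATURES

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def is_missing(self, name: str) -> bool:
        return bool(self.missing[self.names.index(name)])

    def to_series(self) -> pd.Series:
        vals = self.values.copy()
        vals[self.missing] = np.nan
        return pd.Series(vals, index=list(self.names))


def _check_label(label: int) -> None:
    if not 1 <= int(label) < N_CLASSES:
        raise ValueError(f"label must be in 1..6, got {label}")


def tissue_volume(label_map: LabelMap, label: int) -> float:
    """Volume of one tissue in cm³ (voxel count x voxel volume)."""
    _check_label(label)
    n = int((label_map.voxels == label).sum())
    return n * label_map.voxel_volume_mm3 / 1000.0


def _bbox(mask: np.ndarray):
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        return None
    return [(int(ax.min()), int(ax.max())) for ax in idx]


def tissue_extents(label_map: LabelMap, label: int) -> tuple[float, float, float]:
    """Inclusive bounding-box extents (LR, AP, SI) of one tissue in cm.

    A single voxel spans one voxel edge per axis; an absent tissue reports
    zeros.
    """
    _check_label(label)
    bb = _bbox(label_map.voxels == label)
    if bb is None:
        return (0.0, 0.0, 0.0)
    return tuple(
        (hi - lo + 1) * d / 10.0 for (lo, hi), d in zip(bb, label_map.spacing)
    )


def locate_tuberculum(label_map: LabelMap) -> SellarLandmark:
    """Place the tuberculum-sellae surrogate on the sphenoid sinus.

    The most superior sinus voxel is chosen; ties resolve to the most
    anterior, then to the lowest slice index.
    """
    ii, jj, kk = np.nonzero(label_map.voxels == SPHENOID_SINUS)
    if ii.size == 0:
        raise LandmarkUnavailableError("no sphenoid-sinus voxels in the map")
    top = kk == kk.max()
    ii, jj, kk = ii[top], jj[top], kk[top]
    ant = jj == jj.max()
    ii, jj, kk = ii[ant], jj[ant], kk[ant]
    sel = int(np.argmin(ii))
    return SellarLandmark(index=(int(ii[sel]), int(jj[sel]), int(kk[sel])))


def tumor_fossa_volume(label_map: LabelMap, landmark: SellarLandmark) -> float:
    """Tumor volume strictly inferior to the tuberculum plane, in cm³."""
    mask = label_map.voxels == TUMOR
    n = int(mask[:, :, : landmark.k_ts].sum())
    return n * label_map.voxel_volume_mm3 / 1000.0


def tumor_anterior_volume(label_map: LabelMap, landmark: SellarLandmark) -> float:
    """Tumor volume strictly anterior to the tuberculum plane, in cm³.

    Voxels in the landmark's own AP plane count as posterior, so the
    anterior and posterior parts always sum to the total tumor volume.
    """
    mask = label_map.voxels == TUMOR
    n = int(mask[:, landmark.j_ts + 1 :, :].sum())
    return n * label_map.voxel_volume_mm3 / 1000.0


def _centroid_mm(label_map: LabelMap, label: int) -> np.ndarray:
    idx = np.nonzero(label_map.voxels == label)
    return (np.stack([ax.mean() for ax in idx]) + 0.5) * np.asarray(label_map.spacing)


def relative_position(label_map: LabelMap, reference: str = "brain") -> np.ndarray:
    """Normalized tumor position relative to the brain or the sellar landmark.

    ``reference='brain'``: (tumor centroid - brain centroid) per axis,
    normalized by the brain's extent.  ``reference='landmark'``: offset from
    the tuberculum position, normalized by the tumor's own extent.  The LR
    component is a magnitude; a positive AP component means the tumor lies
    anterior to the reference.
    """
    if not (label_map.voxels == TUMOR).any():
        raise EmptyTumorError("no tumor voxels")
    tc = _centroid_mm(label_map, TUMOR)
    if reference == "brain":
        if not (label_map.voxels == BRAIN).any():
            raise LandmarkUnavailableError("no brain voxels to reference")
        ref = _centroid_mm(label_map, BRAIN)
        norm = np.asarray(tissue_extents(label_map, BRAIN)) * 10.0
    elif reference == "landmark":
        lm = locate_tuberculum(label_map)
        ref = lm.position_mm(label_map.spacing)
        norm = np.asarray(tissue_extents(label_map, TUMOR)) * 10.0
    else:
        raise ValueError("reference must be 'brain' or 'landmark'")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (tc - ref) / norm
    out[0] = abs(out[0])
    return out


def widest_level_fraction(label_map: LabelMap) -> float:
    """Relative SI location of the tumor's maximum transverse (AP) diameter.

    For each SI level occupied by tumor, the AP extent of the tumor at that
    level is measured; the level of maximal extent k* (ties: lowest level)
    is mapped to (k* - k_min) / (k_max - k_min).  A single-level tumor
    reports 0.5.  Values below 0.5 indicate a downward-widening ("positive
    pyramid", S-like) shape; above 0.5 an upward-widening inverted pyramid
    (T-like).
    """
    mask = label_map.voxels == TUMOR
    if not mask.any():
        raise EmptyTumorError("no tumor voxels")
    levels = np.nonzero(mask.any(axis=(0, 1)))[0]
    k_min, k_max = int(levels.min()), int(levels.max())
    if k_min == k_max:
        return 0.5
    extents = np.full(k_max - k_min + 1, -1.0)
    for off, k in enumerate(range(k_min, k_max + 1)):
        jj = np.nonzero(mask[:, :, k].any(axis=0))[0]
        if jj.size:
            extents[off] = (jj.max() - jj.min() + 1) * label_map.spacing[1]
    k_star = k_min + int(np.argmax(extents))
    return (k_star - k_min) / (k_max - k_min)


def aspect_ratio(label_map: LabelMap) -> float:
    """Tumor AP extent over SI extent; > 1 indicates transverse growth."""
    ext = tissue_extents(label_map, TUMOR)
    if ext[2] == 0.0:
        raise EmptyTumorError("tumor absent or has zero SI extent")
    return ext[1] / ext[2]


def extract_features(label_map: LabelMap) -> ClinicalFeatures:
    """Assemble the full 34-feature vector from a label map.

    Requires tumor voxels.  If the sphenoid sinus (landmark) or brain is
    absent, the dependent entries are flagged missing and everything else is
    still computed.  Absent tissues report zero extents/volume with their
    entries flagged missing.
    """
    if not (label_map.voxels == TUMOR).any():
        raise EmptyTumorError("cannot extract features without tumor voxels")

    values = np.zeros(N_FEATURES)
    missing = np.zeros(N_FEATURES, dtype=bool)
    pos = 0

    present = {c: bool((label_map.voxels == c).any()) for c in range(1, N_CLASSES)}

    for c in range(1, N_CLASSES):
        ext = tissue_extents(label_map, c)
        values[pos : pos + 3] = ext
        if not present[c]:
            missing[pos : pos + 3] = True
        pos += 3

    for c in range(1, N_CLASSES):
        values[pos] = tissue_volume(label_map, c)
        if not present[c]:
            missing[pos] = True
        pos += 1

    try:
        values[pos : pos + 3] = relative_position(label_map, "brain")
    except LandmarkUnavailableError:
        missing[pos : pos + 3] = True
    pos += 3

    landmark = None
    try:
        landmark = locate_tuberculum(label_map)
        values[pos : pos + 3] = relative_position(label_map, "landmark")
    except LandmarkUnavailableError:
        missing[pos : pos + 3] = True
    pos += 3

    values[pos] = widest_level_fraction(label_map)
    pos += 1

    if landmark is not None:
        values[pos] = tumor_fossa_volume(label_map, landmark)
        values[pos + 1] = tumor_anterior_volume(label_map, landmark)
    else:
        missing[pos : pos + 2] = True
    pos += 2

    values[pos] = aspect_ratio(label_map)
    pos += 1
    assert pos == N_FEATURES

    return ClinicalFeatures(values=values, missing=missing)


class ClinicalFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping label maps to the 34-feature matrix.

    ``transform`` accepts a sequence of :class:`LabelMap` and returns an
    ``(n, 34)`` float array with NaN at missing entries.  Included so the
    extraction step composes with sklearn pipelines and the fusion
    classifier.
    """

    def fit(self, X=None, y=None):
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X):
        rows = []
        for lm in X:
            feats = extract_features(lm)
            row = feats.values.copy()
            row[feats.missing] = np.nan
            rows.append(row)
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
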