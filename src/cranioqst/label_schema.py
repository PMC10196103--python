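"""Seven-class sellar-region label schema, canonical orientation and NIfTI I/O.

The pipeline works on sagittal, contrast-enhanced T1 volumes of the sellar
region together with co-registered integer label maps.  Seven classes are
distinguished::

    0  background
    1  tumor (all tumor components, cyst walls included)
    2  pituitary gland + stalk (one class: the stalk is too small to label alone)
    3  sphenoid sinus (air space + bony wall / dura of the pituitary fossa)
    4  brain (cerebrum, cerebellum, brainstem)
    5  suprasellar cistern (may be absent when effaced by tumor)
    6  lateral ventricles

Canonical array orientation (our convention; arbitrary NIfTI input must be
reoriented to it first):

* axis 0 — left-right, the stack of sagittal slices;
* axis 1 — posterior -> anterior (larger index = more anterior);
* axis 2 — inferior -> superior (larger index = more superior).

The default voxel grid is strongly anisotropic: 6 mm slice thickness along
axis 0 and 0.45 mm in-plane, matching a routine sagittal sellar acquisition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "N_CLASSES",
    "LABELS",
    "BACKGROUND",
    "TUMOR",
    "PITUITARY",
    "SPHENOID_SINUS",
    "BRAIN",
    "CISTERN",
    "VENTRICLE",
    "DEFAULT_SPACING",
    "QSTType",
    "LabelMap",
    "MRIVolume",
    "SchemaViolationError",
    "EmptyTumorError",
    "read_volume",
    "write_volume",
    "one_hot_encode",
    "one_hot_decode",
    "select_max_tumor_slice",
    "load_label_schema",
]

N_CLASSES = 7

BACKGROUND = 0
TUMOR = 1
PITUITARY = 2
SPHENOID_SINUS = 3
BRAIN = 4
CISTERN = 5
VENTRICLE = 6

LABELS = {
    BACKGROUND: "background",
    TUMOR: "tumor",
    PITUITARY: "pituitary",
    SPHENOID_SINUS: "sphenoid_sinus",
    BRAIN: "brain",
    CISTERN: "suprasellar_cistern",
    VENTRICLE: "lateral_ventricle",
}

#: (left-right slice thickness, in-plane AP, in-plane SI) in mm.
DEFAULT_SPACING = (6.0, 0.45, 0.45)


class SchemaViolationError(ValueError):
    """A label map contains a value outside the seven-class schema."""


class EmptyTumorError(ValueError):
    """An operation requiring tumor voxels was applied to a tumor-free map."""


class QSTType(str):
    """QST tumor type: ``'Q'``, ``'S'`` or ``'T'``.

    Q — infrasellar/subdiaphragmatic, S — subarachnoidal (stalk cistern
    segment), T — pars tuberalis.  When a rule-based diagnosis ties, the
    priority is T > S > Q.
    """

    VALUES = ("Q", "S", "T")
    #: diagnostic priority used to break score ties (highest first)
    TIE_PRIORITY = ("T", "S", "Q")

    def __new__(cls, value: str):
        value = str(value).upper()
        if value not in cls.VALUES:
            raise ValueError(f"QST type must be one of {cls.VALUES}, got {value!r}")
        return super().__new__(cls, value)


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive floats, got {spacing}")
    return spacing


@dataclass
class LabelMap:
    """A 3D integer class-index volume in canonical orientation.

    Parameters
    ----------
    voxels : ndarray of int, shape (n_slices, n_ap, n_si)
        Class index per voxel, values in ``{0..6}``.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm along (LR, AP, SI).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if not np.array_equal(self.voxels, np.round(self.voxels)):
                raise SchemaViolationError("label map contains non-integer values")
            self.voxels = self.voxels.astype(np.int16)
        bad = (self.voxels < 0) | (self.voxels >= N_CLASSES)
        if bad.any():
            offending = int(self.voxels[bad].flat[0])
            raise SchemaViolationError(
                f"label value {offending} outside the 7-class schema {{0..6}}"
            )
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of one class."""
        return self.voxels == label

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        # spacing compared to float32 precision: NIfTI headers store zooms as float32
        return np.allclose(self.spacing, other.spacing, rtol=1e-6) and np.array_equal(
            self.voxels, other.voxels
        )


@dataclass
class MRIVolume:
    """A 3D scalar intensity volume co-registered with a :class:`LabelMap`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"MRI volume must be 3D, got shape {self.voxels.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_volume(path, expect_labels: bool = False):
    """Read a NIfTI file as an :class:`MRIVolume` or, with validation, a :class:`LabelMap`.

    Voxel spacing is taken from the header zooms.  The array is returned in
    file axis order; callers are responsible for canonical orientation.

    Raises
    ------
    IOError
        If the file cannot be read.
    SchemaViolationError
        If ``expect_labels`` and a voxel value falls outside ``{0..6}``.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if expect_labels:
        return LabelMap(np.asarray(data), spacing=spacing)
    return MRIVolume(np.asarray(data, dtype=np.float32), spacing=spacing)


def write_volume(vol, path) -> None:
    """Write a :class:`LabelMap` (int16) or :class:`MRIVolume` (float32) to NIfTI."""
    path = Path(path)
    if isinstance(vol, LabelMap):
        data = vol.voxels.astype(np.int16)
    else:
        data = vol.voxels.astype(np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def one_hot_encode(label_map: LabelMap) -> np.ndarray:
    """One-hot encode a label map to a (7, *spatial*) binary array.

    Channel ``c`` is 1 exactly where the voxel value equals ``c``; the
    channel sum is therefore 1 at every voxel.
    """
    lv = label_map.voxels
    out = np.zeros((N_CLASSES,) + lv.shape, dtype=np.uint8)
    for c in range(N_CLASSES):
        out[c] = lv == c
    return out

def one_hot_decode(one_hot: np.ndarray, spacing=DEFAULT_SPACING) -> LabelMap:
    """Inverse of :func:`one_hot_encode` (argmax over the channel axis)."""
    one_hot = np.asarray(one_hot)
    if one_hot.shape[0] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} channels, got {one_hot.shape[0]}")
    return LabelMap(np.argmax(one_hot, axis=0).astype(np.int16), spacing=spacing)


def select_max_tumor_slice(label_map: LabelMap) -> int:
    """Index along axis 0 of the sagittal slice with the largest tumor area.

    Ties are broken toward the smallest index.  Raises
    :class:`EmptyTumorError` when the map contains no tumor voxels.
    """
    counts = (label_map.voxels == TUMOR).sum(axis=(1, 2))
    if counts.sum() == 0:
        raise EmptyTumorError("label map contains no tumor voxels")
    return int(np.argmax(counts))


def load_label_schema() -> dict:
    """Load the machine-readable label schema shipped with the package."""
    with resources.files("cranioqst").joinpath("data/labels.json").open() as fh:
        return json.load(fh)
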