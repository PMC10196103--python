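"""Synthetic sellar-region phantom generator.

Every downstream stage — segmentation, feature extraction, scale scoring and
the fusion classifier — is testable without patient data by generating
synthetic MRI + label-map pairs whose morphology follows the three QST
growth archetypes:

* **Q** (infrasellar/subdiaphragmatic): grows upward out of the pituitary
  fossa, so the tumor has a small antero-posterior and a large
  supero-inferior diameter, a large intrasellar volume, an anterior
  position, and a pituitary that is compressed to near-invisibility.
* **S** (subarachnoidal): grows transversely in the suprasellar cistern,
  giving a large AP/SI aspect ratio, a large volume anterior to the
  tuberculum sellae, a positive-pyramid shape (widest level inferior) and
  no ventricular dilatation.
* **T** (pars tuberalis): grows up into the third ventricle, compressing
  the lateral ventricles (dilatation), sitting posteriorly, with an
  inverted-pyramid shape (widest level superior) and little intrasellar
  volume.

Geometry is built from ellipsoids and a stacked-ellipse tumor solid placed
relative to a sphenoid-sinus block whose superior-anterior corner serves as
the tuberculum-sellae landmark.  All positions and sizes are in physical mm
so the same anatomy voxelizes consistently onto the default high-resolution
grid and onto coarse desk-scale grids used for network training.  MRI
intensities are fixed per-class means plus i.i.d. Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .label_schema import (
    BACKGROUND,
    BRAIN,
    CISTERN,
    DEFAULT_SPACING,
    PITUITARY,
    SPHENOID_SINUS,
    TUMOR,
    VENTRICLE,
    LabelMap,
    MRIVolume,
    QSTType,
)

__all__ = [
    "PhantomSpec",
    "GeometryError",
    "archetype_spec",
    "generate_phantom",
    "generate_cohort",
    "COHORT_COUNTS",
    "DEFAULT_MIXTURE",
    "DEFAULT_GRID_SHAPE",
    "DESK_GRID_SHAPE",
    "DESK_SPACING",
    "INTENSITY_MEANS",
]


class GeometryError(ValueError):
    """The requested geometry does not fit on the voxel grid."""


#: cohort composition by surgically verified type in the reference cohort
COHORT_COUNTS = {"Q": 29, "S": 22, "T": 82}
#: default archetype mixture = cohort prevalences (29, 22, 82 of 133)
DEFAULT_MIXTURE = tuple(c / sum(COHORT_COUNTS.values()) for c in COHORT_COUNTS.values())

#: default grid: 10 sagittal slices x 160 (AP) x 176 (SI) at (6.0, 0.45, 0.45) mm
DEFAULT_GRID_SHAPE = (10, 160, 176)
#: coarse grid for desk-scale network training: 64 x 64 in-plane covering the
#: same ~72 x 79 mm field of view
DESK_GRID_SHAPE = (10, 64, 64)
DESK_SPACING = (6.0, 1.125, 1.2375)

#: per-class mean intensities (arbitrary units; tumor enhances most on CE-T1)
INTENSITY_MEANS = {
    BACKGROUND: 0.05,
    TUMOR: 0.90,
    PITUITARY: 0.60,
    SPHENOID_SINUS: 0.15,
    BRAIN: 0.45,
    CISTERN: 0.25,
    VENTRICLE: 0.20,
}

# --- fixed anatomy in physical mm (field of view ~ 60 x 72 x 79 mm) ------
_SINUS_AP_MM = (24.0, 48.0)   # posterior, anterior face -> j_TS at 48 mm
_SINUS_SI_MM = (4.0, 26.0)    # floor, roof -> k_TS at 26 mm
_SINUS_LR_HALF_MM = 21.0
_PITUITARY_CENTER_MM = (0.0, 36.0, 16.0)   # LR offset from midline, AP, SI
_PITUITARY_RADII_RATIO = (1.3, 1.15, 0.8)  # LR, AP, SI shape ratios
_CISTERN_CENTER_MM = (0.0, 38.0, 30.0)
_CISTERN_RADII_MM = (16.0, 14.0, 4.0)
_BRAIN_CENTER_MM = (0.0, 34.0, 52.0)
_BRAIN_RADII_MM = (27.0, 33.0, 24.0)
_VENTRICLE_CENTER_MM = (0.0, 24.0, 60.0)
_VENTRICLE_RADII_MM = (6.5, 8.5, 4.5)

#: tumor cross-section half-extent at the narrow ends, as a fraction of the
#: widest level (a tent profile peaking at ``widest_level_fraction``)
_MIN_PROFILE_FRAC = 0.35


@dataclass
class PhantomSpec:
    """Generative parameters for one synthetic case.

    Extents are in cm, offsets in mm relative to the tuberculum landmark
    (axis order LR, AP, SI).  ``intrasellar_fraction`` is the fraction of
    tumor volume placed below the tuberculum plane; ``anterior_fraction``
    the fraction anterior to it.  ``widest_level_fraction`` places the
    tumor's widest AP cross-section along its SI span (0 = inferior).
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    archetype: str = "T"
    pituitary_volume_cm3: float = 0.45
    tumor_ap_cm: float = 3.0
    tumor_si_cm: float = 4.0
    tumor_lr_cm: float = 3.0
    tumor_center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ventricle_dilation_factor: float = 1.0
    widest_level_fraction: float = 0.5
    intrasellar_fraction: float = 0.1
    anterior_fraction: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.archetype = str(QSTType(self.archetype))
        if min(self.tumor_ap_cm, self.tumor_si_cm, self.tumor_lr_cm) <= 0:
            raise ValueError("tumor extents must be positive")
        if self.pituitary_volume_cm3 < 0:
            raise ValueError("pituitary volume must be >= 0")
        if self.ventricle_dilation_factor < 1:
            raise ValueError("ventricle_dilation_factor must be >= 1")
        for name in ("widest_level_fraction", "intrasellar_fraction", "anterior_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def archetype_spec(qst_type, seed: int = 0, *, grid_shape=DEFAULT_GRID_SHAPE,
                   spacing=DEFAULT_SPACING) -> PhantomSpec:
    """Canonical spec for one QST growth archetype.

    Each archetype's parameters sit firmly on its type's side of every
    clinical-scale cutoff, so the rule-based classifier recovers the
    generating type by construction (up to voxelization noise).
    """
    t = str(QSTType(qst_type))
    common = dict(grid_shape=tuple(grid_shape), spacing=tuple(spacing), seed=seed)
    if t == "Q":
        return PhantomSpec(
            archetype="Q",
            pituitary_volume_cm3=0.01,       # compressed to near-invisibility
            tumor_ap_cm=3.0, tumor_si_cm=4.2, tumor_lr_cm=2.6,
            tumor_center_offset=(0.0, 0.0, 0.0),
            ventricle_dilation_factor=1.0,
            widest_level_fraction=0.6,
            intrasellar_fraction=0.28,       # large fossa component (>2.1 cm3)
            anterior_fraction=0.45,          # anterior position
            **common,
        )
    if t == "S":
        return PhantomSpec(
            archetype="S",
            pituitary_volume_cm3=0.49,
            tumor_ap_cm=4.2, tumor_si_cm=3.0, tumor_lr_cm=3.0,  # aspect 1.4 > 1.1
            tumor_center_offset=(0.0, 0.0, 0.0),
            ventricle_dilation_factor=1.0,   # no dilatation
            widest_level_fraction=0.25,      # positive pyramid: widest inferior
            intrasellar_fraction=0.05,
            anterior_fraction=0.35,          # > 0.8 cm3 anterior to tuberculum
            **common,
        )
    return PhantomSpec(
        archetype="T",
        pituitary_volume_cm3=0.45,
        tumor_ap_cm=3.0, tumor_si_cm=4.0, tumor_lr_cm=3.0,
        tumor_center_offset=(0.0, -20.0, 0.0),  # posterior to the brain centroid
        ventricle_dilation_factor=2.5,       # ventricular dilatation
        widest_level_fraction=0.75,          # inverted pyramid: widest superior
        intrasellar_fraction=0.03,           # small fossa component (<2.1 cm3)
        anterior_fraction=0.0,
        **common,
    )


# --------------------------------------------------------------------------
# geometry helpers

def _voxel_centers(n: int, d: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * d


def _ellipsoid_mask(xs, ys, zs, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    if min(rx, ry, rz) <= 0:
        return np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    u = ((xs - cx) / rx) ** 2
    v = ((ys - cy) / ry) ** 2
    w = ((zs - cz) / rz) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _tent_profile(t: np.ndarray, peak: float, floor: float = _MIN_PROFILE_FRAC) -> np.ndarray:
    """Piecewise-linear profile rising from ``floor`` to 1 at ``peak`` and back."""
    peak = float(np.clip(peak, 0.05, 0.95))
    up = floor + (1.0 - floor) * (t / peak)
    down = floor + (1.0 - floor) * ((1.0 - t) / (1.0 - peak))
    return np.where(t <= peak, up, down)


def _ellipse_segment_fraction(u: np.ndarray) -> np.ndarray:
    """Area fraction of an ellipse beyond the chord x/a = u (toward +x)."""
    u = np.clip(u, -1.0, 1.0)
    return (np.arccos(u) - u * np.sqrt(1.0 - u * u)) / math.pi


def _sinus_top_anterior_indices(spacing) -> tuple[int, int]:
    """(j_TS, k_TS) voxel indices of the sinus' anterior face and roof."""
    _, dy, dz = spacing
    j_ts = int(np.floor(_SINUS_AP_MM[1] / dy - 0.5))
    k_ts = int(np.floor(_SINUS_SI_MM[1] / dz - 0.5))
    return j_ts, k_ts


def _build_tumor(spec: PhantomSpec, xs, ys, zs) -> np.ndarray:
    dx, dy, dz = spec.spacing
    nx, ny, nz = spec.grid_shape
    ap_mm = spec.tumor_ap_cm * 10.0
    si_mm = spec.tumor_si_cm * 10.0
    lr_mm = spec.tumor_lr_cm * 10.0

    nlev = max(2, int(round(si_mm / dz)))
    if nlev > nz:
        raise GeometryError(
            f"tumor SI extent {si_mm:.0f} mm needs {nlev} levels, grid has {nz}"
        )
    t = np.arange(nlev) / (nlev - 1)
    prof = _tent_profile(t, spec.widest_level_fraction)
    prof = prof / prof.max()  # the widest discrete level realises the full extent
    a = 0.5 * ap_mm * prof            # AP half-extent per level (mm)
    l = 0.5 * lr_mm * prof            # LR half-extent per level (mm)
    area = a * l                      # proportional to per-level volume

    j_ts, k_ts = _sinus_top_anterior_indices(spec.spacing)

    # vertical placement: integer bottom level k0 so the volume fraction at
    # levels strictly below the tuberculum plane matches intrasellar_fraction
    total = area.sum()
    k0_init = int(round((_SINUS_SI_MM[1] + spec.tumor_center_offset[2]) / dz - nlev / 2))
    best_k0, best_err = None, None
    for k0 in range(0, nz - nlev + 1):
        n_below = max(0, min(nlev, k_ts - k0))
        frac = area[:n_below].sum() / total
        err = abs(frac - spec.intrasellar_fraction)
        key = (err, abs(k0 - k0_init))
        if best_err is None or key < best_err:
            best_err, best_k0 = key, k0
    k0 = best_k0
    if best_err[0] > 0.10:
        raise GeometryError(
            "cannot realise the requested intrasellar fraction on this grid "
            f"(best achievable error {best_err[0]:.2f})"
        )

    # AP placement: continuous center cy so the volume fraction anterior to
    # the tuberculum plane matches anterior_fraction (analytic chord areas)
    y_plane = (j_ts + 1) * dy         # anterior means index > j_TS
    a_max = a.max()
    lo, hi = a_max, ny * dy - a_max
    if lo >= hi:
        raise GeometryError("tumor AP extent does not fit on the grid")
    cy_init = _SINUS_AP_MM[1] + spec.tumor_center_offset[1]
    candidates = np.arange(lo, hi, 0.25 * dy)
    best_cy, best_key = None, None
    for cy in candidates:
        u = (y_plane - cy) / a
        frac = (area * _ellipse_segment_fraction(u)).sum() / total
        key = (abs(frac - spec.anterior_fraction), abs(cy - cy_init))
        if best_key is None or key < best_key:
            best_key, best_cy = key, cy
    cy = best_cy
    if best_key[0] > 0.10:
        raise GeometryError("cannot realise the requested anterior fraction on this grid")

    cx = 0.5 * nx * dx + spec.tumor_center_offset[0]
    if cx - 0.5 * lr_mm < 0 or cx + 0.5 * lr_mm > nx * dx:
        raise GeometryError("tumor LR extent does not fit on the grid")

    # voxelize the stacked-ellipse solid
    a_k = np.zeros(nz)
    l_k = np.zeros(nz)
    a_k[k0 : k0 + nlev] = a
    l_k[k0 : k0 + nlev] = l
    with np.errstate(divide="ignore", invalid="ignore"):
        u2 = ((xs[:, None, None] - cx) / l_k[None, None, :]) ** 2
        v2 = ((ys[None, :, None] - cy) / a_k[None, None, :]) ** 2
        mask = (u2 + v2) <= 1.0
    mask &= (l_k > 0)[None, None, :]
    return mask


def _pituitary_radii(volume_cm3: float) -> tuple[float, float, float]:
    if volume_cm3 <= 0:
        return (0.0, 0.0, 0.0)
    prod = volume_cm3 * 1000.0 * 3.0 / (4.0 * math.pi)  # rx*ry*rz in mm^3
    base = float(np.prod(_PITUITARY_RADII_RATIO))
    s = (prod / base) ** (1.0 / 3.0)
    return tuple(r * s for r in _PITUITARY_RADII_RATIO)


def generate_phantom(spec: PhantomSpec):
    """Generate one (MRIVolume, LabelMap, QSTType) triple from a spec.

    Deterministic given ``spec.seed``.  Tissues are composed in increasing
    priority (brain < sinus < ventricle < cistern < pituitary < tumor) so
    that overlapping shapes resolve deterministically with the tumor on top;
    the suprasellar cistern and, for Q archetypes, the pituitary may be
    absent after compression by the tumor.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing
    xs = _voxel_centers(nx, dx)
    ys = _voxel_centers(ny, dy)
    zs = _voxel_centers(nz, dz)
    fov = (nx * dx, ny * dy, nz * dz)
    if fov[1] < 70.0 or fov[2] < 78.0 or fov[0] < 54.0:
        raise GeometryError(
            f"grid field of view {fov} mm too small for the sellar anatomy "
            "(needs ~ (54, 70, 78) mm)"
        )
    mid = 0.5 * fov[0]

    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    brain = _ellipsoid_mask(
        xs, ys, zs, (mid + _BRAIN_CENTER_MM[0], _BRAIN_CENTER_MM[1], _BRAIN_CENTER_MM[2]),
        _BRAIN_RADII_MM,
    )
    labels[brain] = BRAIN

    sinus = (
        (np.abs(xs - mid) <= _SINUS_LR_HALF_MM)[:, None, None]
        & ((ys >= _SINUS_AP_MM[0]) & (ys <= _SINUS_AP_MM[1]))[None, :, None]
        & ((zs >= _SINUS_SI_MM[0]) & (zs <= _SINUS_SI_MM[1]))[None, None, :]
    )
    labels[sinus] = SPHENOID_SINUS

    vent_radii = tuple(r * spec.ventricle_dilation_factor for r in _VENTRICLE_RADII_MM)
    ventricle = _ellipsoid_mask(
        xs, ys, zs,
        (mid + _VENTRICLE_CENTER_MM[0], _VENTRICLE_CENTER_MM[1], _VENTRICLE_CENTER_MM[2]),
        vent_radii,
    )
    labels[ventricle & brain] = VENTRICLE   # ventricles live inside the brain

    cistern = _ellipsoid_mask(
        xs, ys, zs,
        (mid + _CISTERN_CENTER_MM[0], _CISTERN_CENTER_MM[1], _CISTERN_CENTER_MM[2]),
        _CISTERN_RADII_MM,
    )
    labels[cistern] = CISTERN

    pit = _ellipsoid_mask(
        xs, ys, zs,
        (mid + _PITUITARY_CENTER_MM[0], _PITUITARY_CENTER_MM[1], _PITUITARY_CENTER_MM[2]),
        _pituitary_radii(spec.pituitary_volume_cm3),
    )
    labels[pit] = PITUITARY

    tumor = _build_tumor(spec, xs, ys, zs)
    labels[tumor] = TUMOR

    label_map = LabelMap(labels, spacing=spec.spacing)

    rng = np.random.default_rng(spec.seed)
    intensity = np.zeros(spec.grid_shape, dtype=np.float32)
    for c, mu in INTENSITY_MEANS.items():
        intensity[labels == c] = mu
    intensity += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape).astype(np.float32)
    mri = MRIVolume(intensity, spacing=spec.spacing)

    return mri, label_map, QSTType(spec.archetype)


# --------------------------------------------------------------------------
# cohorts

def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Bounded parameter jitter keeping a sample on its type's side of every cutoff."""
    def u(lo, hi):
        return float(rng.uniform(lo, hi))

    return replace(
        spec,
        tumor_ap_cm=spec.tumor_ap_cm + u(-0.2, 0.2),
        tumor_si_cm=spec.tumor_si_cm + u(-0.2, 0.2),
        tumor_lr_cm=spec.tumor_lr_cm + u(-0.2, 0.2),
        pituitary_volume_cm3=spec.pituitary_volume_cm3 * u(0.7, 1.3),
        widest_level_fraction=float(
            np.clip(spec.widest_level_fraction + u(-0.08, 0.08), 0.05, 0.95)
        ),
        intrasellar_fraction=float(
            np.clip(spec.intrasellar_fraction + u(-0.02, 0.02), 0.0, 1.0)
        ),
        anterior_fraction=float(
            np.clip(spec.anterior_fraction + u(-0.04, 0.04), 0.0, 1.0)
        ),
        ventricle_dilation_factor=(
            spec.ventricle_dilation_factor
            if spec.ventricle_dilation_factor == 1.0
            else max(1.0, spec.ventricle_dilation_factor + u(-0.3, 0.3))
        ),
        tumor_center_offset=tuple(
            o + u(-2.0, 2.0) for o in spec.tumor_center_offset
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int,
    mixture=DEFAULT_MIXTURE,
    seed: int = 0,
    *,
    grid_shape=DEFAULT_GRID_SHAPE,
    spacing=DEFAULT_SPACING,
    jitter: bool = True,
    return_specs: bool = False,
):
    """Generate a cohort of ``n`` phantoms with archetypes drawn from ``mixture``.

    ``mixture`` gives the (Q, S, T) proportions; the default mirrors the
    reference cohort prevalences (21.8%, 16.5%, 61.7%).  Reproducible given
    ``seed``.  Returns a list of (MRIVolume, LabelMap, QSTType) triples, or
    with ``return_specs`` a list of (mri, labels, type, spec).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (3,) or (mixture < 0).any() or not math.isclose(
        mixture.sum(), 1.0, abs_tol=1e-8
    ):
        raise ValueError("mixture must be 3 nonnegative proportions summing to 1")

    rng = np.random.default_rng(seed)
    types = rng.choice(np.array(["Q", "S", "T"]), size=n, p=mixture)
    out = []
    for t in types:
        spec = archetype_spec(t, seed=0, grid_shape=grid_shape, spacing=spacing)
        if jitter:
            spec = _jitter_spec(spec, rng)
        else:
            spec = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        mri, labels, qst = generate_phantom(spec)
        out.append((mri, labels, qst, spec) if return_specs else (mri, labels, qst))
    return out
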