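"""Rule-based clinical scale for fast QST classification.

Nine imaging findings are binarized at fixed cutoffs and award points to
one or more of the three types; each type's points sum to a score in
0-16 and the diagnosis is the score argmax with tie priority T > S > Q:

====================================  ==========  ==========  ==========
Finding                                Q           S           T
====================================  ==========  ==========  ==========
Pituitary                              not seen 8  —           seen 6
Tumor AP diameter < 3.5 cm             3           —           —
Tumor SI diameter > 3.5 cm             2           —           —
Ventricle dilatation                   —           no: 5       yes: 3
Position relative to brain             anterior 3  anterior 2  posterior 1
Widest transverse level                —           inferior 2  superior 2
Tumor volume in pituitary fossa        —           —           < 2.1 cm³: 4
Tumor volume anterior to tuberculum    —           > 0.8 cm³: 3  —
Aspect ratio > 1.1                     —           4           —
====================================  ==========  ==========  ==========

Inequalities are strict as printed; boundary cases score nothing.  The
qualitative items ("clearly seen", "dilatation", anterior/posterior) are
given operational defaults here (configurable): the pituitary counts as
seen at >= 0.1 cm³ — reference cohorts separate Q glands (~0.01 cm³) from
S/T glands (~0.45-0.49 cm³) by an order of magnitude — the ventricles as
dilated at >= 2% of brain volume, and the brain-relative AP offset gets a
±0.05 neutral dead-zone so a centred tumor scores neither anterior nor
posterior.  A missing (indeterminate) item contributes 0 to every type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import ClinicalFeatures, extract_features
from .label_schema import LabelMap, QSTType

__all__ = [
    "ScaleThresholds",
    "ScaleItems",
    "ScaleScores",
    "POINTS",
    "MAX_SCORE",
    "binarize",
    "score",
    "classify",
    "diagnose",
    "find_cutoff",
    "QSTScaleClassifier",
]

#: point awards per type; keys name the state of the item that scores
POINTS: dict[str, dict[str, int]] = {
    "Q": {
        "pituitary_not_seen": 8,
        "ap_lt_cutoff": 3,
        "si_gt_cutoff": 2,
        "position_anterior": 3,
    },
    "S": {
        "no_dilatation": 5,
        "position_anterior": 2,
        "widest_inferior": 2,
        "anterior_volume_gt_cutoff": 3,
        "aspect_gt_cutoff": 4,
    },
    "T": {
        "pituitary_seen": 6,
        "dilatation": 3,
        "position_posterior": 1,
        "widest_superior": 2,
        "fossa_lt_cutoff": 4,
    },
}

MAX_SCORE = 16
assert all(sum(v.values()) == MAX_SCORE for v in POINTS.values())


@dataclass(frozen=True)
class ScaleThresholds:
    """Cutoffs for the nine scale items.

    The five printed cutoffs (AP, SI, fossa, anterior volume, aspect) are
    fixed by the scale; the remaining three operationalize qualitative
    findings and are calibration choices.
    """

    ap_cm: float = 3.5
    si_cm: float = 3.5
    fossa_cm3: float = 2.1
    anterior_cm3: float = 0.8
    aspect: float = 1.1
    pituitary_seen_cm3: float = 0.1
    ventricle_brain_ratio: float = 0.02
    position_deadzone: float = 0.05
    widest_split: float = 0.5


@dataclass(frozen=True)
class ScaleItems:
    """The nine binarized findings; ``None`` marks an indeterminate item."""

    pituitary_clearly_seen: Optional[bool]
    tumor_ap_lt_cutoff: Optional[bool]
    tumor_si_gt_cutoff: Optional[bool]
    ventricle_dilated: Optional[bool]
    tumor_position: Optional[str]        # 'anterior' | 'posterior' | 'neutral'
    widest_location: Optional[str]       # 'inferior' | 'superior' | 'neutral'
    fossa_volume_lt_cutoff: Optional[bool]
    anterior_volume_gt_cutoff: Optional[bool]
    aspect_gt_cutoff: Optional[bool]

    def __post_init__(self):
        if self.tumor_position not in (None, "anterior", "posterior", "neutral"):
            raise ValueError(f"bad tumor_position {self.tumor_position!r}")
        if self.widest_location not in (None, "inferior", "superior", "neutral"):
            raise ValueError(f"bad widest_location {self.widest_location!r}")


@dataclass(frozen=True)
class ScaleScores:
    """Per-type integer scores, each in 0-16."""

    q_score: int
    s_score: int
    t_score: int

    def __post_init__(self):
        for s in (self.q_score, self.s_score, self.t_score):
            if not 0 <= s <= MAX_SCORE:
                raise ValueError(f"score {s} outside 0-{MAX_SCORE}")

    def as_dict(self) -> dict[str, int]:
        return {"Q": self.q_score, "S": self.s_score, "T": self.t_score}


def binarize(features: ClinicalFeatures, thresholds: ScaleThresholds | None = None) -> ScaleItems:
    """Binarize a 34-feature vector into the nine scale items.

    A missing pituitary volume means the gland was not delineated at all
    and maps to "not clearly seen"; other missing inputs make the dependent
    item indeterminate (``None``).
    """
    th = thresholds or ScaleThresholds()

    def get(name):
        return None if features.is_missing(name) else features[name]

    pit_vol = get("pituitary_volume_cm3")
    pituitary_seen = False if pit_vol is None else pit_vol >= th.pituitary_seen_cm3

    ap = get("tumor_extent_ap_cm")
    si = get("tumor_extent_si_cm")

    vent = get("lateral_ventricle_volume_cm3")
    brain_vol = get("brain_volume_cm3")
    if brain_vol is None or brain_vol == 0:
        dilated = None
    else:
        dilated = (0.0 if vent is None else vent) / brain_vol >= th.ventricle_brain_ratio

    ap_off = get("tumor_vs_brain_ap")
    if ap_off is None:
        position = None
    elif ap_off >= th.position_deadzone:
        position = "anterior"
    elif ap_off <= -th.position_deadzone:
        position = "posterior"
    else:
        position = "neutral"

    wl = get("widest_level_fraction")
    if wl is None:
        widest = None
    else:
        widest = "inferior" if wl < th.widest_split else "superior"

    fossa = get("fossa_volume_cm3")
    anterior_vol = get("anterior_volume_cm3")
    aspect = get("aspect_ratio")

    return ScaleItems(
        pituitary_clearly_seen=pituitary_seen,
        tumor_ap_lt_cutoff=None if ap is None else ap < th.ap_cm,
        tumor_si_gt_cutoff=None if si is None else si > th.si_cm,
        ventricle_dilated=dilated,
        tumor_position=position,
        widest_location=widest,
        fossa_volume_lt_cutoff=None if fossa is None else fossa < th.fossa_cm3,
        anterior_volume_gt_cutoff=None if anterior_vol is None else anterior_vol > th.anterior_cm3,
        aspect_gt_cutoff=None if aspect is None else aspect > th.aspect,
    )


def _item_states(items: ScaleItems) -> set[str]:
    states = set()
    if items.pituitary_clearly_seen is True:
        states.add("pituitary_seen")
    elif items.pituitary_clearly_seen is False:
        states.add("pituitary_not_seen")
    if items.tumor_ap_lt_cutoff:
        states.add("ap_lt_cutoff")
    if items.tumor_si_gt_cutoff:
        states.add("si_gt_cutoff")
    if items.ventricle_dilated is True:
        states.add("dilatation")
    elif items.ventricle_dilated is False:
        states.add("no_dilatation")
    if items.tumor_position in ("anterior", "posterior"):
        states.add(f"position_{items.tumor_position}")
    if items.widest_location in ("inferior", "superior"):
        states.add(f"widest_{items.widest_location}")
    if items.fossa_volume_lt_cutoff:
        states.add("fossa_lt_cutoff")
    if items.anterior_volume_gt_cutoff:
        states.add("anterior_volume_gt_cutoff")
    if items.aspect_gt_cutoff:
        states.add("aspect_gt_cutoff")
    return states


def score(items: ScaleItems) -> ScaleScores:
    """Sum each type's points over the item states that are present."""
    states = _item_states(items)
    totals = {
        t: sum(pts for state, pts in table.items() if state in states)
        for t, table in POINTS.items()
    }
    return ScaleScores(q_score=totals["Q"], s_score=totals["S"], t_score=totals["T"])


def classify(scores: ScaleScores) -> QSTType:
    """Score argmax; equal scores resolve by the diagnostic priority T > S > Q."""
    d = scores.as_dict()
    best = max(d.values())
    for t in QSTType.TIE_PRIORITY:
        if d[t] == best:
            return QSTType(t)
    raise AssertionError("unreachable")


def diagnose(label_map: LabelMap, thresholds: ScaleThresholds | None = None):
    """Full chain label map -> features -> items -> scores -> diagnosis."""
    feats = extract_features(label_map)
    items = binarize(feats, thresholds)
    sc = score(items)
    return classify(sc), sc, items


def find_cutoff(values, binary_outcome) -> tuple[float, str, float]:
    """Single-threshold cutoff maximizing AUC (equivalently the Youden index).

    Scans the midpoints between sorted distinct values in both directions
    ('gt': positive when value > threshold; 'lt': positive when below) and
    returns ``(threshold, direction, auc)``.  Ties resolve to the lower
    threshold, preferring 'gt'.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(binary_outcome, dtype=bool)
    if values.shape != outcome.shape or values.ndim != 1:
        raise ValueError("values and binary_outcome must be equal-length 1D")
    n_pos, n_neg = int(outcome.sum()), int((~outcome).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("need at least two distinct values")
    midpoints = 0.5 * (distinct[:-1] + distinct[1:])
    best = None
    for thr in midpoints:
        for direction in ("gt", "lt"):
            pred = values > thr if direction == "gt" else values < thr
            sens = (pred & outcome).sum() / n_pos
            spec = (~pred & ~outcome).sum() / n_neg
            auc = 0.5 * (sens + spec)
            if best is None or auc > best[2] + 1e-12:
                best = (float(thr), direction, float(auc))
    return best


class QSTScaleClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around the clinical scale.

    A rule-based classifier: ``fit`` only records the classes (the point
    table and cutoffs are fixed knowledge, optionally overridden via
    ``thresholds``).  ``predict`` accepts a sequence of :class:`LabelMap`
    or :class:`ClinicalFeatures`; ``decision_scores`` exposes the raw
    per-type 0-16 scores.
    """

    def __init__(self, thresholds: ScaleThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        self.classes_ = np.asarray(["Q", "S", "T"])
        self.thresholds_ = self.thresholds or ScaleThresholds()
        return self

    def _features(self, x) -> ClinicalFeatures:
        if isinstance(x, ClinicalFeatures):
            return x
        if isinstance(x, LabelMap):
            return extract_features(x)
        arr = np.asarray(x, dtype=float)
        return ClinicalFeatures(values=np.nan_to_num(arr), missing=np.isnan(arr))

    def decision_scores(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit()
        out = []
        for x in X:
            sc = score(binarize(self._features(x), self.thresholds_))
            out.append([sc.q_score, sc.s_score, sc.t_score])
        return np.asarray(out)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit()
        preds = []
        for x in X:
            sc = score(binarize(self._features(x), self.thresholds_))
            preds.append(str(classify(sc)))
        return np.asarray(preds)
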