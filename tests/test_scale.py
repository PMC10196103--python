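import itertools

import numpy as np
import pytest

from cranioqst.features import ClinicalFeatures, N_FEATURES, FEATURE_NAMES, extract_features
from cranioqst.scale import (
    MAX_SCORE,
    POINTS,
    QSTScaleClassifier,
    ScaleItems,
    ScaleScores,
    ScaleThresholds,
    binarize,
    classify,
    find_cutoff,
    score,
)


def _features(**overrides):
    values = np.zeros(N_FEATURES)
    missing = np.zeros(N_FEATURES, dtype=bool)
    names = list(FEATURE_NAMES)
    defaults = {"brain_volume_cm3": 100.0, "tumor_extent_si_cm": 3.0,
                "tumor_extent_ap_cm": 3.0, "aspect_ratio": 1.0}
    for k, v in {**defaults, **overrides}.items():
        if v is None:
            missing[names.index(k)] = True
        else:
            values[names.index(k)] = v
    return ClinicalFeatures(values=values, missing=missing)


def _items(**overrides):
    base = dict(
        pituitary_clearly_seen=True, tumor_ap_lt_cutoff=False,
        tumor_si_gt_cutoff=False, ventricle_dilated=True,
        tumor_position="neutral", widest_location="neutral",
        fossa_volume_lt_cutoff=False, anterior_volume_gt_cutoff=False,
        aspect_gt_cutoff=False,
    )
    base.update(overrides)
    return ScaleItems(**base)


class TestBinarize:
    def test_invisible_pituitary_not_seen(self):
        items = binarize(_features(pituitary_volume_cm3=0.01))
        assert items.pituitary_clearly_seen is False

    def test_missing_pituitary_means_not_seen(self):
        items = binarize(_features(pituitary_volume_cm3=None))
        assert items.pituitary_clearly_seen is False

    def test_small_ap_diameter_below_cutoff(self):
        assert binarize(_features(tumor_extent_ap_cm=3.0)).tumor_ap_lt_cutoff is True
        assert binarize(_features(tumor_extent_ap_cm=3.6)).tumor_ap_lt_cutoff is False

    def test_aspect_exactly_at_cutoff_scores_nothing(self):
        # strict inequality: 1.1 is not > 1.1
        assert binarize(_features(aspect_ratio=1.1)).aspect_gt_cutoff is False

    def test_position_deadzone(self):
        assert binarize(_features(tumor_vs_brain_ap=0.2)).tumor_position == "anterior"
        assert binarize(_features(tumor_vs_brain_ap=-0.2)).tumor_position == "posterior"
        assert binarize(_features(tumor_vs_brain_ap=0.01)).tumor_position == "neutral"

    def test_ventricle_dilation_ratio(self):
        f = _features(lateral_ventricle_volume_cm3=5.0, brain_volume_cm3=100.0)
        assert binarize(f).ventricle_dilated is True
        f = _features(lateral_ventricle_volume_cm3=1.0, brain_volume_cm3=100.0)
        assert binarize(f).ventricle_dilated is False


class TestScore:
    def test_full_q_pattern(self):
        items = ScaleItems(
            pituitary_clearly_seen=False, tumor_ap_lt_cutoff=True,
            tumor_si_gt_cutoff=True, ventricle_dilated=False,
            tumor_position="anterior", widest_location="inferior",
            fossa_volume_lt_cutoff=False, anterior_volume_gt_cutoff=True,
            aspect_gt_cutoff=False,
        )
        # Q: 8+3+2+3; S: 5+2+2+3; T: 0
        assert score(items) == ScaleScores(16, 12, 0)

    def test_full_t_pattern(self):
        items = ScaleItems(
            pituitary_clearly_seen=True, tumor_ap_lt_cutoff=False,
            tumor_si_gt_cutoff=True, ventricle_dilated=True,
            tumor_position="posterior", widest_location="superior",
            fossa_volume_lt_cutoff=True, anterior_volume_gt_cutoff=False,
            aspect_gt_cutoff=False,
        )
        # Q: SI>cutoff only (2); S: 0; T: 6+3+1+2+4
        assert score(items) == ScaleScores(2, 0, 16)

    def test_all_missing_scores_zero(self):
        items = ScaleItems(*([None] * 9))
        assert score(items) == ScaleScores(0, 0, 0)

    def test_q_item_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            items = _items(
                pituitary_clearly_seen=bool(rng.integers(2)),
                tumor_ap_lt_cutoff=bool(rng.integers(2)),
                tumor_si_gt_cutoff=bool(rng.integers(2)),
                tumor_position=str(rng.choice(["anterior", "posterior", "neutral"])),
            )
            base = score(items)
            import dataclasses
            better = dataclasses.replace(items, tumor_ap_lt_cutoff=True)
            after = score(better)
            assert after.q_score >= base.q_score
            assert after.s_score == base.s_score and after.t_score == base.t_score


class TestClassify:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            (ScaleScores(16, 12, 0), "Q"),
            (ScaleScores(10, 10, 10), "T"),   # tie priority T first
            (ScaleScores(0, 7, 7), "T"),
            (ScaleScores(7, 7, 0), "S"),
            (ScaleScores(1, 0, 0), "Q"),
        ],
    )
    def test_argmax_with_tie_priority(self, scores, expected):
        assert classify(scores) == expected


class TestExhaustiveScaleEnumeration:
    def test_max_attainable_score_is_16_per_type(self):
        """Enumerate every item combination; per-type maxima are exactly 16."""
        best = {"Q": 0, "S": 0, "T": 0}
        for combo in itertools.product(
            [True, False], [True, False], [True, False], [True, False],
            ["anterior", "posterior", "neutral"],
            ["inferior", "superior", "neutral"],
            [True, False], [True, False], [True, False],
        ):
            s = score(ScaleItems(*combo))
            d = s.as_dict()
            for t in best:
                best[t] = max(best[t], d[t])
                assert 0 <= d[t] <= MAX_SCORE
        assert best == {"Q": 16, "S": 16, "T": 16}

    def test_point_table_sums_to_16(self):
        for table in POINTS.values():
            assert sum(table.values()) == MAX_SCORE


class TestFindCutoff:
    def test_perfect_separation(self):
        thr, direction, auc = find_cutoff([1, 2, 8, 9], [False, False, True, True])
        assert 2 < thr < 8 and direction == "gt" and auc == 1.0

    def test_anti_separated_flips_direction(self):
        thr, direction, auc = find_cutoff([1, 2, 8, 9], [True, True, False, False])
        assert direction == "lt" and auc == 1.0

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=50)
        outcome = rng.random(50) < 0.5
        thr, direction, auc = find_cutoff(values, outcome)
        # oracle: brute force over all midpoints and directions
        best = 0.0
        distinct = np.unique(values)
        for t in 0.5 * (distinct[:-1] + distinct[1:]):
            for pred in (values > t, values < t):
                sens = (pred & outcome).sum() / outcome.sum()
                spec = (~pred & ~outcome).sum() / (~outcome).sum()
                best = max(best, 0.5 * (sens + spec))
        assert auc == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            find_cutoff([1, 2, 3], [True, True, True])


class TestScaleClassifier:
    def test_determinism_identical_features_identical_diagnosis(self, archetype_phantoms):
        clf = QSTScaleClassifier().fit()
        maps = [archetype_phantoms[t][1] for t in "QST"]
        p1, p2 = clf.predict(maps), clf.predict(maps)
        assert np.array_equal(p1, p2)

    def test_recovers_archetypes(self, archetype_phantoms):
        clf = QSTScaleClassifier().fit()
        maps = [archetype_phantoms[t][1] for t in "QST"]
        assert list(clf.predict(maps)) == ["Q", "S", "T"]

    def test_decision_scores_in_range(self, archetype_phantoms):
        clf = QSTScaleClassifier().fit()
        scores = clf.decision_scores([archetype_phantoms["S"][1]])
        assert scores.shape == (1, 3) and (scores >= 0).all() and (scores <= 16).all()
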