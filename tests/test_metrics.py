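import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cranioqst.label_schema import LabelMap
from cranioqst.metrics import (
    classification_report,
    dice,
    make_cv_folds,
    multiclass_dice,
)


def _lm(arr):
    return LabelMap(np.asarray(arr, dtype=np.int16), spacing=(1, 1, 1))


class TestDice:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (np.ones((4, 4)), np.ones((4, 4)), 1.0),          # identical
            (np.zeros((4, 4)), np.zeros((4, 4)), 1.0),        # both empty
            ([1, 1, 1, 1, 0, 0], [0, 0, 1, 1, 1, 1], 0.5),    # |A|=|B|=4, overlap 2
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),                # disjoint
        ],
    )
    def test_known_values(self, a, b, expected):
        assert dice(np.asarray(a), np.asarray(b)) == expected

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.ones((2, 2)), np.ones((3, 3)))

    @settings(deadline=None, max_examples=50)
    @given(
        a=hnp.arrays(bool, (5, 6)),
        b=hnp.arrays(bool, (5, 6)),
    )
    def test_symmetry_and_range(self, a, b):
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestMulticlassDice:
    def test_perfect_prediction(self, archetype_phantoms):
        _, lm, _, _ = archetype_phantoms["S"]
        rep = multiclass_dice(lm, lm)
        assert all(v == 1.0 for v in rep.per_class.values())
        assert rep.mean == 1.0

    def test_erased_tumor_scores_zero(self, archetype_phantoms):
        _, lm, _, _ = archetype_phantoms["S"]
        pred = LabelMap(np.where(lm.voxels == 1, 0, lm.voxels), spacing=lm.spacing)
        rep = multiclass_dice(pred, lm)
        assert rep.per_class[1] == 0.0

    def test_matches_voxel_count_oracle_under_corruption(self, archetype_phantoms):
        _, ref, _, _ = archetype_phantoms["T"]
        rng = np.random.default_rng(0)
        vox = ref.voxels.copy()
        corrupt = rng.random(vox.shape) < 0.1
        vox[corrupt] = rng.integers(0, 7, size=int(corrupt.sum()))
        pred = LabelMap(vox, spacing=ref.spacing)
        rep = multiclass_dice(pred, ref)
        for c in range(1, 7):
            a, b = pred.voxels == c, ref.voxels == c
            inter = int((a & b).sum())
            denom = int(a.sum()) + int(b.sum())
            oracle = 2 * inter / denom if denom else 1.0
            assert rep.per_class[c] == pytest.approx(oracle)
        assert rep.mean == pytest.approx(np.mean(list(rep.per_class.values())))


class TestClassificationReport:
    def test_perfect_prediction(self):
        rep = classification_report(list("QSTQST"), list("QSTQST"))
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_hand_computed_confusion(self):
        rep = classification_report(["Q", "Q", "S", "T"], ["Q", "S", "S", "T"])
        assert rep.sensitivity["Q"] == 0.5
        assert rep.specificity["S"] == pytest.approx(2 / 3)
        assert rep.overall_accuracy == 0.75

    def test_youden_is_definitional(self):
        rng = np.random.default_rng(4)
        y = rng.choice(list("QST"), size=30)
        p = rng.choice(list("QST"), size=30)
        rep = classification_report(y, p)
        for t in "QST":
            assert rep.youden[t] == pytest.approx(
                rep.sensitivity[t] + rep.specificity[t] - 1.0
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_report([], [])


class TestCVFolds:
    def test_133_in_5_fold_sizes(self):
        folds = make_cv_folds(133, 5, seed=0)
        assert sorted(len(f) for f in folds) == [26, 26, 27, 27, 27]

    def test_partition_and_reproducibility(self):
        folds = make_cv_folds(50, 5, seed=7)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(50))
        again = make_cv_folds(50, 5, seed=7)
        for a, b in zip(folds, again):
            assert np.array_equal(a, b)

    def test_stratified_preserves_proportions(self):
        labels = ["Q"] * 10 + ["S"] * 15 + ["T"] * 25
        folds = make_cv_folds(50, 5, labels=labels, seed=1)
        labels = np.asarray(labels)
        for f in folds:
            counts = {t: (labels[f] == t).sum() for t in "QST"}
            assert counts == {"Q": 2, "S": 3, "T": 5}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_cv_folds(3, 5)
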