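import numpy as np
import pytest

from cranioqst import nn
from cranioqst.label_schema import MRIVolume
from cranioqst.metrics import dice
from cranioqst.segmentation import (
    NetworkConfig,
    SwapLayer,
    SwapUNetSegmenter,
    build_network,
    feature_swap,
    slices_from_cohort,
)


class TestConfig:
    def test_invalid_swap_pair_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=3, swap_pairs=((0, 5),))

    def test_depth_minimum(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=1)

    def test_supervision_weights_normalized_and_halving(self):
        w = NetworkConfig(depth=4, supervision_decay=0.5).supervision_weights
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(2 * w[1]) and w[1] == pytest.approx(2 * w[2])


class TestBuildNetwork:
    def test_output_is_seven_channels_at_input_resolution(self):
        net = build_network(NetworkConfig(depth=3, base_width=4, seed=0))
        x = np.random.default_rng(0).normal(size=(2, 1, 32, 32))
        logits = net.forward(x)
        assert logits[0].shape == (2, 7, 32, 32)
        assert logits[1].shape == (2, 7, 16, 16)   # deep-supervision head

    def test_same_seed_identical_parameters(self):
        cfg = NetworkConfig(depth=3, base_width=4, seed=7)
        a, b = build_network(cfg), build_network(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestFeatureSwap:
    def _pyramid(self, rng, channels=(4, 8), size=16):
        return [
            rng.normal(size=(2, c, size // 2**i, size // 2**i))
            for i, c in enumerate(channels)
        ]

    def test_empty_spec_is_identity(self):
        rng = np.random.default_rng(0)
        pyr = self._pyramid(rng)
        layer = SwapLayer([4, 8], (), rng)
        out = feature_swap(pyr, layer)
        for a, b in zip(out, pyr):
            assert np.array_equal(a, b)
        assert layer.params() == []

    def test_shapes_preserved_for_any_spec(self):
        rng = np.random.default_rng(1)
        pyr = self._pyramid(rng, channels=(4, 8, 16), size=16)
        layer = SwapLayer([4, 8, 16], ((0, 1), (1, 2), (0, 2)), rng)
        out = feature_swap(pyr, layer)
        for a, b in zip(out, pyr):
            assert a.shape == b.shape

    def test_zero_pyramid_maps_to_zero(self):
        rng = np.random.default_rng(2)
        pyr = [np.zeros((1, 4, 8, 8)), np.zeros((1, 8, 4, 4))]
        layer = SwapLayer([4, 8], ((0, 1),), rng)
        out = feature_swap(pyr, layer)
        for a in out:
            assert not a.any()

    def test_identity_swap_network_equals_plain_backbone_bitwise(self):
        cfg = NetworkConfig(depth=3, base_width=4, swap_pairs=(), seed=3)
        net = build_network(cfg)
        x = np.random.default_rng(3).normal(size=(1, 1, 16, 16))
        out_swap = net.forward(x)

        class _Identity:
            def forward(self, pyr):
                return pyr

        plain = build_network(cfg)
        plain.swap = _Identity()
        out_plain = plain.forward(x)
        for a, b in zip(out_swap, out_plain):
            assert np.array_equal(a, b)


class TestTraining:
    def test_loss_decreases_across_seeds(self, desk_cohort):
        X, y = slices_from_cohort(desk_cohort[:1])
        for seed in (0, 1, 2):
            est = SwapUNetSegmenter(epochs=8, base_width=4, random_state=seed).fit(X, y)
            assert est.loss_history_[-1] < est.loss_history_[0]

    def test_single_slice_overfit_reaches_high_tumor_dice(self, desk_cohort):
        mri, lm, _ = desk_cohort[0]
        i = int(np.argmax((lm.voxels == 1).sum(axis=(1, 2))))
        X, y = mri.voxels[i : i + 1], lm.voxels[i : i + 1]
        est = SwapUNetSegmenter(epochs=60, random_state=0).fit(X, y)
        pred = est.predict(X)
        assert dice(pred[0] == 1, y[0] == 1) > 0.95

    def test_training_reproducible_given_seed(self, desk_cohort):
        X, y = slices_from_cohort(desk_cohort[:1])
        a = SwapUNetSegmenter(epochs=3, base_width=4, random_state=5).fit(X, y)
        b = SwapUNetSegmenter(epochs=3, base_width=4, random_state=5).fit(X, y)
        assert np.array_equal(a.loss_history_, b.loss_history_)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SwapUNetSegmenter().fit(np.zeros((2, 8, 8)), np.zeros((2, 8, 10), dtype=int))


class TestPrediction:
    def test_labels_within_schema_and_shape_preserved(self, desk_cohort):
        X, y = slices_from_cohort(desk_cohort[:1])
        est = SwapUNetSegmenter(epochs=2, base_width=4, random_state=0).fit(X, y)
        mri = desk_cohort[1][0]
        out = est.predict_volume(mri)
        assert out.shape == mri.shape
        assert set(np.unique(out.voxels)) <= set(range(7))
        assert out.spacing == pytest.approx(mri.spacing)

    def test_probability_simplex_after_normalization(self, desk_cohort):
        X, y = slices_from_cohort(desk_cohort[:1])
        est = SwapUNetSegmenter(epochs=1, base_width=4, random_state=0).fit(X, y)
        logits = est.network_.forward(X[:2, None].astype(float))
        p = nn.softmax(logits[0])
        assert np.allclose(p.sum(axis=1), 1.0)
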