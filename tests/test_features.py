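import numpy as np
import pytest

from cranioqst.features import (
    FEATURE_NAMES,
    N_FEATURES,
    ClinicalFeatureExtractor,
    LandmarkUnavailableError,
    aspect_ratio,
    extract_features,
    locate_tuberculum,
    relative_position,
    tissue_extents,
    tissue_volume,
    tumor_anterior_volume,
    tumor_fossa_volume,
    widest_level_fraction,
)
from cranioqst.label_schema import DEFAULT_SPACING, LabelMap
from cranioqst.scale import ScaleThresholds


def _lm(arr, spacing=DEFAULT_SPACING):
    return LabelMap(np.asarray(arr, dtype=np.int16), spacing=spacing)


class TestVolumesAndExtents:
    def test_volume_arithmetic(self):
        arr = np.zeros((10, 10, 10))
        arr.flat[:1000] = 1
        # 1000 voxels x (6.0 * 0.45 * 0.45) mm3 = 1.215 cm3
        assert tissue_volume(_lm(arr), 1) == pytest.approx(1.215)

    def test_absent_tissue_zero(self):
        lm = _lm(np.zeros((4, 4, 4)))
        assert tissue_volume(lm, 2) == 0.0
        assert tissue_extents(lm, 2) == (0.0, 0.0, 0.0)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            tissue_volume(_lm(np.zeros((2, 2, 2))), 0)

    def test_single_voxel_extent_is_one_voxel_edge(self):
        arr = np.zeros((4, 4, 4))
        arr[1, 2, 3] = 1
        assert tissue_extents(_lm(arr), 1) == pytest.approx((0.6, 0.045, 0.045))

    def test_box_extents(self):
        arr = np.zeros((12, 25, 35))
        arr[1:11, 2:22, 3:33] = 4
        lr, ap, si = tissue_extents(_lm(arr), 4)
        assert (lr, ap, si) == pytest.approx((10 * 0.6, 20 * 0.045, 30 * 0.045))


class TestLandmark:
    def test_block_superior_anterior_corner(self):
        arr = np.zeros((4, 10, 10))
        arr[:, 2:6, 1:5] = 3
        lm_ = locate_tuberculum(_lm(arr))
        assert lm_.index == (0, 5, 4)

    def test_tie_prefers_more_anterior(self):
        arr = np.zeros((2, 10, 10))
        arr[1, 3, 7] = 3
        arr[0, 6, 7] = 3   # same superior level, more anterior
        assert locate_tuberculum(_lm(arr)).index == (0, 6, 7)

    def test_no_sinus_raises(self):
        with pytest.raises(LandmarkUnavailableError):
            locate_tuberculum(_lm(np.zeros((2, 2, 2))))

    def test_phantom_landmark_on_sinus_roof(self, archetype_phantoms):
        for _, lm, _, _ in archetype_phantoms.values():
            mark = locate_tuberculum(lm)
            assert lm.voxels[mark.index] == 3
            # brute force: no sinus voxel is more superior
            _, _, kk = np.nonzero(lm.voxels == 3)
            assert mark.k_ts == kk.max()


class TestPlaneVolumes:
    def test_conservation_fossa_and_anterior(self, archetype_phantoms):
        for _, lm, _, _ in archetype_phantoms.values():
            mark = locate_tuberculum(lm)
            total = tissue_volume(lm, 1)
            below = tumor_fossa_volume(lm, mark)
            above = (lm.voxels[:, :, mark.k_ts :] == 1).sum() * lm.voxel_volume_mm3 / 1000
            assert below + above == pytest.approx(total)
            front = tumor_anterior_volume(lm, mark)
            back = (lm.voxels[:, : mark.j_ts + 1, :] == 1).sum() * lm.voxel_volume_mm3 / 1000
            assert front + back == pytest.approx(total)

    def test_intrasellar_fraction_recovered(self, archetype_phantoms):
        for t in "QST":
            _, lm, _, spec = archetype_phantoms[t]
            frac = tumor_fossa_volume(lm, locate_tuberculum(lm)) / tissue_volume(lm, 1)
            assert frac == pytest.approx(spec.intrasellar_fraction, abs=0.05)

    def test_anterior_fraction_recovered(self, archetype_phantoms):
        for t in "QST":
            _, lm, _, spec = archetype_phantoms[t]
            frac = tumor_anterior_volume(lm, locate_tuberculum(lm)) / tissue_volume(lm, 1)
            assert frac == pytest.approx(spec.anterior_fraction, abs=0.05)


class TestRelativePosition:
    def test_centered_tumor_zero_offset(self):
        arr = np.zeros((5, 21, 21))
        arr[:, 5:16, 5:16] = 4    # brain box
        arr[2, 9:12, 9:12] = 1    # tumor at its centre
        off = relative_position(_lm(arr), "brain")
        assert off == pytest.approx((0, 0, 0), abs=1e-9)

    def test_translation_invariance(self):
        base = np.zeros((6, 30, 30))
        base[1:4, 4:14, 4:14] = 4
        base[2, 6:9, 10:13] = 1
        shifted = np.roll(base, (5, 5), axis=(1, 2))
        a = relative_position(_lm(base), "brain")
        b = relative_position(_lm(shifted), "brain")
        assert a == pytest.approx(b)

    def test_t_phantom_sits_posterior_to_brain(self, archetype_phantoms):
        _, lm, _, _ = archetype_phantoms["T"]
        off = relative_position(lm, "brain")
        assert off[1] < -0.05


class TestWidestLevel:
    def _wedge(self, widths):
        arr = np.zeros((3, 40, len(widths) + 2))
        for k, w in enumerate(widths):
            arr[1, 10 : 10 + w, k + 1] = 1
        return _lm(arr)

    def test_downward_widening_is_inferior(self):
        assert widest_level_fraction(self._wedge([9, 7, 5, 3, 1])) < 0.5

    def test_upward_widening_is_superior(self):
        assert widest_level_fraction(self._wedge([1, 3, 5, 7, 9])) > 0.5

    def test_uniform_box_ties_to_lowest_level(self):
        assert widest_level_fraction(self._wedge([5, 5, 5, 5])) == 0.0

    def test_single_level_is_half(self):
        assert widest_level_fraction(self._wedge([5])) == 0.5

    def test_phantom_recovers_spec_value(self, archetype_phantoms):
        for t in "QST":
            _, lm, _, spec = archetype_phantoms[t]
            assert widest_level_fraction(lm) == pytest.approx(
                spec.widest_level_fraction, abs=0.06
            )


class TestAspectRatio:
    def test_cube_is_one(self):
        arr = np.zeros((3, 10, 10))
        arr[1, 2:8, 2:8] = 1
        assert aspect_ratio(_lm(arr, spacing=(6.0, 1.0, 1.0))) == 1.0

    def test_known_ratio(self, archetype_phantoms):
        _, lm, _, spec = archetype_phantoms["S"]
        assert aspect_ratio(lm) == pytest.approx(
            spec.tumor_ap_cm / spec.tumor_si_cm, abs=0.08
        )


class TestExtractFeatures:
    def test_exactly_34_features_and_deterministic(self, archetype_phantoms):
        _, lm, _, _ = archetype_phantoms["Q"]
        f1, f2 = extract_features(lm), extract_features(lm)
        assert len(f1) == N_FEATURES == len(FEATURE_NAMES)
        assert np.array_equal(f1.values, f2.values)
        assert np.array_equal(f1.missing, f2.missing)

    def test_absent_pituitary_flagged_not_zero_filled_silently(self, archetype_phantoms):
        _, lm, _, _ = archetype_phantoms["Q"]
        f = extract_features(lm)
        assert f.is_missing("pituitary_volume_cm3")
        assert f["pituitary_volume_cm3"] == 0.0

    def test_left_right_mirror_invariance(self, archetype_phantoms):
        for _, lm, _, _ in archetype_phantoms.values():
            flipped = LabelMap(lm.voxels[::-1].copy(), spacing=lm.spacing)
            a, b = extract_features(lm), extract_features(flipped)
            assert a.values == pytest.approx(b.values, nan_ok=True)
            assert np.array_equal(a.missing, b.missing)

    def test_archetypes_fall_on_their_side_of_every_cutoff(self, archetype_phantoms):
        th = ScaleThresholds()
        f = {t: extract_features(archetype_phantoms[t][1]) for t in "QST"}
        # Q: small AP, tall SI, big fossa volume, anterior, gland invisible
        assert f["Q"]["tumor_extent_ap_cm"] < th.ap_cm
        assert f["Q"]["tumor_extent_si_cm"] > th.si_cm
        assert f["Q"]["fossa_volume_cm3"] > th.fossa_cm3
        assert f["Q"]["tumor_vs_brain_ap"] > th.position_deadzone
        # S: transverse, anterior volume, widest inferior, gland visible
        assert f["S"]["aspect_ratio"] > th.aspect
        assert f["S"]["anterior_volume_cm3"] > th.anterior_cm3
        assert f["S"]["widest_level_fraction"] < th.widest_split
        assert f["S"]["pituitary_volume_cm3"] >= th.pituitary_seen_cm3
        # T: posterior, small fossa volume, widest superior
        assert f["T"]["tumor_vs_brain_ap"] < -th.position_deadzone
        assert f["T"]["fossa_volume_cm3"] < th.fossa_cm3
        assert f["T"]["widest_level_fraction"] >= th.widest_split

    def test_transformer_emits_matrix_with_nan_for_missing(self, archetype_phantoms):
        maps = [archetype_phantoms[t][1] for t in "QST"]
        mat = ClinicalFeatureExtractor().fit().transform(maps)
        assert mat.shape == (3, N_FEATURES)
        q_row = mat[0]
        assert np.isnan(q_row[list(FEATURE_NAMES).index("pituitary_volume_cm3")])
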