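from __future__ import annotations

import numpy as np
import pytest

from ce4dct.compare import (
    ComparisonReport,
    centroid,
    centroid_shift,
    compare_masks,
    derive_margins,
    evaluate_with_margins,
    mean_distance_agreement,
    overlap_indices,
    pct_volume_difference,
)
from ce4dct.phantom import generate_itv_pair
from ce4dct.structures import GridMismatchError, MarginVector, VoxelMask

from conftest import random_mask
from oracles import (
    oracle_centroid,
    oracle_dice_jaccard,
    oracle_margins,
    oracle_mda,
)


def mask_from(vox, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelMask(np.asarray(vox, bool), spacing, origin)


def shifted(mask: VoxelMask, axis: int, steps: int) -> VoxelMask:
    vox = np.zeros_like(mask.voxels)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if steps >= 0:
        dst[axis], src[axis] = slice(steps, None), slice(None, -steps or None)
    else:
        dst[axis], src[axis] = slice(None, steps), slice(-steps, None)
    vox[tuple(dst)] = mask.voxels[tuple(src)]
    return VoxelMask(vox, mask.spacing, mask.origin)


class TestCentroid:
    def test_single_voxel(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 3, 4] = True
        m = mask_from(vox, spacing=(1.0, 2.0, 3.0), origin=(1.0, 1.0, 1.0))
        np.testing.assert_allclose(centroid(m), [3.0, 7.0, 13.0])

    def test_sphere_symmetry(self):
        x = np.arange(21)
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        vox = (xx - 10.0) ** 2 + (yy - 10.0) ** 2 + (zz - 10.0) ** 2 <= 49
        m = mask_from(vox)
        np.testing.assert_allclose(centroid(m), [10.0, 10.0, 10.0], atol=0.5)

    def test_l_shape_matches_loop_oracle(self):
        vox = np.zeros((8, 8, 8), bool)
        vox[1:6, 1:3, 1:3] = True
        vox[1:3, 1:7, 1:3] = True
        m = mask_from(vox, spacing=(0.8, 1.1, 2.0))
        np.testing.assert_allclose(
            centroid(m), oracle_centroid(m.voxels, m.spacing, m.origin), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centroid(mask_from(np.zeros((3, 3, 3))))


class TestOverlapIndices:
    def test_identical(self, rng):
        m = random_mask(rng)
        assert overlap_indices(m, m) == (1.0, 1.0)

    def test_disjoint(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:3], b[6:] = True, True
        assert overlap_indices(mask_from(a), mask_from(b)) == (0.0, 0.0)

    def test_shifted_cube_half_overlap(self):
        vox = np.zeros((20, 20, 20), bool)
        vox[0:10, 0:10, 0:10] = True
        a = mask_from(vox)
        b = shifted(a, 0, 5)
        dice, jaccard = overlap_indices(a, b)
        assert dice == pytest.approx(0.5)  # 500/1000 intersection
        assert jaccard == pytest.approx(1.0 / 3.0)

    def test_both_empty_convention(self):
        e = mask_from(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty"):
            assert overlap_indices(e, e) == (1.0, 1.0)

    def test_dice_jaccard_relation(self, rng):
        a = random_mask(rng, max_dim=14)
        b = VoxelMask(np.roll(a.voxels, 2, axis=1), a.spacing)
        dice, jaccard = overlap_indices(a, b)
        assert jaccard <= dice
        assert dice == pytest.approx(2 * jaccard / (1 + jaccard), abs=1e-9)

    def test_symmetry(self, rng):
        a = random_mask(rng, max_dim=12)
        b = VoxelMask(np.roll(a.voxels, 1, axis=2), a.spacing)
        assert overlap_indices(a, b) == overlap_indices(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            overlap_indices(mask_from(np.ones((4, 4, 4))),
                            mask_from(np.ones((4, 4, 4)), spacing=(2, 2, 2)))


class TestMDA:
    def test_identical_zero(self, rng):
        m = random_mask(rng)
        assert mean_distance_agreement(m, m) == 0.0

    def test_translation_upper_bound(self):
        vox = np.zeros((20, 20, 20), bool)
        vox[4:10, 4:10, 4:10] = True
        a = mask_from(vox, spacing=(1.0, 1.0, 2.0))
        b = shifted(a, 2, 3)  # 6 mm shift along z
        assert mean_distance_agreement(a, b) <= 6.0 + 1e-9

    def test_two_slabs_match_all_pairs_oracle(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2:5, 2:8, 2:4] = True
        b[5:9, 3:7, 3:8] = True
        ma = mask_from(a, spacing=(1.0, 1.3, 2.0))
        mb = mask_from(b, spacing=(1.0, 1.3, 2.0))
        got = mean_distance_agreement(ma, mb)
        expected = oracle_mda(a, b, (1.0, 1.3, 2.0))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self, rng):
        a = random_mask(rng, max_dim=12)
        b = VoxelMask(np.roll(a.voxels, 1, axis=0), a.spacing)
        assert (mean_distance_agreement(a, b)
                == mean_distance_agreement(b, a))

    def test_empty_rejected(self, rng):
        m = random_mask(rng, max_dim=8)
        with pytest.raises(ValueError):
            mean_distance_agreement(m, mask_from(np.zeros(m.dims), m.spacing))


class TestPctVolumeDifference:
    def test_equal_zero(self):
        assert pct_volume_difference(25.0, 25.0) == 0.0

    def test_simple_arithmetic(self):
        assert pct_volume_difference(20.0, 25.0) == pytest.approx(-20.0)

    def test_sign_convention_larger_itv2(self):
        # a 13.4% larger comparison volume reads +13.4% against reference
        assert pct_volume_difference(1.134 * 50.0, 50.0) == pytest.approx(13.4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pct_volume_difference(10.0, 0.0)


class TestDeriveMargins:
    def test_contained_all_zero(self):
        outer = np.zeros((16, 16, 16), bool)
        inner = np.zeros((16, 16, 16), bool)
        outer[2:14, 2:14, 2:14] = True
        inner[5:10, 5:10, 5:10] = True
        m = derive_margins(mask_from(outer), mask_from(inner))
        np.testing.assert_array_equal(m.as_array(), 0.0)

    def test_translated_toward_s(self):
        vox = np.zeros((16, 16, 16), bool)
        vox[4:10, 4:10, 4:10] = True
        itv2 = mask_from(vox, spacing=(1.0, 1.0, 2.0))
        itv1 = shifted(itv2, 2, 2)  # +4 mm toward S
        m = derive_margins(itv2, itv1)
        np.testing.assert_allclose(m.as_array(), [0, 0, 0, 0, 4.0, 0])

    def test_matches_extent_oracle(self, rng):
        for _ in range(5):
            a = random_mask(rng, max_dim=14)
            b = VoxelMask(np.roll(a.voxels, (1, -2, 1), axis=(0, 1, 2)), a.spacing)
            got = derive_margins(a, b).as_dict()
            expected = oracle_margins(a.voxels, b.voxels, a.spacing)
            for d in "rlapsi":
                assert got[d] == pytest.approx(expected[d], abs=1e-9)

    def test_self_margins_zero(self, rng):
        m = random_mask(rng)
        np.testing.assert_array_equal(derive_margins(m, m).as_array(), 0.0)

    def test_translation_equivariance_single_direction(self):
        # translating the reference +t toward P adds exactly t to margin P
        vox = np.zeros((20, 20, 20), bool)
        vox[6:14, 6:14, 6:14] = True
        itv2 = mask_from(vox)
        base = derive_margins(itv2, itv2).as_dict()
        for t_steps in (1, 3):
            moved = shifted(itv2, 1, t_steps)
            m = derive_margins(itv2, moved).as_dict()
            assert m["p"] == pytest.approx(base["p"] + t_steps * 1.0)
            for d in "rlasi":
                assert m[d] == pytest.approx(base[d])

    def test_phantom_ground_truth(self, small_spec):
        itv1, itv2, expected = generate_itv_pair(
            small_spec, dropout_phases=(0,), known_shift_mm=(2.0, 0.0, -4.0))
        got = derive_margins(itv2, itv1)
        voxel = max(small_spec.spacing)
        np.testing.assert_allclose(got.as_array(), expected.as_array(),
                                   atol=voxel + 1e-9)


class TestEvaluateWithMargins:
    def test_zero_margins_equals_plain_report(self, small_spec):
        itv1, itv2, _ = generate_itv_pair(small_spec, dropout_phases=(0,))
        plain = compare_masks(itv1, itv2)
        with pytest.warns(UserWarning):  # itv2 misses itv1 extremes
            post = evaluate_with_margins(itv2, MarginVector.zeros(), itv1)
        assert post == plain

    def test_derived_margins_encompass_extremes(self, small_spec):
        itv1, itv2, _ = generate_itv_pair(small_spec, dropout_phases=(0, 9),
                                          known_shift_mm=(0.0, 2.0, 2.0))
        margins = derive_margins(itv2, itv1)
        post = evaluate_with_margins(itv2, margins, itv1, strict=True)
        assert isinstance(post, ComparisonReport)

    def test_post_margin_dice_improves(self, small_spec):
        itv1, itv2, _ = generate_itv_pair(small_spec, dropout_phases=(0, 1, 9))
        pre = compare_masks(itv1, itv2)
        margins = derive_margins(itv2, itv1)
        post = evaluate_with_margins(itv2, margins, itv1, strict=True)
        assert post.dice >= pre.dice


class TestCompareMasks:
    def test_report_fields_consistent(self, small_spec):
        itv1, itv2, _ = generate_itv_pair(small_spec, dropout_phases=(0,))
        rep = compare_masks(itv1, itv2)
        assert rep.vol1_cc == pytest.approx(itv1.volume_cc)
        assert rep.vol2_cc == pytest.approx(itv2.volume_cc)
        assert rep.jaccard <= rep.dice <= 1.0
        assert rep.dice == pytest.approx(2 * rep.jaccard / (1 + rep.jaccard),
                                         abs=1e-9)
        assert rep.centroid_shift_mm >= 0.0
        assert rep.mda_mm >= 0.0

    def test_translation_invariance_of_overlap(self, rng):
        a = random_mask(rng, max_dim=12)
        b = VoxelMask(np.roll(a.voxels, 1, axis=0), a.spacing)
        d0 = overlap_indices(a, b)
        a2 = VoxelMask(a.voxels, a.spacing, origin=(5.0, -3.0, 2.0))
        b2 = VoxelMask(b.voxels, b.spacing, origin=(5.0, -3.0, 2.0))
        assert overlap_indices(a2, b2) == d0

    def test_random_masks_match_oracles(self, rng):
        for _ in range(3):
            a = random_mask(rng, max_dim=10)
            b = VoxelMask(np.roll(a.voxels, 1, axis=1), a.spacing)
            dice, jaccard = overlap_indices(a, b)
            od, oj = oracle_dice_jaccard(a.voxels, b.voxels)
            assert dice == pytest.approx(od, abs=1e-12)
            assert jaccard == pytest.approx(oj, abs=1e-12)
            assert centroid_shift(a, b) == pytest.approx(
                float(np.linalg.norm(
                    oracle_centroid(a.voxels, a.spacing, a.origin)
                    - oracle_centroid(b.voxels, b.spacing, b.origin))), abs=1e-9)
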