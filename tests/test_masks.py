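"""Mask pipeline: rescale, denoise, threshold, mask algebra, labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from myofuse.masks import (
    binarize,
    classify_fusion_pixels,
    denoise_median,
    label_myotubes,
    mask_and,
    mask_subtract,
    to_grayscale8,
)

from oracles import flood_fill_components, median_filter_oracle, truth_table_areas


class TestGrayscale8:
    def test_endpoints_map_to_0_and_255(self):
        img = np.array([[0, 65535]], dtype=np.uint16)
        out = to_grayscale8(img)
        assert out.dtype == np.uint8
        assert out.tolist() == [[0, 255]]

    def test_constant_image_maps_to_zero(self):
        assert to_grayscale8(np.full((4, 4), 500)).max() == 0

    def test_two_point_rescale(self):
        assert to_grayscale8(np.array([[100], [300]])).ravel().tolist() == [0, 255]

    @pytest.mark.parametrize("bad", [np.empty((0, 3)), np.array([[1.0, np.nan]]), np.array([[-1.0, 2.0]])])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            to_grayscale8(bad)


class TestMedianDenoise:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.array_equal(denoise_median(img, 0), img)

    def test_removes_isolated_hot_pixel(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 255
        assert denoise_median(img, 2).max() == 0

    def test_matches_bruteforce_disc_median(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert np.array_equal(denoise_median(img, 2), median_filter_oracle(img, 2))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            denoise_median(np.zeros((4, 4), dtype=np.uint8), -1)


class TestBinarize:
    def test_threshold_zero_all_true(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        mask, t = binarize(img, "fixed", 0)
        assert mask.all() and t == 0

    def test_threshold_above_max_all_false(self):
        img = np.full((4, 4), 100, dtype=np.uint8)
        mask, _ = binarize(img, "fixed", 101)
        assert not mask.any()

    def test_otsu_separates_bimodal_like_any_between_modes_threshold(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((32, 32)) < 0.4, 200, 10).astype(np.uint8)
        otsu_mask, t = binarize(img, "otsu")
        assert 10 < t <= 200
        for fixed_t in range(11, 201):
            fixed_mask, _ = binarize(img, "fixed", fixed_t)
            assert np.array_equal(otsu_mask, fixed_mask)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        lower, _ = binarize(img, "fixed", 60)
        higher, _ = binarize(img, "fixed", 120)
        assert (lower | higher).sum() == lower.sum()  # higher-threshold mask ⊆ lower


class TestMaskAlgebra:
    @pytest.fixture
    def random_pair(self):
        rng = np.random.default_rng(3)
        return rng.random((16, 16)) < 0.5, rng.random((16, 16)) < 0.5

    def test_and_idempotent_and_annihilator(self, random_pair):
        a, _ = random_pair
        assert np.array_equal(mask_and(a, a), a)
        assert not mask_and(a, np.zeros_like(a)).any()

    def test_subtract_self_and_identity(self, random_pair):
        a, _ = random_pair
        assert not mask_subtract(a, a).any()
        assert np.array_equal(mask_subtract(a, np.zeros_like(a)), a)

    def test_matches_per_pixel_oracle(self, random_pair):
        a, b = random_pair
        for r in range(a.shape[0]):
            for c in range(a.shape[1]):
                assert mask_and(a, b)[r, c] == (a[r, c] and b[r, c])
                assert mask_subtract(a, b)[r, c] == (a[r, c] and not b[r, c])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_and(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestClassifyFusionPixels:
    def test_full_overlap_is_all_dual(self):
        full = np.ones((8, 8), dtype=bool)
        cm = classify_fusion_pixels(full, full, full)
        assert cm.mt_dual.all() and not cm.mt_gfp.any() and not cm.mt_rfp.any()

    def test_single_channel_is_single_class(self):
        full, empty = np.ones((8, 8), bool), np.zeros((8, 8), bool)
        cm = classify_fusion_pixels(full, empty, full)
        assert cm.mt_gfp.all() and not cm.mt_rfp.any() and not cm.mt_dual.any()

    def test_matches_truth_table_oracle(self):
        rng = np.random.default_rng(5)
        gfp, rfp, myh = (rng.random((32, 32)) < 0.5 for _ in range(3))
        cm = classify_fusion_pixels(gfp, rfp, myh)
        expected = truth_table_areas(gfp, rfp, myh)
        assert cm.area("mt_gfp") == expected["MT_GFP"]
        assert cm.area("mt_rfp") == expected["MT_RFP"]
        assert cm.area("mt_dual") == expected["MT_DUAL"]
        assert int(cm.unclassified.sum()) == expected["UNCLASSIFIED"]

    def test_partition_of_myh_area(self):
        rng = np.random.default_rng(6)
        gfp, rfp, myh = (rng.random((32, 32)) < 0.5 for _ in range(3))
        cm = classify_fusion_pixels(gfp, rfp, myh)
        total = cm.area("mt_gfp") + cm.area("mt_rfp") + cm.area("mt_dual")
        assert total + int(cm.unclassified.sum()) == int(myh.sum())
        # disjointness and subset invariants
        assert not (cm.mt_gfp & cm.mt_rfp).any()
        assert not (cm.mt_gfp & cm.mt_dual).any()
        assert not (cm.mt_rfp & cm.mt_dual).any()
        for m in (cm.mt_gfp, cm.mt_rfp, cm.mt_dual):
            assert not (m & ~cm.myh_total).any()

    def test_swapping_gfp_rfp_swaps_classes(self):
        rng = np.random.default_rng(8)
        gfp, rfp, myh = (rng.random((16, 16)) < 0.5 for _ in range(3))
        cm = classify_fusion_pixels(gfp, rfp, myh)
        swapped = classify_fusion_pixels(rfp, gfp, myh)
        assert np.array_equal(cm.mt_gfp, swapped.mt_rfp)
        assert np.array_equal(cm.mt_rfp, swapped.mt_gfp)
        assert np.array_equal(cm.mt_dual, swapped.mt_dual)


bool_mask = arrays(np.bool_, (12, 12), elements=st.booleans())


@settings(max_examples=30, derandomize=True, deadline=None)
@given(gfp=bool_mask, rfp=bool_mask, myh=bool_mask)
def test_classification_partition_property(gfp, rfp, myh):
    """For any mask triplet, the class masks partition the classified
    MYH area: disjoint, within MYH, and sum + unclassified = MYH."""
    cm = classify_fusion_pixels(gfp, rfp, myh)
    assert not (cm.mt_gfp & cm.mt_rfp).any()
    assert not (cm.mt_gfp & cm.mt_dual).any()
    assert not (cm.mt_rfp & cm.mt_dual).any()
    union = cm.mt_gfp | cm.mt_rfp | cm.mt_dual
    assert not (union & ~cm.myh_total).any()
    assert (union | cm.unclassified).sum() == cm.myh_total.sum()
    # equality of areas when gfp ∨ rfp covers myh
    if ((gfp | rfp) | ~myh).all():
        assert not cm.unclassified.any()


class TestLabelMyotubes:
    def test_empty_mask_gives_empty_list(self):
        res = label_myotubes(np.zeros((16, 16), bool), min_area=1)
        assert res.records == [] and res.n_discarded == 0

    def test_two_separated_squares(self):
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        res = label_myotubes(mask, min_area=1)
        assert sorted(r.area_px for r in res.records) == [9, 9]

    def test_min_area_discards_small_components(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True  # 1-px speck
        mask[5:10, 5:10] = True  # 25-px object
        res = label_myotubes(mask, min_area=5)
        assert len(res.records) == 1 and res.n_discarded == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(9)
        mask = rng.random((64, 64)) < 0.45
        res = label_myotubes(mask, min_area=1, connectivity=connectivity)
        assert sorted(r.area_px for r in res.records) == flood_fill_components(mask, connectivity)

    def test_pixel_size_scales_area(self):
        mask = np.zeros((8, 8), bool)
        mask[1:4, 1:4] = True
        res = label_myotubes(mask, min_area=1, pixel_size=0.5)
        assert res.records[0].area_um2 == pytest.approx(9 * 0.25)
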