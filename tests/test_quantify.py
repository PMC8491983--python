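import warnings

import numpy as np
import pytest

from pdl1quant.quantify import (
    LabeledComponents,
    QuantConfig,
    ROIPolygon,
    SlidePair,
    _decide_call,
    classify_cells,
    deduct_control,
    label_nuclei,
    make_brown_mask,
    make_nucleus_mask,
    make_tissue_mask,
    quantify_roi,
    rasterize_roi,
    register_masks,
    translate_mask,
)
from pdl1quant.stains import RGBImage, StainChannels, rgb_to_optical_density, separate_stains
from pdl1quant.synthetic import ImageSimParams, generate_ihc_pair


def white(h=64, w=64):
    return RGBImage(np.full((h, w, 3), 255, dtype=np.uint8))


class TestRasterizeROI:
    def test_axis_aligned_square_covers_100_pixels(self):
        roi = ROIPolygon([(0, 0), (9, 0), (9, 9), (0, 9)])
        mask = rasterize_roi(roi, (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all() and not mask[10:, :].any()

    def test_matches_bruteforce_point_in_polygon(self):
        verts = [(2.5, 1.0), (17.2, 3.3), (12.0, 18.0), (1.0, 11.5)]
        mask = rasterize_roi(ROIPolygon(verts), (20, 20))
        from shapely.geometry import Point, Polygon

        poly = Polygon(verts)
        for y in range(20):
            for x in range(20):
                expected = poly.intersects(Point(x, y))
                assert mask[y, x] == expected

    def test_full_frame_rectangle(self):
        roi = ROIPolygon([(0, 0), (7, 0), (7, 7), (0, 7)])
        assert rasterize_roi(roi, (8, 8)).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            rasterize_roi(ROIPolygon([(0, 0), (5, 5), (10, 10)]), (20, 20))
        with pytest.raises(ValueError):
            ROIPolygon([(0, 0), (5, 5)])


class TestTissueMask:
    def test_uniform_white_yields_empty_mask(self):
        roi = np.ones((32, 32), dtype=bool)
        mask, _ = make_tissue_mask(white(32, 32), roi)
        assert not mask.any()

    def test_dark_disc_on_white_recovered(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        ys, xs = np.mgrid[0:64, 0:64]
        disc = (xs - 32) ** 2 + (ys - 32) ** 2 <= 15**2
        img[disc] = 90
        mask, _ = make_tissue_mask(RGBImage(img), np.ones((64, 64), bool))
        assert abs(mask.sum() - disc.sum()) <= 0.05 * disc.sum()
        assert mask[disc].mean() > 0.95

    def test_roi_excluding_the_disc_is_empty(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        img[40:60, 40:60] = 90
        roi = np.zeros((64, 64), bool)
        roi[:20, :20] = True
        mask, _ = make_tissue_mask(RGBImage(img), roi)
        assert not mask.any()

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            make_tissue_mask(white(), np.zeros((64, 64), bool))


class TestStainMasks:
    def test_zero_channels_give_empty_masks_with_warning(self):
        ch = StainChannels(
            blue=np.zeros((16, 16)), brown=np.zeros((16, 16)), residual=np.zeros((16, 16))
        )
        region = np.ones((16, 16), bool)
        with pytest.warns(UserWarning, match="degenerate"):
            nuc, t = make_nucleus_mask(ch, region)
        assert not nuc.any() and t is None
        with pytest.warns(UserWarning, match="degenerate"):
            brown, t = make_brown_mask(ch, region)
        assert not brown.any() and t is None

    def test_masks_restricted_to_region(self, clean_pair_f30, default_config):
        pair, _ = clean_pair_f30
        roi = rasterize_roi(pair.roi_stained, pair.stained.shape)
        tissue, _ = make_tissue_mask(pair.stained, roi)
        ch = separate_stains(rgb_to_optical_density(pair.stained))
        nuc, _ = make_nucleus_mask(ch, roi & tissue)
        brown, _ = make_brown_mask(ch, roi & tissue)
        assert not (nuc & ~(roi & tissue)).any()
        assert not (brown & ~(roi & tissue)).any()

    def test_nucleus_mask_area_close_to_truth(self, clean_pair_f30):
        pair, truth = clean_pair_f30
        roi = rasterize_roi(pair.roi_stained, pair.stained.shape)
        tissue, _ = make_tissue_mask(pair.stained, roi)
        ch = separate_stains(rgb_to_optical_density(pair.stained))
        nuc, _ = make_nucleus_mask(ch, roi & tissue)
        true_area = truth.n_cells * np.pi * 4.0**2
        assert abs(nuc.sum() - true_area) <= 0.15 * true_area


class TestRegistration:
    def test_identity_for_identical_masks(self):
        mask = np.zeros((64, 64), bool)
        mask[20:40, 25:45] = True
        assert register_masks(mask, mask) == (0, 0)

    def test_recovers_known_translation(self):
        ref = np.zeros((96, 96), bool)
        ref[30:60, 20:55] = True
        ref[35:45, 60:70] = True  # asymmetry pins the optimum
        moving = translate_mask(ref, (-5, 3))
        assert register_masks(ref, moving) == (5, -3)

    def test_no_overlap_warns_and_returns_identity(self):
        a = np.zeros((64, 64), bool)
        a[:4, :4] = True
        b = np.zeros((64, 64), bool)  # blank control
        with pytest.warns(UserWarning, match="identity"):
            assert register_masks(a, b) == (0, 0)


class TestDeduction:
    def test_empty_control_is_identity(self, rng):
        stained = rng.random((32, 32)) > 0.6
        out = deduct_control(stained, np.zeros((32, 32), bool))
        np.testing.assert_array_equal(out, stained)

    def test_full_overlap_erases_everything(self, rng):
        stained = rng.random((32, 32)) > 0.6
        assert not deduct_control(stained, stained).any()

    def test_corrected_mask_is_subset(self, rng):
        stained = rng.random((48, 48)) > 0.5
        control = rng.random((48, 48)) > 0.5
        for shift in [(0, 0), (3, -2), (-7, 5)]:
            out = deduct_control(stained, control, shift)
            assert not (out & ~stained).any()

    def test_count_mode_leaves_mask_unchanged(self, rng):
        stained = rng.random((16, 16)) > 0.5
        control = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(
            deduct_control(stained, control, mode="count"), stained
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deduct_control(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestLabelNuclei:
    def test_empty_mask(self):
        out = label_nuclei(np.zeros((16, 16), bool))
        assert out.n_components == 0

    def test_two_disjoint_squares(self):
        mask = np.zeros((32, 32), bool)
        mask[2:7, 2:7] = True
        mask[20:25, 20:25] = True
        out = label_nuclei(mask, min_area_px=10)
        assert out.n_components == 2
        assert sorted(out.areas[1:]) == [25, 25]

    def test_min_area_filter_drops_specks(self):
        mask = np.zeros((32, 32), bool)
        mask[2:7, 2:7] = True
        mask[15, 15] = True  # single-pixel speck
        out = label_nuclei(mask, min_area_px=10)
        assert out.n_components == 1

    def test_synthetic_cell_count_recovered(self, clean_pair_f30, default_config):
        pair, truth = clean_pair_f30
        res = quantify_roi(pair, default_config)
        assert abs(res.n_total - truth.n_cells) <= 2


class TestClassifyCells:
    def _one_cell(self):
        mask = np.zeros((32, 32), bool)
        mask[10:18, 10:18] = True
        return label_nuclei(mask, min_area_px=10)

    def test_all_masks_empty_all_negative(self):
        cells = self._one_cell()
        labels = classify_cells(
            cells, np.zeros((32, 32), bool), np.zeros((32, 32), bool)
        )
        assert list(labels) == ["negative"]

    def test_nucleus_inside_pdl1_mask_is_positive(self):
        cells = self._one_cell()
        pdl1 = np.zeros((32, 32), bool)
        pdl1[5:25, 5:25] = True
        labels = classify_cells(cells, pdl1, np.zeros((32, 32), bool))
        assert list(labels) == ["pdl1_pos"]

    def test_pdl1_takes_precedence_over_melanin(self):
        cells = self._one_cell()
        both = np.zeros((32, 32), bool)
        both[5:25, 5:25] = True
        labels = classify_cells(cells, both, both)
        assert list(labels) == ["pdl1_pos"]

    def test_min_overlap_threshold_respected(self):
        cells = self._one_cell()
        pdl1 = np.zeros((32, 32), bool)
        pdl1[10:13, 10:13] = True  # 9 px < default 10
        assert list(classify_cells(cells, pdl1, np.zeros((32, 32), bool))) == ["negative"]
        assert list(
            classify_cells(cells, pdl1, np.zeros((32, 32), bool), min_overlap_px=5)
        ) == ["pdl1_pos"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_cells(self._one_cell(), np.zeros((8, 8), bool), np.zeros((8, 8), bool))


class TestCallRule:
    @pytest.mark.parametrize(
        "n_total, n_pdl1, expected_pct, expected_call",
        [
            (100, 5, 5.0, "positive"),  # >=5% of >=100 cells is positive
            (100, 4, 4.0, "negative"),
            (80, 40, 50.0, "indeterminate"),  # too few evaluable cells
        ],
    )
    def test_cutoff_and_min_cells(self, n_total, n_pdl1, expected_pct, expected_call):
        pct, call = _decide_call(n_total, n_pdl1, cutoff_percent=5.0, min_cells=100)
        assert pct == pytest.approx(expected_pct)
        assert call == expected_call

    def test_zero_cells_percent_is_missing(self):
        pct, call = _decide_call(0, 0, 5.0, 100)
        assert pct is None and call == "indeterminate"

    def test_min_cells_guard_can_be_disabled(self):
        pct, call = _decide_call(80, 40, 5.0, None)
        assert call == "positive"


class TestQuantifyROI:
    def test_determinism_bit_identical(self, default_config):
        pair, _ = generate_ihc_pair(ImageSimParams(pdl1_fraction=0.2, seed=77))
        a = quantify_roi(pair, default_config)
        b = quantify_roi(pair, default_config)
        assert a == b

    def test_corrected_mask_subset_holds_end_to_end(self, melanin_pair_f30):
        pair, _ = melanin_pair_f30
        roi = rasterize_roi(pair.roi_stained, pair.stained.shape)
        tissue, _ = make_tissue_mask(pair.stained, roi)
        ch_s = separate_stains(rgb_to_optical_density(pair.stained))
        ch_c = separate_stains(rgb_to_optical_density(pair.control))
        roi_c = rasterize_roi(pair.roi_control, pair.control.shape)
        tissue_c, _ = make_tissue_mask(pair.control, roi_c)
        brown_s, _ = make_brown_mask(ch_s, roi & tissue)
        brown_c, _ = make_brown_mask(ch_c, roi_c & tissue_c)
        corrected = deduct_control(brown_s, brown_c, (0, 0))
        assert not (corrected & ~brown_s).any()

    def test_count_mode_is_a_conservative_fallback(self, melanin_pair_f30):
        """Count-level deduction subtracts whole-slide brown cell counts,
        so pigmented or background-touched PD-L1+ cells are deducted
        twice: it tracks the truth coarsely and errs low, never high."""
        pair, truth = melanin_pair_f30
        pix = quantify_roi(pair, QuantConfig(mode="pixel"))
        cnt = quantify_roi(pair, QuantConfig(mode="count"))
        assert cnt.mode == "count"
        assert abs(cnt.percent_pdl1 - 100 * truth.true_fraction) <= 15.0
        assert cnt.percent_pdl1 <= pix.percent_pdl1 + 2.0

    def test_melanin_only_pair_scores_negative(self):
        pair, _ = generate_ihc_pair(
            ImageSimParams(pdl1_fraction=0.0, melanin_area_fraction=0.15, seed=31)
        )
        res = quantify_roi(pair, QuantConfig())
        assert res.call == "negative"
        assert res.percent_pdl1 <= 2.0
        assert res.n_melanin > 0
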