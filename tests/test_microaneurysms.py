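import numpy as np
import pytest

from oracles import brute_dilate, brute_erode, exhaustive_otsu
from retinoquant.exudates import label_regions
from retinoquant.fundus_io import PixelCalibration, extract_green
from retinoquant.microaneurysms import (
    MAConfig,
    binarize_invert,
    circle_offsets,
    count_mas,
    filter_candidates,
    hough_accumulate,
    hough_circles,
    otsu_threshold,
    remove_vessels,
)

CAL10 = PixelCalibration(microns_per_pixel=10.0)


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        gray = np.array([50 / 255] * 10 + [200 / 255] * 10).reshape(4, 5)
        res = otsu_threshold(gray)
        assert 50 / 255 < res.threshold < 200 / 255
        k, var = exhaustive_otsu(gray)
        assert res.threshold == pytest.approx((k + 0.5) / 255)
        assert res.between_class_variance * 255**2 == pytest.approx(var)

    def test_tie_broken_by_lowest_threshold(self):
        # equal masses at bins 50 and 200: every cut in [50, 199] yields the
        # same between-class variance, so the lowest (50) must be returned
        gray = np.array([50 / 255] * 8 + [200 / 255] * 8)
        res = otsu_threshold(gray.reshape(4, 4))
        assert res.threshold == pytest.approx((50 + 0.5) / 255)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 0.4))

    def test_matches_exhaustive_scan_on_random_images(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, (64, 64)) / 255.0
            res = otsu_threshold(gray)
            k, _ = exhaustive_otsu(gray)
            assert res.threshold == pytest.approx((k + 0.5) / 255)

    def test_agrees_with_skimage_partition(self, rng):
        from skimage.filters import threshold_otsu

        gray = rng.integers(0, 256, (50, 50)) / 255.0
        ours = gray > otsu_threshold(gray).threshold
        theirs = gray > threshold_otsu(gray, nbins=256)
        np.testing.assert_array_equal(ours, theirs)

    def test_class_probabilities_sum_to_one(self, rng):
        res = otsu_threshold(rng.random((32, 32)))
        assert sum(res.class_probs) == pytest.approx(1.0)
        assert res.histogram.sum() == 32 * 32

    def test_mask_restricts_histogram(self, rng):
        gray = np.full((20, 20), 0.9)
        gray[:10] = rng.uniform(0.0, 0.5, (10, 20))
        mask = np.zeros((20, 20), bool)
        mask[:10] = True
        res = otsu_threshold(gray, mask=mask)
        assert res.threshold < 0.5  # the 0.9 half never entered the histogram


class TestBinarizeInvert:
    def test_dark_pixels_become_foreground(self):
        gray = np.full((6, 6), 0.9)
        gray[2, 3] = 0.1
        mask = binarize_invert(gray, 0.5)
        assert mask[2, 3] and mask.sum() == 1

    def test_threshold_below_minimum_gives_empty(self, rng):
        gray = rng.uniform(0.5, 1.0, (8, 8))
        assert not binarize_invert(gray, 0.4).any()

    def test_complement_identity(self, rng):
        gray = rng.random((16, 16))
        t = 0.5
        np.testing.assert_array_equal(binarize_invert(gray, t), ~(gray > t))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -1.0])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            binarize_invert(np.random.rand(4, 4), bad)


class TestRemoveVessels:
    def test_small_dot_fully_retained(self):
        mask = np.zeros((21, 21), bool)
        mask[9:12, 9:12] = True  # 3-px-wide dot, erased by the 2-px erosion
        np.testing.assert_array_equal(remove_vessels(mask), mask)

    def test_wide_bar_almost_fully_removed(self):
        mask = np.zeros((40, 120), bool)
        mask[17:24, 10:110] = True  # 7 px x 100 px vessel-like bar
        out = remove_vessels(mask)
        assert out.sum() < 0.05 * mask.sum()

    def test_empty_mask(self):
        assert not remove_vessels(np.zeros((10, 10), bool)).any()

    def test_output_subset_of_input(self, rng):
        mask = rng.random((40, 40)) < 0.3
        assert not (remove_vessels(mask) & ~mask).any()

    def test_matches_brute_force_oracle(self, rng):
        mask = rng.random((24, 24)) < 0.35
        expected = mask & ~brute_dilate(brute_erode(mask, 2), 3)
        np.testing.assert_array_equal(remove_vessels(mask), expected)

    def test_dilate_difference_variant_also_subset(self, rng):
        mask = rng.random((30, 30)) < 0.4
        out = remove_vessels(mask, dilate_difference=True)
        assert not (out & ~mask).any()


class TestFilterCandidates:
    def _regions(self, areas):
        mask = np.zeros((100, 100), bool)
        col = 2
        for a in areas:  # horizontal strips are low-circularity; use squares
            side = int(np.ceil(np.sqrt(a)))
            mask[2:2 + side, col:col + side] = True
            col += side + 3
        return label_regions(mask)

    def test_mid_sized_round_region_kept(self):
        # area 20 px at 10 um/px -> equivalent diameter ~50.5 um
        from skimage.morphology import disk

        lr = label_regions(np.pad(disk(2).astype(bool), 3))  # area 13 -> 40.7 um
        kept = filter_candidates(lr, CAL10)
        assert len(kept) == 1

    def test_oversized_region_rejected(self):
        from skimage.morphology import disk

        lr = label_regions(np.pad(disk(10).astype(bool), 3))  # area 317 -> ~200 um
        assert filter_candidates(lr, CAL10) == []

    def test_low_circularity_rejected(self):
        mask = np.zeros((40, 40), bool)
        mask[5:7, 2:32] = True  # 2 x 30 bar: MA-sized area, vessel-like shape
        lr = label_regions(mask)
        assert 30 <= 2 * np.sqrt(60 / np.pi) * 10 <= 100  # size alone would pass
        assert filter_candidates(lr, CAL10) == []

    def test_empty_input(self):
        assert filter_candidates(label_regions(np.zeros((5, 5), bool)), CAL10) == []


class TestHough:
    def test_blank_edge_mask(self):
        assert hough_circles(np.zeros((30, 30), bool), [3, 5]) == []

    def test_empty_radii_rejected(self):
        with pytest.raises(ValueError):
            hough_circles(np.zeros((10, 10), bool), [])

    def test_single_full_circle_recovered(self):
        mask = np.zeros((80, 80), bool)
        offs = circle_offsets(10)
        mask[offs[:, 0] + 40, offs[:, 1] + 40] = True
        cands = hough_circles(mask, list(range(5, 16)))
        assert len(cands) == 1
        c = cands[0]
        assert abs(c.center[0] - 40) <= 1 and abs(c.center[1] - 40) <= 1
        assert abs(c.radius - 10) <= 1
        assert c.support >= 0.9

    def test_two_disjoint_circles(self):
        mask = np.zeros((60, 120), bool)
        for (cr, cc, r) in [(30, 30, 5), (30, 90, 9)]:
            offs = circle_offsets(r)
            mask[offs[:, 0] + cr, offs[:, 1] + cc] = True
        cands = hough_circles(mask, list(range(3, 12)))
        assert len(cands) == 2
        found = sorted(c.radius for c in cands)
        assert abs(found[0] - 5) <= 1 and abs(found[1] - 9) <= 1

    def test_half_circle_support_is_about_half(self):
        full = circle_offsets(8)
        half = full[full[:, 0] <= 0]  # upper half
        mask = np.zeros((40, 40), bool)
        mask[half[:, 0] + 20, half[:, 1] + 20] = True
        cands = hough_circles(mask, [8], support_min=0.3)
        best = max(cands, key=lambda c: c.votes)
        assert best.support == pytest.approx(0.5, abs=0.1)

    def test_accumulator_invariants(self, rng):
        edge = rng.random((30, 30)) < 0.05
        acc = hough_accumulate(edge, [2, 4])
        assert acc.votes.min() >= 0
        assert acc.edge_count == int(edge.sum())
        # each edge pixel casts at most one vote per offset cell per radius
        for i, r in enumerate(acc.radii):
            assert acc.votes[i].sum() <= acc.edge_count * acc.expected_votes[i]


class TestCountMAs:
    def test_unknown_method_rejected(self, default_phantom):
        img, _ = default_phantom
        with pytest.raises(ValueError):
            count_mas(extract_green(img), CAL10, method="ensemble")

    @pytest.mark.parametrize("method", ["morphology", "hough"])
    def test_recovers_planted_count(self, ma15_phantom, method):
        img, truth = ma15_phantom
        cal = PixelCalibration(25.0)
        report = count_mas(extract_green(img), cal, method=method)
        assert abs(report.count - truth.ma_count) <= 2
        assert report.count == len(report.candidates)
        assert report.method == method

    def test_hough_centers_near_planted(self, ma15_phantom):
        img, truth = ma15_phantom
        report = count_mas(extract_green(img), PixelCalibration(25.0), method="hough")
        planted = np.array([(r, c) for r, c, _ in truth.ma_centers])
        hits = 0
        for cand in report.candidates:
            d = np.hypot(planted[:, 0] - cand.center[0],
                         planted[:, 1] - cand.center[1]).min()
            hits += d <= 2.0
        assert hits >= 0.8 * len(report.candidates)

    def test_lesion_free_phantom_is_clean(self):
        from retinoquant import PhantomSpec, make_phantom

        img, _ = make_phantom(PhantomSpec(seed=11, n_mas=0, n_exudates=0))
        green = extract_green(img)
        cal = PixelCalibration(25.0)
        assert count_mas(green, cal, "morphology").count <= 1
        assert count_mas(green, cal, "hough").count <= 1
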