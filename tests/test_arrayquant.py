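"""Array quantification: segmentation, backgrounds, fences, normalization."""

import numpy as np
import pytest

from epifinger import (
    GridNotFoundError,
    GridTransform,
    block_background,
    detect_grid,
    gen_array_image,
    geodesic_segment,
    iqr_filter,
    normalize_and_call,
    segment_spot,
    spot_total,
    transform_centers,
    water_baseline,
)


def reconstruct_oracle(window, seed_thresh, mask_thresh, valid=None):
    """BFS flood fill: components of {window > mask_thresh} that contain a
    pixel > seed_thresh — by definition equal to binary morphological
    reconstruction (4-connected geodesic dilation to fixpoint)."""
    h, w = window.shape
    mask = window > mask_thresh
    if valid is not None:
        mask &= valid
    seeds = (window > seed_thresh) & mask
    out = np.zeros_like(mask)
    stack = list(zip(*np.nonzero(seeds)))
    while stack:
        r, c = stack.pop()
        if out[r, c] or not mask[r, c]:
            continue
        out[r, c] = True
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not out[rr, cc]:
                stack.append((rr, cc))
    return out


class TestGeodesicSegment:
    def test_worked_example_core_ring_detached(self):
        """3x3 core at 250 ringed by 150 on background 10 is reconstructed;
        a detached 150-pixel elsewhere in the window is excluded."""
        win = np.full((11, 11), 10.0)
        win[4:7, 4:7] = 250.0
        win[3, 3:8] = win[7, 3:8] = 150.0
        win[3:8, 3] = win[3:8, 7] = 150.0
        win[0, 0] = 150.0  # detached, above mask but no seed connection
        seg = geodesic_segment(win, seed_thresh=200, mask_thresh=100)
        assert seg[4:7, 4:7].all()
        assert not seg[0, 0]
        np.testing.assert_array_equal(
            seg, reconstruct_oracle(win, 200, 100)
        )

    def test_uniform_below_mask_is_empty(self):
        win = np.full((9, 9), 5.0)
        seg = geodesic_segment(win, 200, 100)
        assert not seg.any()

    def test_equal_thresholds_degenerate_to_components(self):
        rng = np.random.default_rng(0)
        win = rng.uniform(0, 300, size=(16, 16))
        seg = geodesic_segment(win, 150, 150)
        np.testing.assert_array_equal(seg, reconstruct_oracle(win, 150, 150))

    def test_mask_above_seed_rejected(self):
        with pytest.raises(ValueError):
            geodesic_segment(np.zeros((4, 4)), 10, 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            win = rng.uniform(0, 255, size=(32, 32))
            mt = float(rng.uniform(40, 180))
            st = mt + float(rng.uniform(0, 60))
            np.testing.assert_array_equal(
                geodesic_segment(win, st, mt), reconstruct_oracle(win, st, mt)
            )

    def test_matches_skimage_reconstruction(self):
        """Cross-check against the reference grayscale reconstruction."""
        from skimage.morphology import reconstruction

        rng = np.random.default_rng(3)
        for _ in range(20):
            win = rng.uniform(0, 255, size=(24, 24))
            mt = float(rng.uniform(40, 160))
            st = mt + float(rng.uniform(0, 60))
            mask = (win > mt).astype(float)
            seeds = ((win > st) & (win > mt)).astype(float)
            ref = reconstruction(seeds, mask, method="dilation",
                                 footprint=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            np.testing.assert_array_equal(geodesic_segment(win, st, mt), ref > 0.5)


class TestSpotTotal:
    def test_arithmetic(self):
        img2 = np.full((6, 6), 0.0)
        img2[2:4, 2:4] = 100.0
        mask2 = segment_spot(img2, (2.5, 2.5), 2.5, seed_thresh=50, mask_thresh=50)
        m = spot_total(img2, mask2, bg_median=10.0)
        assert m.n_pixels == 4
        assert m.corrected_total == pytest.approx(4 * (100 - 10))

    def test_empty_mask_flagged_zero(self):
        img = np.zeros((8, 8))
        mask = segment_spot(img, (4, 4), 3, 100, 50)
        m = spot_total(img, mask, bg_median=5.0)
        assert m.empty_segment and m.corrected_total == 0.0

    def test_negative_sum_clamped(self):
        img = np.full((8, 8), 20.0)
        mask = segment_spot(img, (4, 4), 3, 10, 10)
        m = spot_total(img, mask, bg_median=50.0)
        assert m.corrected_total == 0.0 and m.clamped


class TestBlockBackground:
    def test_uniform_background(self, small_layout):
        inten = {s: 5000.0 for s in {"water", *small_layout.replicate_groups()}}
        img, truth = gen_array_image(
            small_layout, inten, seed=2, noise_sd=0.0, outlier_fraction=0.0,
            background_levels={1: 10, 2: 10},
        )
        med, sd = block_background(img, small_layout, 1, GridTransform())
        assert med == 10.0 and sd == 0.0

    def test_median_excludes_bright_spots(self, small_layout):
        groups = {"water", *small_layout.replicate_groups()}
        for level in (500.0, 50000.0):
            inten = {s: level for s in groups}
            img, _ = gen_array_image(
                small_layout, inten, seed=2, noise_sd=0.0, outlier_fraction=0.0,
                background_levels={1: 10, 2: 10},
            )
            med, _ = block_background(img, small_layout, 1, GridTransform())
            assert med == 10.0

    def test_two_level_background_median_interpolates(self):
        """Median convention: mean of the central pair on an even count."""
        vals = np.array([10.0] * 5 + [20.0] * 5)
        assert float(np.median(vals)) == 15.0  # convention used by the block op


class TestIQRFilter:
    def test_all_equal_retained(self):
        assert iqr_filter([100, 100, 100, 100]) == [100, 100, 100, 100]

    def test_worked_quartile_case(self):
        """(98,100,102,500): Q1=99.5, Q3=201.5, IQR=102 -> 500 excluded."""
        assert sorted(iqr_filter([98, 100, 102, 500])) == [98, 100, 102]

    def test_extreme_outlier_excluded(self):
        assert sorted(iqr_filter([0, 0, 0, 1_000_000])) == [0, 0, 0]

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1, 2, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_quartile_oracle(self, seed):
        """Direct fence computation with the explicit n=4 interpolation
        formula (positions 1+0.25*(n-1) and 1+0.75*(n-1))."""
        rng = np.random.default_rng(seed)
        for _ in range(500):
            v = rng.integers(0, 50, size=4).astype(float)  # ints force ties
            s = np.sort(v)
            q1 = s[0] + 0.75 * (s[1] - s[0])
            q3 = s[2] + 0.25 * (s[3] - s[2])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            want = sorted(x for x in v if lo <= x <= hi)
            assert sorted(iqr_filter(v)) == want


class TestNormalizeAndCall:
    def test_fold_arithmetic(self):
        s = normalize_and_call([150, 150, 150], 50.0)
        assert s.adjusted == pytest.approx(3.0) and s.positive

    def test_equal_to_water_not_positive(self):
        s = normalize_and_call([50, 50], 50.0, pos_fold=2.0)
        assert s.adjusted == pytest.approx(1.0) and not s.positive

    def test_invalid_water_baseline(self):
        with pytest.raises(ValueError, match="water"):
            normalize_and_call([10], 0.0)
        with pytest.raises(ValueError, match="water"):
            water_baseline([])


class TestDetectGrid:
    def _image(self, small_layout, transform, seed=11, noise=0.0):
        inten = {s: 20000.0 for s in {"water", *small_layout.replicate_groups()}}
        img, _ = gen_array_image(
            small_layout, inten, seed=seed, transform=transform,
            noise_sd=noise, outlier_fraction=0.0,
        )
        return img

    def test_identity_recovered(self, small_layout):
        img = self._image(small_layout, GridTransform())
        tr = detect_grid(img, small_layout)
        assert abs(tr.rotation) <= 0.1
        assert abs(tr.dx) <= 0.5 and abs(tr.dy) <= 0.5

    def test_rotation_and_shift_recovered(self, small_layout):
        truth = GridTransform(0.5, 3.0, -2.0)
        img = self._image(small_layout, truth)
        tr = detect_grid(img, small_layout)
        assert abs(tr.rotation - 0.5) <= 0.1
        assert abs(tr.dx - 3.0) <= 0.5 and abs(tr.dy + 2.0) <= 0.5

    def test_blank_image_not_found(self, small_layout):
        rng = np.random.default_rng(0)
        blank = np.clip(
            np.rint(rng.normal(300, 10, size=(170, 430))), 0, 65535
        ).astype(np.uint16)
        with pytest.raises(GridNotFoundError):
            detect_grid(blank, small_layout)

    def test_transform_centers_roundtrip(self, small_layout):
        tr = GridTransform(1.0, 2.5, -3.5)
        inv_pts = transform_centers(small_layout.centers(), tr, (200, 400))
        assert inv_pts.shape == small_layout.centers().shape
        # identity transform is a no-op
        same = transform_centers(small_layout.centers(), GridTransform(), (200, 400))
        np.testing.assert_allclose(same, small_layout.centers())
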