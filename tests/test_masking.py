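"""Mask construction: thresholds, tissue/RBC/marker masks, size filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import label, regionprops

from pimoquant import masking, synth
from pimoquant.types import BinaryMask, ChannelImage, ThresholdPolicy

from conftest import channel, disk_mask, mask


class TestComputeThreshold:
    def test_fixed_returns_value_verbatim(self):
        img = channel(np.random.default_rng(0).uniform(0, 500, (32, 32)))
        assert masking.compute_threshold(img, ThresholdPolicy("fixed", 100.0)) == 100.0

    def test_otsu_splits_two_level_image(self):
        """Otsu lands strictly between the two modes; oracle is an
        exhaustive scan of between-class variance over candidate cutoffs."""
        px = np.full((20, 20), 10.0)
        px[:, 10:] = 200.0
        thr = masking.compute_threshold(channel(px), ThresholdPolicy("otsu"))
        assert 10.0 < thr < 200.0
        # exhaustive oracle: between-class variance is maximal for any cutoff
        # separating the levels, and zero for cutoffs outside (10, 200]
        vals = px.ravel()

        def between_var(t):
            lo, hi = vals[vals < t], vals[vals >= t]
            if len(lo) == 0 or len(hi) == 0:
                return 0.0
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2
        candidates = np.linspace(1, 250, 500)
        best = candidates[np.argmax([between_var(t) for t in candidates])]
        assert 10.0 < best <= 200.0
        assert between_var(thr) == pytest.approx(between_var(best))

    def test_quantile_median_matches_sort_oracle(self):
        px = np.arange(1.0, 101.0).reshape(10, 10)
        thr = masking.compute_threshold(channel(px), ThresholdPolicy("quantile", 0.5))
        assert thr == pytest.approx(np.sort(px.ravel())[[49, 50]].mean())

    def test_constant_image_otsu_returns_constant(self):
        img = channel(np.full((8, 8), 42.0))
        thr = masking.compute_threshold(img, ThresholdPolicy("otsu"))
        assert thr == 42.0
        # >= convention: the resulting mask is full, not undefined
        assert (img.pixels >= thr).all()

    @pytest.mark.parametrize(
        "method,value",
        [("fixed", None), ("fixed", -1.0), ("quantile", 0.0), ("quantile", 1.5), ("bogus", 1.0)],
    )
    def test_invalid_policies_rejected(self, method, value):
        with pytest.raises(ValueError):
            ThresholdPolicy(method, value)


class TestTissueMask:
    def test_uniform_bright_no_erosion_gives_full_frame(self):
        m = masking.tissue_mask(channel(np.full((30, 30), 200.0)), ThresholdPolicy("fixed", 50.0), erosion_px=0)
        assert m.pixels.all()

    def test_disk_eroded_to_analytic_area(self):
        """A 50 px bright disk eroded by 10 px shrinks to ~ a 40 px disk."""
        px = np.where(disk_mask((128, 128), (64, 64), 50), 200.0, 0.0)
        m = masking.tissue_mask(channel(px), ThresholdPolicy("fixed", 100.0), erosion_px=10)
        assert m.area_px == pytest.approx(np.pi * 40**2, rel=0.05)

    def test_all_dark_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            m = masking.tissue_mask(channel(np.zeros((16, 16))), ThresholdPolicy("fixed", 10.0))
        assert m.area_px == 0

    def test_holes_filled_before_erosion(self):
        """A DAPI-dark necrotic core inside tissue is still tumor area."""
        px = np.full((100, 100), 200.0)
        px[40:60, 40:60] = 0.0
        m = masking.tissue_mask(channel(px), ThresholdPolicy("fixed", 100.0), erosion_px=0)
        assert m.pixels[50, 50]


class TestRbcMask:
    def test_speckle_count_matches_ground_truth(self):
        spec = synth.SectionSpec(seed=0)
        ch, gt = synth.generate_section(spec)
        tissue = masking.tissue_mask(ch["nuclear"], ThresholdPolicy("fixed", 50.0), erosion_px=10)
        rbc = masking.rbc_mask(ch["nuclear"], ThresholdPolicy("fixed", 600.0), tissue)
        assert label(rbc.pixels, connectivity=2).max() == spec.n_rbc
        assert label(gt.rbc_mask.pixels, connectivity=2).max() == spec.n_rbc

    def test_no_pixels_above_cutoff_gives_empty_mask(self):
        img = channel(np.full((16, 16), 100.0))
        tissue = masking.tissue_mask(img, ThresholdPolicy("fixed", 50.0), erosion_px=0)
        rbc = masking.rbc_mask(img, ThresholdPolicy("fixed", 500.0), tissue)
        assert rbc.area_px == 0

    def test_speckle_outside_tissue_excluded(self):
        px = np.zeros((64, 64))
        px[8:40, 8:40] = 100.0  # tissue block
        px[50, 50] = 1000.0  # bright speckle outside tissue
        img = channel(px)
        # edge erosion removes the isolated super-threshold speckle from
        # the tissue mask, leaving it genuinely outside tissue
        tissue = masking.tissue_mask(img, ThresholdPolicy("fixed", 50.0), erosion_px=2)
        assert not tissue.pixels[50, 50]
        rbc = masking.rbc_mask(img, ThresholdPolicy("fixed", 500.0), tissue)
        assert not rbc.pixels[50, 50]
        assert rbc.area_px == 0

    def test_cutoff_not_above_tissue_threshold_rejected(self):
        img = channel(np.full((16, 16), 100.0))
        tissue = masking.tissue_mask(img, ThresholdPolicy("fixed", 50.0), erosion_px=0)
        with pytest.raises(ValueError, match="exceed"):
            masking.rbc_mask(img, ThresholdPolicy("fixed", 40.0), tissue)


class TestMarkerMaskSizeFilter:
    def _tissue(self, shape):
        return mask(np.ones(shape, dtype=bool))

    def test_small_square_removed(self):
        """A 10 um x 10 um blob is below the 30 um floor."""
        px = np.zeros((100, 100))
        px[10:20, 10:20] = 500.0
        m = masking.marker_mask(channel(px), ThresholdPolicy("fixed", 100.0), self._tissue((100, 100)))
        assert m.area_px == 0

    def test_large_disk_retained(self):
        px = np.where(disk_mask((100, 100), (50, 50), 30), 500.0, 0.0)
        m = masking.marker_mask(channel(px), ThresholdPolicy("fixed", 100.0), self._tissue((100, 100)))
        assert m.area_px > 0
        rp = regionprops(label(m.pixels))[0]
        assert rp.equivalent_diameter_area > 30.0

    def test_mixed_components_filtered_componentwise(self):
        px = np.zeros((200, 200))
        px[disk_mask((200, 200), (50, 50), 10)] = 500.0  # 20 um diameter: goes
        px[disk_mask((200, 200), (140, 140), 30)] = 500.0  # 60 um diameter: stays
        m = masking.marker_mask(channel(px), ThresholdPolicy("fixed", 100.0), self._tissue((200, 200)))
        assert not m.pixels[50, 50]
        assert m.pixels[140, 140]
        assert label(m.pixels, connectivity=2).max() == 1

    def test_every_survivor_exceeds_floor_by_independent_remeasure(self):
        """Brute-force re-measurement of every component of a random mask:
        survivors have equivalent diameter > floor, casualties <= floor."""
        rng = np.random.default_rng(5)
        raw = rng.random((150, 150)) > 0.72
        px = np.where(raw, 500.0, 0.0)
        img = channel(px, px_um=2.0)  # 2 um pixels: floor is 15 px diameter
        tissue = mask(np.ones((150, 150), dtype=bool), px_um=2.0)
        m = masking.marker_mask(img, ThresholdPolicy("fixed", 100.0), tissue, min_size_um=30.0)
        lab = label(raw, connectivity=2)
        for rp in regionprops(lab):
            surviving = m.pixels[lab == rp.label].any()
            diam_um = rp.equivalent_diameter_area * 2.0
            assert surviving == (diam_um > 30.0)

    def test_area_interpretation_selectable(self):
        px = np.zeros((50, 50))
        px[10:17, 10:17] = 500.0  # 49 um^2 component
        img = channel(px)
        tissue = mask(np.ones((50, 50), dtype=bool))
        by_area = masking.marker_mask(
            img, ThresholdPolicy("fixed", 100.0), tissue, min_size_um=30.0, size_measure="area"
        )
        by_diam = masking.marker_mask(
            img, ThresholdPolicy("fixed", 100.0), tissue, min_size_um=30.0
        )
        assert by_area.area_px == 49  # 49 um^2 > 30 um^2
        assert by_diam.area_px == 0  # equivalent diameter ~7.9 um <= 30 um


class TestSubtract:
    def test_identity_and_annihilation(self):
        a = mask(np.eye(8, dtype=bool))
        empty = mask(np.zeros((8, 8), dtype=bool))
        assert np.array_equal(masking.subtract(a, empty).pixels, a.pixels)
        assert masking.subtract(a, a).area_px == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masking.subtract(mask(np.ones((4, 4), dtype=bool)), mask(np.ones((5, 5), dtype=bool)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_pixel_count_arithmetic(self, seed):
        """|a - b| = |a| - |a AND b| for any pair of masks."""
        rng = np.random.default_rng(seed)
        a = mask(rng.random((20, 20)) > 0.5)
        b = mask(rng.random((20, 20)) > 0.5)
        inter = int((a.pixels & b.pixels).sum())
        assert masking.subtract(a, b).area_px == a.area_px - inter


class TestPimoSeedMask:
    def test_threshold_above_max_gives_empty_seed(self):
        img = channel(np.full((32, 32), 100.0), label="pimo")
        tissue = mask(np.ones((32, 32), dtype=bool))
        rbc = mask(np.zeros((32, 32), dtype=bool))
        assert masking.pimo_seed_mask(img, 1e6, tissue, rbc).area_px == 0

    def test_noiseless_seed_recovers_pocket_area(self):
        """Midway threshold between background and plateau recovers the
        ground-truth pocket area within 5% on a sharp-edged section."""
        spec = synth.SectionSpec(noise_sd=0.0, gradient_halfwidth_um=0.5, seed=2)
        ch, gt = synth.generate_section(spec)
        midway = spec.background_mean * (1 + spec.pimo_fold) / 2
        tissue = masking.tissue_mask(ch["nuclear"], ThresholdPolicy("fixed", 50.0), erosion_px=10)
        rbc = masking.rbc_mask(ch["nuclear"], ThresholdPolicy("fixed", 600.0), tissue)
        seed = masking.pimo_seed_mask(ch["pimo"], midway, tissue, rbc)
        assert seed.area_px == pytest.approx(gt.pimo_mask.area_px, rel=0.05)

    def test_rbc_pixels_inside_pocket_are_excluded(self):
        px = np.full((100, 100), 100.0)
        px[disk_mask((100, 100), (50, 50), 30)] = 500.0
        tissue = mask(np.ones((100, 100), dtype=bool))
        rbc_arr = disk_mask((100, 100), (50, 50), 4)
        rbc = BinaryMask(rbc_arr, 1.0)
        seed = masking.pimo_seed_mask(channel(px, label="pimo"), 300.0, tissue, rbc)
        assert not (seed.pixels & rbc_arr).any()
        assert seed.area_px > 0
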