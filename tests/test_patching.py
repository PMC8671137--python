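"""Patch extraction: tissue masking, spaced center sampling, co-registered
multi-scale crops, labelling rules, stain normalization, manifests."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from noisypath.patching import (
    AnnotationSet,
    ColorStats,
    SlideImage,
    assign_label,
    build_manifest,
    compute_color_stats,
    compute_tissue_mask,
    crop_multiscale,
    extract_patch_array,
    sample_centers,
    stain_normalize,
)


def _uniform_slide(value=128, side=256, base=20.0):
    img = np.full((side, side, 3), value, dtype=np.uint8)
    return SlideImage(img, base_magnification=base, slide_id="u")


class TestTissueMask:
    def test_all_white_empty(self):
        assert not compute_tissue_mask(_uniform_slide(250)).any()

    def test_all_textured_full(self):
        assert compute_tissue_mask(_uniform_slide(120)).all()

    def test_half_and_half_fraction(self, rng):
        img = np.full((200, 200, 3), 250, dtype=np.uint8)
        img[:, :100] = rng.integers(80, 160, size=(200, 100, 3), dtype=np.uint8)
        frac = compute_tissue_mask(SlideImage(img)).mean()
        assert frac == pytest.approx(0.5, abs=0.02)


class TestSampleCenters:
    def test_single_center_on_tissue(self, phantom_as_slide, phantom_slide):
        pts = sample_centers(phantom_as_slide, phantom_slide.tissue_region, 1, 10.0, seed=0)
        assert pts.shape == (1, 2)
        x, y = pts[0]
        assert phantom_slide.tissue_region[y, x]

    def test_huge_min_distance_forces_single_center(self, phantom_as_slide, phantom_slide):
        pts = sample_centers(phantom_as_slide, phantom_slide.tissue_region, 50, 10_000.0, seed=0)
        assert len(pts) == 1

    def test_min_distance_respected_exhaustively(self):
        slide = _uniform_slide(120, side=1000)
        mask = np.ones((1000, 1000), dtype=bool)
        pts = sample_centers(slide, mask, 100, 50.0, seed=3)
        assert len(pts) == 100
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, 10**9)
        assert d2.min() >= 50.0**2

    @pytest.mark.parametrize("seed", range(20))
    def test_min_distance_property_over_seeds(self, seed):
        slide = _uniform_slide(120, side=256)
        mask = np.ones((256, 256), dtype=bool)
        pts = sample_centers(slide, mask, 40, 30.0, seed=seed)
        if len(pts) > 1:
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, 10**9)
            assert d2.min() >= 30.0**2

    def test_empty_mask_warns_and_returns_empty(self):
        slide = _uniform_slide(250)
        with pytest.warns(UserWarning):
            pts = sample_centers(slide, np.zeros((256, 256), bool), 5, 1.0, seed=0)
        assert len(pts) == 0


class TestCropMultiscale:
    def test_native_magnification_is_identity(self, rng):
        img = rng.integers(0, 255, size=(256, 256, 3), dtype=np.uint8)
        slide = SlideImage(img, base_magnification=20.0)
        group = crop_multiscale(slide, (128, 128), (20.0,), out_size=64)
        np.testing.assert_array_equal(group.crops[20.0], img[96:160, 96:160])

    def test_native_window_arithmetic(self):
        # base x40, target x20, out 448 -> native window 896 before resize
        slide = SlideImage(np.zeros((2048, 2048, 3), np.uint8), base_magnification=40.0)
        group = crop_multiscale(slide, (1024, 1024), (20.0,), out_size=448)
        assert group.crops[20.0].shape == (448, 448, 3)

    def test_three_scales_coregistered(self, phantom_as_slide):
        """The center pixel of every crop maps to the same source location."""
        cx, cy = 131, 117
        marked = phantom_as_slide.image.copy()
        marked[cy - 2 : cy + 3, cx - 2 : cx + 3] = (255, 0, 0)
        slide = SlideImage(marked, 20.0, "m")
        group = crop_multiscale(slide, (cx, cy), (5.0, 20.0, 50.0), out_size=64)
        assert set(group.crops) == {5.0, 20.0, 50.0}
        for m, crop in group.crops.items():
            assert crop.shape == (64, 64, 3)
            # red marker dominates near the crop center at every scale
            c = crop[30:34, 30:34].astype(int)
            assert (c[..., 0] - c[..., 1]).max() > 30

    def test_scale_ordering_native_coverage(self):
        slide = _uniform_slide()
        for m_small, m_large in [(5.0, 20.0), (20.0, 50.0)]:
            side_small = 64 * 20.0 / m_small
            side_large = 64 * 20.0 / m_large
            assert side_small > side_large

    def test_center_off_slide_errors(self, phantom_as_slide):
        with pytest.raises(ValueError):
            crop_multiscale(phantom_as_slide, (-5, 10), (20.0,), 64)

    def test_out_of_bounds_padded_white(self):
        slide = _uniform_slide(100)
        group = crop_multiscale(slide, (0, 0), (20.0,), out_size=64)
        crop = group.crops[20.0]
        assert (crop[0, 0] == 245).all()  # padded corner
        assert (crop[-1, -1] == 100).all()  # real content


class TestAssignLabel:
    square = AnnotationSet([Polygon([(10, 10), (50, 10), (50, 50), (10, 50)])])

    def test_inside(self):
        assert assign_label((30, 30), self.square) == 1

    def test_outside(self):
        assert assign_label((80, 80), self.square) == 0

    def test_boundary_counts_as_inside(self):
        assert assign_label((10, 30), self.square) == 1

    def test_empty_annotation_defaults_zero(self):
        assert assign_label((0, 0), AnnotationSet([])) == 0

    def test_overlap_rule(self):
        assert assign_label((30, 30), self.square, rule="overlap", footprint_side=10) == 1
        assert assign_label((52, 30), self.square, rule="overlap", footprint_side=10) == 0


class TestStainNormalize:
    def test_identity_method(self, rng):
        patch = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        assert stain_normalize(patch, method="identity") is patch

    def test_fixed_point(self, rng):
        patch = rng.integers(60, 200, (64, 64, 3), dtype=np.uint8)
        ref = compute_color_stats(patch)
        out = stain_normalize(patch, ref)
        assert int(np.max(np.abs(out.astype(int) - patch.astype(int)))) <= 2

    def test_matches_reference_statistics(self, rng):
        patch = rng.integers(60, 200, (64, 64, 3), dtype=np.uint8)
        shifted = np.clip(patch.astype(int) + 30, 0, 255).astype(np.uint8)
        ref = compute_color_stats(patch)
        out = stain_normalize(shifted, ref)
        got = compute_color_stats(out)
        np.testing.assert_allclose(got.means, ref.means, atol=1.0)

    def test_degenerate_patch_warns(self):
        flat = np.full((16, 16, 3), 100, dtype=np.uint8)
        ref = ColorStats(np.array([50.0, 0.0, 0.0]), np.array([10.0, 5.0, 5.0]))
        with pytest.warns(UserWarning):
            out = stain_normalize(flat, ref)
        np.testing.assert_array_equal(out, flat)


class TestManifest:
    def _cohort(self, phantom_as_slide, phantom_annotations):
        rough, _ = phantom_annotations
        return [(phantom_as_slide, rough)]

    def test_row_count(self, phantom_as_slide, phantom_annotations):
        m = build_manifest(
            self._cohort(phantom_as_slide, phantom_annotations),
            n_centers=10,
            min_distance=8.0,
            seed=0,
        )
        assert len(m) == 30  # 10 centers x 3 magnifications

    def test_deterministic(self, phantom_as_slide, phantom_annotations):
        kw = dict(n_centers=12, min_distance=8.0, seed=5)
        a = build_manifest(self._cohort(phantom_as_slide, phantom_annotations), **kw)
        b = build_manifest(self._cohort(phantom_as_slide, phantom_annotations), **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_unique_keys_and_shared_group_label(self, phantom_as_slide, phantom_annotations):
        m = build_manifest(
            self._cohort(phantom_as_slide, phantom_annotations), n_centers=15, seed=1
        )
        assert not m.duplicated(["slide_id", "center_x", "center_y", "magnification"]).any()
        per_group = m.groupby(["slide_id", "center_x", "center_y"])["label"].nunique()
        assert (per_group == 1).all()

    def test_extract_patch_array_shape(self, phantom_as_slide, phantom_annotations):
        m = build_manifest(
            self._cohort(phantom_as_slide, phantom_annotations), n_centers=6, seed=2
        )
        x, rows = extract_patch_array(m, {"ph0": phantom_as_slide}, 20.0, 64)
        assert x.shape == (6, 3, 64, 64)
        assert x.dtype == np.float32
        assert 0.0 <= x.min() and x.max() <= 1.0
        assert len(rows) == 6
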