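"""Slide calls, threshold sweeps, heatmaps and metrics against brute-force
oracles and forced boundary cases."""

import numpy as np
import pandas as pd
import pytest

from noisypath import nn
from noisypath.inference import (
    PixelHeatmap,
    classification_metrics,
    classify_slide,
    pixel_accuracy,
    pixel_heatmap,
    predict_slide_patches,
    sweep_ratio_threshold,
)
from noisypath.models import MainModelConfig, build_main_model
from noisypath.patching import SlideImage


class _ConstantModel(nn.Sequential):
    """Stub classifier returning a fixed logit for every patch."""

    def __init__(self, logit: float):
        super().__init__()
        self.logit = logit
        self.input_size = None

    def forward(self, x):
        return np.full((len(x), 1), self.logit, dtype=np.float32)


class TestPredictSlidePatches:
    def test_grid_count_and_determinism(self, phantom_as_slide, phantom_slide):
        model = build_main_model(MainModelConfig(64), seed=0)
        kw = dict(window=64, stride=64, out_size=64, tissue_mask=phantom_slide.tissue_region)
        c1, p1 = predict_slide_patches(model, phantom_as_slide, **kw)
        c2, p2 = predict_slide_patches(model, phantom_as_slide, **kw)
        assert len(c1) == len(p1) > 0
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(p1, p2)
        # exactly the tissue grid points
        on_tissue = phantom_slide.tissue_region[c1[:, 1], c1[:, 0]]
        assert on_tissue.all()

    def test_no_tissue_empty(self):
        slide = SlideImage(np.full((256, 256, 3), 250, np.uint8))
        model = _ConstantModel(0.0)
        centers, probs = predict_slide_patches(
            model, slide, window=64, stride=64, out_size=64
        )
        assert len(centers) == 0 and len(probs) == 0


class TestClassifySlide:
    def test_ratio_above_threshold_is_tumor(self):
        probs = np.array([0.9] * 5 + [0.1] * 95)
        pred = classify_slide(np.zeros((100, 2)), probs, ratio_threshold=0.04)
        assert pred.cancer_ratio == pytest.approx(0.05)
        assert pred.slide_call == "tumor"

    def test_zero_cancer_calls_non_tumor(self):
        probs = np.full(50, 0.2)
        pred = classify_slide(np.zeros((50, 2)), probs, ratio_threshold=0.01)
        assert pred.slide_call == "non-tumor"

    def test_boundary_ratio_counts_as_tumor(self):
        probs = np.array([0.9] * 4 + [0.1] * 96)
        pred = classify_slide(np.zeros((100, 2)), probs, ratio_threshold=0.04)
        assert pred.cancer_ratio == pytest.approx(0.04)
        assert pred.slide_call == "tumor"

    def test_monotone_in_threshold(self, rng):
        probs = rng.uniform(0, 1, 200)
        calls = [
            classify_slide(np.zeros((200, 2)), probs, ratio_threshold=t).slide_call
            for t in np.linspace(0.01, 0.99, 25)
        ]
        tumor = np.array([c == "tumor" for c in calls])
        assert not np.any(tumor[1:] > tumor[:-1])  # never flips back to tumor

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_slide(np.zeros((0, 2)), np.array([]))


class TestSweep:
    def test_separated_returns_smallest_optimal(self):
        ratios = np.array([0.5, 0.6, 0.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        best, curve = sweep_ratio_threshold(ratios, labels)
        assert best == pytest.approx(0.01)
        assert len(curve) == 50

    def test_matches_exhaustive_scan(self, rng):
        ratios = rng.uniform(0, 0.3, 20)
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        grid = np.round(np.arange(0.0, 0.3, 0.005), 4)
        best, curve = sweep_ratio_threshold(ratios, labels, grid=grid)
        accs = [np.mean((ratios >= t).astype(int) == labels) for t in grid]
        assert best == pytest.approx(grid[int(np.argmax(accs))])
        np.testing.assert_allclose(curve["accuracy"].to_numpy(), accs)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            sweep_ratio_threshold(np.array([0.1, 0.2]), np.array([1, 1]))


class TestPixelHeatmap:
    def test_constant_model_constant_map(self):
        slide = SlideImage(np.full((128, 128, 3), 120, np.uint8))
        hm = pixel_heatmap(_ConstantModel(2.0), slide, window=32, stride=32, out_size=32)
        covered = hm.coverage > 0
        expected = float(nn.sigmoid(2.0))
        np.testing.assert_allclose(hm.values[covered], expected, atol=1e-6)

    def test_nonoverlapping_equals_tiled_probabilities(self):
        rng = np.random.default_rng(2)
        img = rng.integers(60, 200, (128, 128, 3), dtype=np.uint8)
        slide = SlideImage(img)
        model = build_main_model(MainModelConfig(32), seed=1)
        hm = pixel_heatmap(model, slide, window=32, stride=32, out_size=32)
        centers, probs = predict_slide_patches(
            model, slide, window=32, stride=32, out_size=32,
            tissue_mask=np.ones((128, 128), bool),
        )
        for (cx, cy), p in zip(centers, probs):
            block = hm.values[cy - 16 : cy + 16, cx - 16 : cx + 16]
            np.testing.assert_allclose(block, p, atol=1e-12)

    def test_overlapping_matches_bruteforce_means(self):
        rng = np.random.default_rng(3)
        img = rng.integers(60, 200, (64, 64, 3), dtype=np.uint8)
        slide = SlideImage(img)
        model = build_main_model(MainModelConfig(32), seed=2)
        hm = pixel_heatmap(model, slide, window=32, stride=16, out_size=32)
        centers, probs = predict_slide_patches(
            model, slide, window=32, stride=16, out_size=32,
            tissue_mask=np.ones((64, 64), bool),
        )
        acc = np.zeros((64, 64))
        cov = np.zeros((64, 64))
        for (cx, cy), p in zip(centers, probs):
            y0, x0 = max(cy - 16, 0), max(cx - 16, 0)
            y1, x1 = min(cy + 16, 64), min(cx + 16, 64)
            acc[y0:y1, x0:x1] += p
            cov[y0:y1, x0:x1] += 1
        expected = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
        np.testing.assert_allclose(hm.values, expected, atol=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        img = rng.integers(60, 200, (96, 96, 3), dtype=np.uint8)
        slide = SlideImage(img)
        model = build_main_model(MainModelConfig(32), seed=3)
        hm = pixel_heatmap(model, slide, window=32, stride=16, out_size=32)
        centers, probs = predict_slide_patches(
            model, slide, window=32, stride=16, out_size=32,
            tissue_mask=np.ones((96, 96), bool),
        )
        clipped_areas = []
        for cx, cy in centers:
            y0, x0 = max(cy - 16, 0), max(cx - 16, 0)
            y1, x1 = min(cy + 16, 96), min(cx + 16, 96)
            clipped_areas.append((y1 - y0) * (x1 - x0))
        lhs = float(np.sum(hm.values * hm.coverage))
        rhs = float(np.sum(probs * np.asarray(clipped_areas, dtype=float)))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_stride_exceeding_window_errors(self):
        slide = SlideImage(np.full((64, 64, 3), 120, np.uint8))
        with pytest.raises(ValueError):
            pixel_heatmap(_ConstantModel(0.0), slide, window=16, stride=32)


class TestPixelAccuracy:
    def _hm(self, values, mask):
        return PixelHeatmap(values, np.ones_like(values, int), mask, 2, 2)

    def test_perfect_agreement(self):
        truth = np.zeros((3, 3), bool)
        truth[0] = True
        hm = self._hm(truth.astype(float), np.ones((3, 3), bool))
        assert pixel_accuracy(hm, truth) == 1.0

    def test_inverted_zero(self):
        truth = np.zeros((3, 3), bool)
        truth[0] = True
        hm = self._hm(1.0 - truth.astype(float), np.ones((3, 3), bool))
        assert pixel_accuracy(hm, truth) == 0.0

    def test_one_disagreeing_pixel_of_nine(self):
        truth = np.zeros((3, 3), bool)
        vals = np.zeros((3, 3))
        vals[1, 1] = 1.0
        hm = self._hm(vals, np.ones((3, 3), bool))
        assert pixel_accuracy(hm, truth) == pytest.approx(8 / 9)

    def test_empty_mask_errors(self):
        hm = self._hm(np.zeros((3, 3)), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            pixel_accuracy(hm, np.zeros((3, 3), bool))

    def test_shape_mismatch_errors(self):
        hm = self._hm(np.zeros((3, 3)), np.ones((3, 3), bool))
        with pytest.raises(ValueError):
            pixel_accuracy(hm, np.zeros((4, 4), bool))


class TestMetrics:
    def test_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        m = classification_metrics(p, y)
        assert m == {"accuracy": 1.0, "auc": 1.0, "f1": 1.0}

    def test_f1_formula(self):
        # precision 1, recall 0.5 -> F1 = 2/3
        p = np.array([0.9, 0.1, 0.1, 0.1])
        y = np.array([1, 1, 0, 0])
        m = classification_metrics(p, y)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_auc_matches_pairwise_oracle(self, rng):
        p = rng.uniform(0, 1, 50)
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
        oracle = wins / (len(pos) * len(neg))
        assert classification_metrics(p, y)["auc"] == pytest.approx(oracle, abs=1e-9)

    def test_single_class_auc_missing(self):
        m = classification_metrics(np.array([0.2, 0.6]), np.array([0, 0]))
        assert np.isnan(m["auc"])
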