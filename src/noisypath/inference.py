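"""Slide-level diagnosis and pixel-level heatmaps.

A trained patch classifier is slid over a slide on a regular grid restricted
to tissue. The slide call compares the cancerous-patch ratio (fraction of
patches with probability >= 0.5) against a ratio threshold, default 0.04. The
heatmap assigns each pixel the mean probability of every window containing
it; pixel accuracy compares the thresholded heatmap with the exact annotation
mask over non-blank tissue only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .models import predict_proba
from .patching import SlideImage, compute_tissue_mask, crop_multiscale

__all__ = [
    "SlidePrediction",
    "PixelHeatmap",
    "predict_slide_patches",
    "classify_slide",
    "sweep_ratio_threshold",
    "pixel_heatmap",
    "pixel_accuracy",
    "classification_metrics",
]

DEFAULT_RATIO_THRESHOLD = 0.04


@dataclass
class SlidePrediction:
    slide_id: str
    centers: np.ndarray  # (k, 2)
    probabilities: np.ndarray  # (k,)
    cancer_ratio: float
    slide_call: str  # "tumor" | "non-tumor"
    ratio_threshold: float

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "slide_id": self.slide_id,
                "cancer_ratio": self.cancer_ratio,
                "slide_call": self.slide_call,
                "ratio_threshold": self.ratio_threshold,
                "n_patches": int(len(self.probabilities)),
            },
            indent=2,
        )


@dataclass
class PixelHeatmap:
    values: np.ndarray  # (H, W) float, mean window probability
    coverage: np.ndarray  # (H, W) int, windows covering each pixel
    eval_mask: np.ndarray  # tissue & covered
    window: int
    stride: int


def _grid_centers(
    shape: tuple[int, int], window: int, stride: int, tissue_mask: np.ndarray | None
) -> np.ndarray:
    h, w = shape
    half = window // 2
    ys = np.arange(half, max(h - half + 1, half + 1), stride)
    xs = np.arange(half, max(w - half + 1, half + 1), stride)
    cx, cy = np.meshgrid(xs, ys)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    if tissue_mask is not None:
        on = tissue_mask[centers[:, 1].clip(0, h - 1), centers[:, 0].clip(0, w - 1)]
        centers = centers[on]
    return centers


def predict_slide_patches(
    model: nn.Sequential,
    slide: SlideImage,
    window: int = 64,
    stride: int = 64,
    magnification: float | None = None,
    out_size: int = 64,
    tissue_mask: np.ndarray | None = None,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid predictions on tissue: returns (centers (k,2), probabilities (k,))."""
    magnification = magnification or slide.base_magnification
    if tissue_mask is None:
        tissue_mask = compute_tissue_mask(slide)
    centers = _grid_centers(slide.shape, window, stride, tissue_mask)
    if len(centers) == 0:
        return centers, np.empty(0)
    x = np.empty((len(centers), 3, out_size, out_size), dtype=np.float32)
    for i, (cx, cy) in enumerate(centers):
        group = crop_multiscale(slide, (cx, cy), (magnification,), out_size)
        x[i] = group.crops[magnification].astype(np.float32).transpose(2, 0, 1) / 255.0
    return centers, predict_proba(model, x, batch_size=batch_size)


def classify_slide(
    centers: np.ndarray,
    probabilities: np.ndarray,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    slide_id: str = "slide",
) -> SlidePrediction:
    """Slide call from the cancerous-patch ratio.

    cancer_ratio = #(p >= 0.5) / #patches; the call is tumor iff the ratio is
    greater than or equal to the threshold (boundary counts as tumor).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.size == 0:
        raise ValueError("no patch predictions for slide")
    ratio = float(np.mean(probabilities >= 0.5))
    call = "tumor" if ratio >= ratio_threshold else "non-tumor"
    return SlidePrediction(slide_id, np.asarray(centers), probabilities, ratio, call, ratio_threshold)


def sweep_ratio_threshold(
    cancer_ratios: np.ndarray,
    slide_labels: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Exhaustive accuracy scan over ratio thresholds.

    ``cancer_ratios``: per-slide cancerous-patch ratios; ``slide_labels``:
    true slide classes {0,1}. Returns the threshold maximizing slide-level
    accuracy (ties broken toward the smaller threshold) and the full curve.
    """
    ratios = np.asarray(cancer_ratios, dtype=np.float64)
    labels = np.asarray(slide_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold sweep needs both slide classes")
    if grid is None:
        grid = np.round(np.arange(0.01, 0.51, 0.01), 4)
    accs = np.array([np.mean((ratios >= t).astype(int) == labels) for t in grid])
    best = float(grid[int(np.argmax(accs))])  # argmax takes the first (smallest) maximum
    curve = pd.DataFrame({"threshold": grid, "accuracy": accs})
    return best, curve


def pixel_heatmap(
    model: nn.Sequential,
    slide: SlideImage,
    window: int = 64,
    stride: int = 32,
    magnification: float | None = None,
    out_size: int = 64,
    tissue_mask: np.ndarray | None = None,
) -> PixelHeatmap:
    """Sliding-window mean-probability map.

    Each pixel's value is the mean predicted probability over all windows
    containing it. Blank (non-tissue) areas are excluded from the evaluation
    mask. Windows are placed on the full grid (not only tissue centers) so
    coverage is uniform; with stride == window the map is the tiling of
    per-window probabilities.
    """
    if stride > window:
        raise ValueError("stride must not exceed window")
    if tissue_mask is None:
        tissue_mask = compute_tissue_mask(slide)
    h, w = slide.shape
    centers = _grid_centers(slide.shape, window, stride, tissue_mask=None)
    if len(centers) == 0:  # window larger than slide: single centered window
        centers = np.array([[w // 2, h // 2]])
    magnification = magnification or slide.base_magnification
    x = np.empty((len(centers), 3, out_size, out_size), dtype=np.float32)
    for i, (cx, cy) in enumerate(centers):
        group = crop_multiscale(slide, (cx, cy), (magnification,), out_size)
        x[i] = group.crops[magnification].astype(np.float32).transpose(2, 0, 1) / 255.0
    probs = predict_proba(model, x)

    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int32)
    half = window // 2
    for (cx, cy), p in zip(centers, probs):
        y0, x0 = max(cy - half, 0), max(cx - half, 0)
        y1, x1 = min(cy - half + window, h), min(cx - half + window, w)
        acc[y0:y1, x0:x1] += p
        cov[y0:y1, x0:x1] += 1
    values = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    eval_mask = tissue_mask & (cov > 0)
    return PixelHeatmap(values, cov, eval_mask, window, stride)


def pixel_accuracy(
    heatmap: PixelHeatmap, truth_mask: np.ndarray, prob_cut: float = 0.5
) -> float:
    """Agreement of the thresholded heatmap with the exact tumor mask over
    the evaluation mask (tissue, covered pixels only)."""
    if heatmap.values.shape != truth_mask.shape:
        raise ValueError("heatmap / truth shape mismatch")
    m = heatmap.eval_mask
    if not m.any():
        raise ValueError("empty evaluation mask")
    pred = heatmap.values >= prob_cut
    return float(np.mean(pred[m] == truth_mask.astype(bool)[m]))


def classification_metrics(
    probabilities: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Accuracy, ROC-AUC and F1 (hard calls at 0.5).

    F1 = 2 * precision * recall / (precision + recall). AUC needs both
    classes; with a single class it is reported as nan.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    hard = (p >= 0.5).astype(int)
    acc = float(np.mean(hard == y))
    tp = int(np.sum((hard == 1) & (y == 1)))
    fp = int(np.sum((hard == 1) & (y == 0)))
    fn = int(np.sum((hard == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y)) < 2:
        auc = float("nan")
    else:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(y, p))
    return {"accuracy": acc, "auc": auc, "f1": f1}
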