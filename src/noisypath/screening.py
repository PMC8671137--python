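"""Confidence-based screening of noisy training data.

A preliminary model is trained on the raw (noisy) patch labels; its
confidence in each annotated label then filters the training set, either
patch by patch (drop patches whose predicted value for their annotated label
is below a threshold, default 0.7) or slide by slide (drop every patch of
slides whose per-slide accuracy under the model is below a threshold,
default 0.7). Screening decisions are made at one magnification (the x20
patches by default) and applied to the whole co-registered patch group,
since all crops of a group share one label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .models import MainModelConfig, build_main_model, predict_proba
from .patching import SlideImage, extract_patch_array
from .training import TrainConfig, train_classifier

__all__ = [
    "ScreeningReport",
    "pretrain_screening_model",
    "predicted_value",
    "patch_screen",
    "slide_screen",
    "balance_manifest",
]


@dataclass
class ScreeningReport:
    mode: str  # "patch" | "slide"
    threshold: float
    retained: int
    removed: int
    seed: int = 0
    per_slide_accuracy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)


def pretrain_screening_model(
    manifest: pd.DataFrame,
    slides_by_id: dict[str, SlideImage],
    magnification: float = 20.0,
    out_size: int = 64,
    model_config: MainModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[nn.Sequential, float, pd.DataFrame]:
    """Train the preliminary screening model on the raw noisy labels.

    Returns (model, validation accuracy, history). The validation split is
    treated as curated: its exact labels (``clean_label`` when available) are
    used, mirroring a validation set hand-picked to be correctly labelled.
    """
    train_rows = manifest[(manifest["split"] == "train")]
    if train_rows.empty:
        raise ValueError("train split is empty")
    model_config = model_config or MainModelConfig(input_size=out_size)
    train_config = train_config or TrainConfig(epochs=8, seed=seed)
    x, rows = extract_patch_array(train_rows, slides_by_id, magnification, out_size)
    y = rows["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("screening pretraining needs both classes in the train split")
    val_rows = manifest[manifest["split"] == "val"]
    x_val = y_val = None
    if not val_rows.empty:
        x_val, vrows = extract_patch_array(val_rows, slides_by_id, magnification, out_size)
        col = "clean_label" if "clean_label" in vrows else "label"
        y_val = vrows[col].to_numpy()
    model = build_main_model(model_config, seed=seed)
    model, history, _ = train_classifier(
        model, x, y, train_config, x_val=x_val, y_val=y_val
    )
    val_acc = float(history["val_acc"].max()) if "val_acc" in history else float("nan")
    return model, val_acc, history


def predicted_value(probabilities: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Model confidence in the annotated label: p if label 1 else 1 - p."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    return np.where(y == 1, p, 1.0 - p)


def _screen_probs(
    model: nn.Sequential,
    rows: pd.DataFrame,
    slides_by_id: dict[str, SlideImage],
    magnification: float,
    out_size: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Screening probabilities, averaged over the 8 dihedral views of each
    patch so that confidence reflects content rather than orientation."""
    x, sub = extract_patch_array(rows, slides_by_id, magnification, out_size)
    acc = np.zeros(len(x), dtype=np.float64)
    for k in range(4):
        v = np.rot90(x, k=k, axes=(2, 3))
        acc += predict_proba(model, np.ascontiguousarray(v))
        acc += predict_proba(model, np.ascontiguousarray(v[:, :, :, ::-1]))
    return sub, acc / 8.0


def patch_screen(
    model: nn.Sequential | None,
    manifest: pd.DataFrame,
    slides_by_id: dict[str, SlideImage] | None = None,
    threshold: float = 0.7,
    magnification: float = 20.0,
    out_size: int = 64,
    probabilities: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop train patches whose predicted value is below ``threshold``.

    A patch whose predicted value equals the threshold exactly is retained
    (only values strictly below are filtered). The decision is taken at the
    screening magnification and applied to all magnifications of the same
    center. ``probabilities`` may be supplied directly (aligned with the
    train rows at the screening magnification, in manifest order) in place
    of a model.
    """
    train = manifest[manifest["split"] == "train"]
    rows = train[train["magnification"] == magnification].reset_index(drop=True)
    if probabilities is None:
        rows, probabilities = _screen_probs(model, rows, slides_by_id, magnification, out_size)
    pv = predicted_value(probabilities, rows["label"].to_numpy())
    keep = pv >= threshold
    keep_keys = set(
        zip(rows.loc[keep, "slide_id"], rows.loc[keep, "center_x"], rows.loc[keep, "center_y"])
    )

    def group_kept(r) -> bool:
        return (r["slide_id"], r["center_x"], r["center_y"]) in keep_keys

    is_train = manifest["split"] == "train"
    kept_mask = manifest.apply(group_kept, axis=1) | ~is_train
    out = manifest[kept_mask].copy()
    out.loc[out["split"] == "train", "screening_status"] = "retained"
    n_groups = len(rows)
    report = ScreeningReport(
        mode="patch",
        threshold=threshold,
        retained=int(keep.sum()),
        removed=int(n_groups - keep.sum()),
    )
    return out.reset_index(drop=True), report


def slide_screen(
    model: nn.Sequential | None,
    manifest: pd.DataFrame,
    slides_by_id: dict[str, SlideImage] | None = None,
    acc_threshold: float = 0.7,
    magnification: float = 20.0,
    out_size: int = 64,
    probabilities: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop every patch of train slides whose per-slide accuracy is below
    ``acc_threshold``.

    Per-slide accuracy is the fraction of that slide's patches whose hard
    prediction (p >= 0.5 -> tumor) matches the annotated label; a slide at
    exactly the threshold is retained.
    """
    train = manifest[manifest["split"] == "train"]
    rows = train[train["magnification"] == magnification].reset_index(drop=True)
    if probabilities is None:
        rows, probabilities = _screen_probs(model, rows, slides_by_id, magnification, out_size)
    hard = (np.asarray(probabilities) >= 0.5).astype(int)
    rows = rows.assign(_correct=(hard == rows["label"].to_numpy()).astype(float))
    per_slide = rows.groupby("slide_id")["_correct"].agg(["mean", "count"])
    empty = per_slide[per_slide["count"] == 0]
    if len(empty):
        warnings.warn(f"slides with zero patches skipped: {list(empty.index)}", stacklevel=2)
    keep_slides = set(per_slide.index[per_slide["mean"] >= acc_threshold])
    is_train = manifest["split"] == "train"
    kept_mask = manifest["slide_id"].isin(keep_slides) | ~is_train
    out = manifest[kept_mask].copy().reset_index(drop=True)
    removed = int(len(rows) - rows["slide_id"].isin(keep_slides).sum())
    report = ScreeningReport(
        mode="slide",
        threshold=acc_threshold,
        retained=int(len(rows) - removed),
        removed=removed,
        per_slide_accuracy={k: float(v) for k, v in per_slide["mean"].items()},
    )
    return out, report


def balance_manifest(
    manifest: pd.DataFrame,
    per_class_cap: int = 10**9,
    per_slide_cap: int = 10**9,
    seed: int = 0,
) -> pd.DataFrame:
    """Equalize class counts (and cap per-slide counts) in the train split.

    Operates on patch groups (slide, center) so co-registered crops stay
    together; non-train rows pass through unchanged. Raises if a class is
    absent.
    """
    if per_class_cap < 1 or per_slide_cap < 1:
        raise ValueError("caps must be >= 1")
    rng = np.random.default_rng(seed)
    train = manifest[manifest["split"] == "train"]
    groups = (
        train.groupby(["slide_id", "center_x", "center_y"])
        .agg(label=("label", "first"))
        .reset_index()
    )
    if groups["label"].nunique() < 2:
        raise ValueError("both classes must be present to balance")

    # per-slide cap first
    kept = []
    for _, sub in groups.groupby("slide_id"):
        if len(sub) > per_slide_cap:
            sub = sub.iloc[np.sort(rng.choice(len(sub), per_slide_cap, replace=False))]
        kept.append(sub)
    groups = pd.concat(kept, ignore_index=True)

    # equalize classes
    counts = groups["label"].value_counts()
    target = min(int(counts.min()), per_class_cap)
    parts = []
    for lbl, sub in groups.groupby("label"):
        if len(sub) > target:
            sub = sub.iloc[np.sort(rng.choice(len(sub), target, replace=False))]
        parts.append(sub)
    groups = pd.concat(parts, ignore_index=True)
    keys = set(zip(groups["slide_id"], groups["center_x"], groups["center_y"]))

    is_train = manifest["split"] == "train"
    in_keys = manifest.apply(
        lambda r: (r["slide_id"], r["center_x"], r["center_y"]) in keys, axis=1
    )
    return manifest[in_keys | ~is_train].reset_index(drop=True)
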