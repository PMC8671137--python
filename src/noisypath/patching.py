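"""Multi-scale patch extraction from annotated slides.

Centers are sampled on tissue with a minimum pairwise distance; at each
center, co-registered square patches are cropped at several nominal
magnifications (default x5 / x20 / x50 relative to the scan) and resized to a
common side length. Labels come from the center's position relative to the
annotation polygons. Coordinates are 0-based pixel coordinates at base
magnification, origin top-left, half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, shape as shapely_shape
from shapely.ops import unary_union
from skimage.transform import resize

__all__ = [
    "SlideImage",
    "AnnotationSet",
    "PatchGroup",
    "ColorStats",
    "compute_tissue_mask",
    "sample_centers",
    "crop_multiscale",
    "assign_label",
    "stain_normalize",
    "compute_color_stats",
    "build_manifest",
    "extract_patch_array",
    "read_annotations_geojson",
    "load_slide",
]

BACKGROUND_VALUE = 245  # padding for out-of-bounds crops: background white


@dataclass
class SlideImage:
    """An in-memory slide raster with its nominal scan magnification."""

    image: np.ndarray  # (H, W, 3) uint8
    base_magnification: float = 20.0
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        if self.base_magnification <= 0:
            raise ValueError("base_magnification must be positive")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("slide raster must be (H, W, 3)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class AnnotationSet:
    """Labelled polygons for one slide; ``kind`` is 'rough' or 'elaborate'."""

    polygons: list[Polygon]
    kind: str = "rough"

    _union: object = field(default=None, repr=False, compare=False)

    def union(self):
        if self._union is None:
            self._union = unary_union(self.polygons) if self.polygons else Polygon()
            shapely.prepare(self._union)
        return self._union


@dataclass
class PatchGroup:
    slide_id: str
    center: tuple[float, float]  # (x, y) at base magnification
    crops: dict[float, np.ndarray]  # magnification -> (S, S, 3) uint8
    label: int
    out_size: int = 448


@dataclass
class ColorStats:
    """Per-channel mean/std in LAB space, the stain-normalization reference."""

    means: np.ndarray
    stds: np.ndarray


def load_slide(path, base_magnification: float = 20.0, slide_id: str | None = None) -> SlideImage:
    """Read a PNG/TIFF raster into a SlideImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(np.ascontiguousarray(img[..., :3]), base_magnification, slide_id or path.stem)


def read_annotations_geojson(path, kind: str = "rough") -> AnnotationSet:
    import json

    with open(path) as fh:
        fc = json.load(fh)
    polys = [shapely_shape(f["geometry"]) for f in fc.get("features", [])]
    return AnnotationSet([p for p in polys if isinstance(p, Polygon)], kind=kind)


def compute_tissue_mask(slide: SlideImage, blank_threshold: float = 235.0) -> np.ndarray:
    """Tissue = pixels darker than the blank-background intensity threshold."""
    gray = slide.image.mean(axis=2)
    return gray < blank_threshold


def sample_centers(
    slide: SlideImage,
    tissue_mask: np.ndarray,
    n: int,
    min_distance: float,
    seed: int = 0,
) -> np.ndarray:
    """Seeded greedy dart-throwing: up to ``n`` tissue centers, pairwise
    distances >= ``min_distance``. Returns an (m, 2) array of (x, y)."""
    if min_distance < 0:
        raise ValueError("min_distance must be non-negative")
    rng = np.random.default_rng(seed)
    ys, xs = np.nonzero(tissue_mask)
    if len(ys) == 0:
        warnings.warn("empty tissue mask: no centers sampled", stacklevel=2)
        return np.empty((0, 2), dtype=np.int64)
    order = rng.permutation(len(ys))
    accepted: list[tuple[int, int]] = []
    md2 = min_distance * min_distance
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if accepted:
            arr = np.asarray(accepted)
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if d2.min() < md2:
                continue
        accepted.append((x, y))
        if len(accepted) == n:
            break
    return np.asarray(accepted, dtype=np.int64).reshape(-1, 2)


def _crop_window(image: np.ndarray, cx: float, cy: float, side: int) -> np.ndarray:
    """Half-open window of `side` px centered at (cx, cy), white-padded."""
    h, w = image.shape[:2]
    x0 = int(round(cx)) - side // 2
    y0 = int(round(cy)) - side // 2
    out = np.full((side, side, 3), BACKGROUND_VALUE, dtype=image.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + side, w), min(y0 + side, h)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out


def crop_multiscale(
    slide: SlideImage,
    center: tuple[float, float],
    magnifications: tuple[float, ...] = (5.0, 20.0, 50.0),
    out_size: int = 448,
    label: int = 0,
) -> PatchGroup:
    """Co-registered crops at each magnification, resized to ``out_size``.

    A crop at magnification m covers a native square of side
    out_size * base/m around the center; m above base upsamples.
    """
    if out_size <= 0:
        raise ValueError("out_size must be positive")
    cx, cy = center
    h, w = slide.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {center} off slide of shape {(w, h)}")
    crops: dict[float, np.ndarray] = {}
    for m in magnifications:
        native = int(round(out_size * slide.base_magnification / m))
        window = _crop_window(slide.image, cx, cy, native)
        if native == out_size:
            crops[m] = window
        else:
            resized = resize(
                window.astype(np.float32),
                (out_size, out_size),
                order=1,
                anti_aliasing=native > out_size,
                preserve_range=True,
            )
            crops[m] = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    return PatchGroup(slide.slide_id, (cx, cy), crops, label, out_size)


def assign_label(
    center: tuple[float, float],
    annotations: AnnotationSet,
    rule: str = "center",
    overlap_threshold: float = 0.5,
    footprint_side: float | None = None,
) -> int:
    """Patch label from its position relative to the annotated tumor region.

    'center': 1 iff the center lies inside (or on the boundary of) any tumor
    polygon — scale-invariant default. 'overlap': 1 iff the footprint square
    overlaps tumor by at least ``overlap_threshold``.
    """
    if not annotations.polygons:
        return 0
    geom = annotations.union()
    if rule == "center":
        return int(shapely.intersects_xy(geom, center[0], center[1]))
    if rule == "overlap":
        if footprint_side is None:
            raise ValueError("overlap rule needs footprint_side")
        half = footprint_side / 2
        box = shapely.box(center[0] - half, center[1] - half, center[0] + half, center[1] + half)
        return int(box.intersection(geom).area / box.area >= overlap_threshold)
    raise ValueError(f"unknown label rule {rule!r}")


def compute_color_stats(patch: np.ndarray) -> ColorStats:
    from skimage.color import rgb2lab

    lab = rgb2lab(patch.astype(np.float64) / 255.0)
    return ColorStats(lab.mean(axis=(0, 1)), lab.std(axis=(0, 1)))


def stain_normalize(
    patch: np.ndarray, reference: ColorStats | None = None, method: str = "reinhard"
) -> np.ndarray:
    """Match channel statistics to a reference in LAB space (Reinhard-style).

    ``method='identity'`` passes the patch through unchanged (synthetic mode,
    where appearance is already uniform by construction).
    """
    if method == "identity":
        return patch
    if method != "reinhard":
        raise ValueError(f"unknown stain normalization method {method!r}")
    if reference is None:
        raise ValueError("reinhard normalization needs a reference")
    from skimage.color import lab2rgb, rgb2lab

    lab = rgb2lab(patch.astype(np.float64) / 255.0)
    means = lab.mean(axis=(0, 1))
    stds = lab.std(axis=(0, 1))
    if np.any(stds < 1e-8):
        warnings.warn("degenerate (zero-variance) patch left unnormalized", stacklevel=2)
        return patch
    lab = (lab - means) / stds * reference.stds + reference.means
    rgb = lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def build_manifest(
    slides: list[tuple[SlideImage, AnnotationSet]],
    n_centers: int = 100,
    min_distance: float = 32.0,
    magnifications: tuple[float, ...] = (5.0, 20.0, 50.0),
    out_size: int = 448,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    blank_threshold: float = 235.0,
    seed: int = 0,
    clean_annotations: list[AnnotationSet] | None = None,
) -> pd.DataFrame:
    """Sample centers on every slide and index all patches as a manifest.

    One row per (slide, center, magnification); the label is derived from the
    training (rough) annotation. When a clean annotation set is supplied
    (phantom cohorts), a ``clean_label`` column records the exact label for
    evaluation. Splits are assigned per slide so patches of one slide never
    straddle splits.
    """
    if not slides:
        raise ValueError("need at least one slide")
    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    n_slides = len(slides)
    # stratify the slide-level split by annotation presence so every split
    # sees both tumor-bearing and tumor-free slides where possible
    strata: dict[bool, list[int]] = {}
    for si, (_, ann) in enumerate(slides):
        strata.setdefault(bool(ann.polygons), []).append(si)
    splits: dict[int, str] = {}
    for members in strata.values():
        order = split_rng.permutation(len(members))
        k = len(members)
        n_train = max(int(round(split_fractions[0] * k)), 1)
        n_val = max(int(round(split_fractions[1] * k)), 1) if k > 2 else 0
        for rank, oi in enumerate(order):
            si = members[oi]
            if rank < n_train:
                splits[si] = "train"
            elif rank < n_train + n_val:
                splits[si] = "val"
            else:
                splits[si] = "test"

    rows = []
    center_seeds = ss.generate_state(n_slides + 1)[1:] % (2**31)
    for si, (slide, ann) in enumerate(slides):
        mask = compute_tissue_mask(slide, blank_threshold)
        centers = sample_centers(slide, mask, n_centers, min_distance, seed=int(center_seeds[si]))
        clean = clean_annotations[si] if clean_annotations is not None else None
        for cx, cy in centers:
            label = assign_label((cx, cy), ann)
            clean_label = assign_label((cx, cy), clean) if clean is not None else label
            for m in magnifications:
                rows.append(
                    {
                        "slide_id": slide.slide_id,
                        "center_x": int(cx),
                        "center_y": int(cy),
                        "magnification": float(m),
                        "label": label,
                        "clean_label": clean_label,
                        "split": splits[si],
                        "screening_status": "retained",
                        "path": "",
                    }
                )
    manifest = pd.DataFrame(rows)
    if len(manifest):
        dup = manifest.duplicated(["slide_id", "center_x", "center_y", "magnification"])
        manifest = manifest[~dup].reset_index(drop=True)
    return manifest


def extract_patch_array(
    manifest: pd.DataFrame,
    slides_by_id: dict[str, SlideImage],
    magnification: float,
    out_size: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Materialize all manifest rows at one magnification as model input.

    Returns (X, rows): X is (N, 3, S, S) float32 in [0, 1] in NCHW order,
    rows the matching manifest subset (index reset, aligned with X).
    """
    rows = manifest[manifest["magnification"] == magnification].reset_index(drop=True)
    xs = np.empty((len(rows), 3, out_size, out_size), dtype=np.float32)
    for i, row in rows.iterrows():
        slide = slides_by_id[row["slide_id"]]
        group = crop_multiscale(
            slide, (row["center_x"], row["center_y"]), (magnification,), out_size
        )
        patch = group.crops[magnification].astype(np.float32) / 255.0
        xs[i] = patch.transpose(2, 0, 1)
    return xs, rows
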