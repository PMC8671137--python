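"""Synthetic slide phantoms with controllable annotation noise.

A phantom emulates the data regime of tumor-region classification on roughly
annotated whole-slide images: a tissue ellipse on a blank background, blobby
tumor regions with non-tumor inclusions (stroma, vessels) inside them, and
small scattered tumor foci outside the main regions. Two annotation sets are
produced per slide:

* the *elaborate* annotation — exact tumor outlines: the main blobs with
  inclusion holes, plus the scattered foci; it agrees with the per-pixel
  ground-truth mask;
* the *rough* annotation — what a pathologist outlining quickly would draw:
  hole-free, dilated main blobs that swallow the inclusions and miss the
  scattered foci.

Patches labelled from the rough annotation therefore carry label noise whose
rate is controlled by ``inclusion_rate``, ``scatter_rate`` and
``dilation_radius_px`` and can be measured directly with
:func:`measure_noise_rate`.

Textures are stationary band-limited noise fields with class-specific color
statistics and nuclear spot density. The red channel mean is shared across all
tissue classes, so a classifier cannot succeed by mean color alone; spot
density and grain scale carry most of the class signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union
from skimage.draw import disk as draw_disk

__all__ = [
    "ClassTexture",
    "PhantomSpec",
    "PhantomSlide",
    "generate_phantom",
    "roughen_annotation",
    "measure_noise_rate",
    "generate_cohort",
    "rasterize_polygons",
    "save_phantom",
    "default_texture_params",
]


@dataclass
class ClassTexture:
    """Appearance of one tissue class: base color + grain + nuclear spots."""

    base_rgb: tuple[float, float, float]
    contrast: tuple[float, float, float] = (0.06, 0.06, 0.06)
    grain_sigma: float = 2.0
    spot_density: float = 0.0  # expected spots per pixel
    spot_radius: float = 2.0
    spot_darkness: float = 0.35
    streak: float = 1.0  # >1 stretches grain horizontally (fibrous look)


def default_texture_params() -> dict[str, ClassTexture]:
    # Red channel base shared by every tissue class (0.72) by design.
    return {
        "background": ClassTexture((0.965, 0.965, 0.975), (0.012, 0.012, 0.012), 1.5),
        "normal": ClassTexture(
            (0.72, 0.55, 0.68), (0.07, 0.08, 0.07), 2.5, 3.0e-4, 3.0, 0.30
        ),
        "tumor": ClassTexture(
            (0.72, 0.49, 0.63), (0.09, 0.10, 0.09), 1.6, 8.0e-4, 2.0, 0.38
        ),
        "stroma": ClassTexture(
            (0.72, 0.62, 0.73), (0.05, 0.06, 0.05), 3.0, 4e-5, 3.0, 0.22, streak=4.0
        ),
        "vessel": ClassTexture((0.72, 0.34, 0.40), (0.05, 0.04, 0.04), 4.0),
    }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slide.

    ``tumor_area_fraction`` is the fraction of *tissue* area that is truly
    tumor; ``inclusion_rate`` the expected fraction of the rough-annotated
    tumor area that is actually non-tumor; ``scatter_rate`` the expected
    fraction of true tumor area lying outside the rough annotation.
    """

    width_px: int = 512
    height_px: int = 512
    n_tumor_regions: int = 3
    tumor_area_fraction: float = 0.35
    inclusion_rate: float = 0.25
    scatter_rate: float = 0.12
    dilation_radius_px: float = 6.0
    # stroma/vessel regions in *non-tumor* tissue, as a fraction of tissue
    # area; same textures as the inclusions but correctly labelled non-tumor.
    # Without them the inclusion "noise" would be a consistent, learnable
    # rule (those textures would only ever appear with tumor labels).
    distractor_rate: float = 0.10
    texture_params: dict[str, ClassTexture] = field(default_factory=default_texture_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 256 or self.height_px < 256:
            raise ValueError("phantom dimensions must be >= 256 px")
        for name in ("tumor_area_fraction", "inclusion_rate", "scatter_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be non-negative")

    def tissue_area(self) -> float:
        return np.pi * (0.44 * self.width_px) * (0.44 * self.height_px)

    def nominal_noise_rate(self) -> float:
        """Analytic estimate of the patch-label noise rate this spec induces.

        Noise pixels are (a) inclusions carved out of the gross tumor blobs,
        (b) the dilation ring around each blob, (c) scattered foci outside
        the rough annotation; all expressed as a fraction of tissue area,
        which is also the probability that a uniformly placed patch center
        receives conflicting rough/elaborate labels.
        """
        a_t = self.tissue_area()
        total_tumor = self.tumor_area_fraction * a_t
        scatter = self.scatter_rate * total_tumor
        main_net = total_tumor - scatter
        if self.inclusion_rate >= 1.0 or self.n_tumor_regions == 0 or total_tumor == 0:
            gross = main_net
            inclusions = 0.0
        else:
            gross = main_net / (1.0 - self.inclusion_rate)
            inclusions = self.inclusion_rate * gross
        r_blob = np.sqrt(gross / max(self.n_tumor_regions, 1) / np.pi)
        # circle-equivalent outline; bumpiness and component merging roughly cancel
        perimeter = self.n_tumor_regions * 2 * np.pi * r_blob
        ring = perimeter * self.dilation_radius_px
        return float((inclusions + ring + scatter) / a_t)


@dataclass
class PhantomSlide:
    """A rendered phantom with ground truth and both annotation sets."""

    image: np.ndarray  # (H, W, 3) uint8
    true_mask: np.ndarray  # (H, W) bool — exact tumor pixels
    rough_annotation: list[Polygon]
    elaborate_annotation: list[Polygon]
    tissue_region: np.ndarray  # (H, W) bool
    metadata: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.true_mask.shape

    _rough_mask_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def rough_mask(self) -> np.ndarray:
        if self._rough_mask_cache is None:
            self._rough_mask_cache = rasterize_polygons(self.rough_annotation, self.shape)
        return self._rough_mask_cache


# ---------------------------------------------------------------------------
# geometry helpers


def rasterize_polygons(polygons: list[Polygon], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon set onto a pixel grid (pixel centers, 0-based)."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if not polygons:
        return mask
    geom = unary_union(polygons)
    if geom.is_empty:
        return mask
    x0, y0, x1, y1 = geom.bounds
    c0, c1 = max(int(np.floor(x0)), 0), min(int(np.ceil(x1)) + 1, w)
    r0, r1 = max(int(np.floor(y0)), 0), min(int(np.ceil(y1)) + 1, h)
    if c1 <= c0 or r1 <= r0:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    shapely.prepare(geom)
    inside = shapely.intersects_xy(geom, xx + 0.5, yy + 0.5)
    mask[r0:r1, c0:c1] = inside
    return mask


def _blob_polygon(rng: np.random.Generator, cx: float, cy: float, r: float) -> Polygon:
    """Blobby closed outline: circle with smooth random radial perturbation."""
    n = 48
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    bumps = rng.standard_normal(n)
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(bumps, 3), kernel, mode="same")[n : 2 * n]
    radii = r * (1.0 + 0.18 * smooth / max(np.abs(smooth).max(), 1e-9))
    pts = np.column_stack([cx + radii * np.cos(theta), cy + radii * np.sin(theta)])
    poly = Polygon(pts)
    return poly if poly.is_valid else poly.buffer(0)


def _sample_point_in(rng: np.random.Generator, geom, max_tries: int = 200):
    x0, y0, x1, y1 = geom.bounds
    for _ in range(max_tries):
        p = Point(rng.uniform(x0, x1), rng.uniform(y0, y1))
        if geom.contains(p):
            return p
    return None


# ---------------------------------------------------------------------------
# texture rendering


def _render_texture(
    rng: np.random.Generator, shape: tuple[int, int], tex: ClassTexture
) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float32)
    sig_y = tex.grain_sigma
    sig_x = tex.grain_sigma * tex.streak
    for c in range(3):
        noise = rng.standard_normal((h, w))
        band = gaussian_filter(noise, sigma=(sig_y, sig_x))
        band /= max(band.std(), 1e-9)
        img[..., c] = tex.base_rgb[c] + tex.contrast[c] * band
    n_spots = rng.poisson(tex.spot_density * h * w)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        radius = max(tex.spot_radius * rng.uniform(0.7, 1.3), 1.0)
        rr, cc = draw_disk((cy, cx), radius, shape=(h, w))
        img[rr, cc, :] *= 1.0 - tex.spot_darkness
        img[rr, cc, 2] += 0.12 * tex.spot_darkness  # hematoxylin-like blue shift
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# public operations


def roughen_annotation(
    elaborate: list[Polygon],
    dilation_radius_px: float,
    inclusion_rate: float,
    scatter_rate: float,
    seed: int = 0,
    small_area_fraction: float = 0.05,
) -> list[Polygon]:
    """Degrade an exact annotation into a rough one.

    Large components are dilated by ``dilation_radius_px`` and, when
    ``inclusion_rate > 0``, their interior holes are filled (the holes become
    non-tumor inclusions swallowed by the rough outline). Components whose
    area is below ``small_area_fraction`` of the largest component are treated
    as scattered foci and dropped with probability ``scatter_rate``. With all
    three knobs at zero the input region is returned unchanged.
    """
    if not elaborate:
        raise ValueError("elaborate annotation must be non-empty")
    if dilation_radius_px < 0:
        raise ValueError("dilation radius must be non-negative")
    rng = np.random.default_rng(seed)
    areas = np.array([p.area for p in elaborate])
    cutoff = small_area_fraction * areas.max()
    out: list[Polygon] = []
    for poly, area in zip(elaborate, areas):
        if area < cutoff and rng.random() < scatter_rate:
            continue
        if inclusion_rate > 0 and poly.interiors:
            poly = Polygon(poly.exterior)
        if dilation_radius_px > 0:
            poly = poly.buffer(dilation_radius_px)
        out.append(poly)
    return out


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomSlide:
    """Render one phantom slide; fully deterministic per (spec, seed)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    w, h = spec.width_px, spec.height_px

    tissue_geom = affinity.scale(
        Point(w / 2, h / 2).buffer(1.0, quad_segs=64), 0.44 * w, 0.44 * h
    )
    a_tissue = tissue_geom.area

    total_tumor = spec.tumor_area_fraction * a_tissue
    scatter_target = spec.scatter_rate * total_tumor
    main_net = total_tumor - scatter_target
    gross = main_net / (1.0 - spec.inclusion_rate) if spec.inclusion_rate < 1 else main_net

    # --- main tumor region: union of blobby components, area-matched to the
    # gross target so the configured fractions are realized faithfully
    gross_geom = Polygon()
    if spec.n_tumor_regions > 0 and gross > 0:
        r_blob = np.sqrt(gross / spec.n_tumor_regions / np.pi)
        margin = r_blob * 0.9 + spec.dilation_radius_px
        inner = tissue_geom.buffer(-margin)
        if inner.is_empty:
            inner = tissue_geom.buffer(-0.3 * min(w, h) * 0.44)
        centers: list[Point] = []
        for _ in range(spec.n_tumor_regions):
            best = None
            for _ in range(60):
                p = _sample_point_in(rng, inner)
                if p is None:
                    break
                if all(p.distance(q) > 1.6 * r_blob for q in centers):
                    best = p
                    break
            if best is None:
                best = p  # crowded layout: allow blobs to merge
            if best is not None:
                centers.append(best)
        blobs = [_blob_polygon(rng, c.x, c.y, r_blob) for c in centers]
        clipper = tissue_geom.buffer(-(spec.dilation_radius_px + 2))
        gross_geom = unary_union(blobs).intersection(clipper)
        for _ in range(4):  # buffer in/out until the union hits the target area
            short = gross - gross_geom.area
            if abs(short) < 0.02 * gross or gross_geom.is_empty:
                break
            delta = short / max(gross_geom.length, 1.0)
            gross_geom = gross_geom.buffer(delta).intersection(clipper)

    # --- inclusions carved inside each main component
    elaborate_main: list[Polygon] = []
    components = [
        g for g in getattr(gross_geom, "geoms", [gross_geom])
        if isinstance(g, Polygon) and not g.is_empty
    ]
    for blob in components:
        target = spec.inclusion_rate * blob.area
        holes: list[Polygon] = []
        carved = 0.0
        r_b = np.sqrt(blob.area / np.pi)
        guard = 0
        while carved < target and guard < 300:
            guard += 1
            # inclusions sized like a patch footprint, so an inclusion-centered
            # patch is dominated by non-tumor content; the last one shrinks to
            # the remaining area budget
            r_i = rng.uniform(0.34, 0.48) * r_b
            r_i = min(r_i, max(np.sqrt((target - carved) / np.pi), 0.15 * r_b))
            interior = blob.buffer(-(r_i + 3))
            if interior.is_empty:
                continue
            p = _sample_point_in(rng, interior)
            if p is None:
                continue
            hole = p.buffer(r_i, quad_segs=24)
            if any(hole.intersects(hh) for hh in holes):
                continue
            holes.append(hole)
            carved += hole.area
        shell = blob.difference(unary_union(holes)) if holes else blob
        for geom in getattr(shell, "geoms", [shell]):
            if isinstance(geom, Polygon) and not geom.is_empty:
                elaborate_main.append(geom)

    # --- rough annotation from the exact main components
    if elaborate_main:
        rough = roughen_annotation(
            elaborate_main,
            spec.dilation_radius_px,
            inclusion_rate=1.0,
            scatter_rate=1.0,
            seed=seed,
        )
    else:
        rough = []
    rough_geom = unary_union(rough) if rough else Polygon()

    # --- scattered foci outside the rough annotation
    foci: list[Polygon] = []
    placed = 0.0
    guard = 0
    while placed < scatter_target and guard < 400:
        guard += 1
        r_f = rng.uniform(8.0, 14.0)
        r_f = min(r_f, max(np.sqrt((scatter_target - placed) / np.pi), 4.0))
        p = _sample_point_in(rng, tissue_geom.buffer(-(r_f + 2)))
        if p is None:
            break
        focus = p.buffer(r_f, quad_segs=16)
        if not rough_geom.is_empty and focus.distance(rough_geom) < 4:
            continue
        if any(focus.distance(f) < 4 for f in foci):
            continue
        foci.append(focus)
        placed += focus.area

    # --- distractor stroma/vessel regions in normal tissue (non-tumor, and
    # outside the rough annotation, so they carry no label noise themselves)
    distractors: list[Polygon] = []
    placed_d = 0.0
    d_target = spec.distractor_rate * a_tissue
    guard = 0
    while placed_d < d_target and guard < 600:
        guard += 1
        r_d = rng.uniform(14.0, 30.0)
        p = _sample_point_in(rng, tissue_geom.buffer(-(r_d + 2)))
        if p is None:
            break
        dgeom = p.buffer(r_d, quad_segs=16)
        if not rough_geom.is_empty and dgeom.distance(rough_geom) < 4:
            continue
        if any(dgeom.intersects(f) for f in foci) or any(
            dgeom.intersects(d) for d in distractors
        ):
            continue
        distractors.append(dgeom)
        placed_d += dgeom.area

    elaborate = elaborate_main + foci
    shape = (h, w)
    true_mask = rasterize_polygons(elaborate, shape)
    tissue_mask = rasterize_polygons([tissue_geom], shape)
    rough_mask = rasterize_polygons(rough, shape)

    # --- composite the texture layers
    tex = spec.texture_params
    image = _render_texture(rng, shape, tex["background"])
    normal_tex = _render_texture(rng, shape, tex["normal"])
    image[tissue_mask] = normal_tex[tissue_mask]
    # inclusions (rough minus true, inside tissue) and distractors share the
    # stroma/vessel textures; alternate the two by coarse column band
    inclusion_mask = rough_mask & ~true_mask & tissue_mask
    if distractors:
        inclusion_mask = inclusion_mask | rasterize_polygons(distractors, shape)
    if inclusion_mask.any():
        half = _render_texture(rng, shape, tex["stroma"])
        other = _render_texture(rng, shape, tex["vessel"])
        lbl = np.indices(shape)[1] // 48 % 2 == 0
        image[inclusion_mask & lbl] = half[inclusion_mask & lbl]
        image[inclusion_mask & ~lbl] = other[inclusion_mask & ~lbl]
    if true_mask.any():
        image[true_mask] = _render_texture(rng, shape, tex["tumor"])[true_mask]

    image8 = np.clip(np.rint(image * 255), 0, 255).astype(np.uint8)

    realized_noise = (
        float((rough_geom.symmetric_difference(unary_union(elaborate))).area / a_tissue)
        if elaborate or rough
        else 0.0
    )
    meta = {
        "seed": int(seed),
        "spec": {k: v for k, v in asdict(spec).items() if k != "texture_params"},
        "expected_noise_rate": realized_noise,
        "nominal_noise_rate": spec.nominal_noise_rate(),
        "tumor_area_px": int(true_mask.sum()),
        "tissue_area_px": int(tissue_mask.sum()),
    }
    return PhantomSlide(
        image=image8,
        true_mask=true_mask,
        rough_annotation=rough,
        elaborate_annotation=elaborate,
        tissue_region=tissue_mask,
        metadata=meta,
    )


def measure_noise_rate(
    slide: PhantomSlide,
    n_patches: int,
    patch_size: int = 64,
    seed: int = 0,
) -> float:
    """Fraction of sampled tissue patches whose rough and exact labels differ.

    Patch labels follow the center-membership rule used downstream, so this is
    the label-noise rate a patch dataset built from the rough annotation
    would carry.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    h, w = slide.shape
    if patch_size > min(h, w):
        raise ValueError("patch larger than slide")
    rng = np.random.default_rng(seed)
    ys, xs = np.nonzero(slide.tissue_region)
    if len(ys) == 0:
        return 0.0
    idx = rng.integers(0, len(ys), size=n_patches)
    cy, cx = ys[idx], xs[idx]
    rough = slide.rough_mask[cy, cx]
    exact = slide.true_mask[cy, cx]
    return float(np.mean(rough != exact))


def generate_cohort(
    n_slides: int, spec: PhantomSpec, seed: int = 0
) -> tuple[list[PhantomSlide], pd.DataFrame]:
    """Generate ``n_slides`` phantoms with per-slide derived seeds + manifest."""
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_slides) % (2**31)
    slides, rows = [], []
    for i, s in enumerate(child_seeds):
        slide = generate_phantom(spec, seed=int(s))
        slides.append(slide)
        rows.append(
            {
                "slide_id": f"phantom_{i:03d}",
                "seed": int(s),
                "noise_rate": measure_noise_rate(slide, 200, seed=int(s)),
                "tumor_area_px": slide.metadata["tumor_area_px"],
                "expected_noise_rate": slide.metadata["expected_noise_rate"],
            }
        )
    return slides, pd.DataFrame(rows)


def save_phantom(slide: PhantomSlide, outdir, stem: str = "phantom") -> None:
    """Write the raster as PNG and both annotation sets as GeoJSON."""
    from pathlib import Path
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(slide.image).save(outdir / f"{stem}.png")
    Image.fromarray((slide.true_mask * 255).astype(np.uint8)).save(
        outdir / f"{stem}_truth.png"
    )
    for kind, polys in (
        ("rough", slide.rough_annotation),
        ("elaborate", slide.elaborate_annotation),
    ):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"label": "tumor"}, "geometry": mapping(p)}
                for p in polys
            ],
        }
        with open(outdir / f"{stem}_{kind}.geojson", "w") as fh:
            json.dump(fc, fh)
    with open(outdir / f"{stem}_meta.json", "w") as fh:
        json.dump(slide.metadata, fh, indent=2, default=float)
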