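"""End-to-end seeded experiments on synthetic cohorts.

One experiment: generate a phantom cohort -> extract multi-scale patches with
rough-annotation labels -> pretrain the screening model on the noisy labels
-> screen (none / slide-level / patch-level) and rebalance -> train the
classifier under each loss mode (hard / static smooth / dynamic smooth) ->
evaluate patch-, slide- and pixel-level performance against the exact
annotations. Everything derives from one master seed, so identical configs
give identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd

from .inference import (
    classification_metrics,
    classify_slide,
    pixel_accuracy,
    pixel_heatmap,
    predict_slide_patches,
    sweep_ratio_threshold,
)
from .models import (
    MainModelConfig,
    PolymerEncoderConfig,
    assemble_polymer,
    build_epsilon_head,
    build_main_model,
    encode_tiles,
    polymer_to_input,
    pretrain_polymer_encoder,
)
from .patching import AnnotationSet, SlideImage, build_manifest, extract_patch_array
from .phantom import PhantomSpec, generate_phantom
from .screening import balance_manifest, patch_screen, pretrain_screening_model, slide_screen
from .training import TrainConfig, train_classifier

__all__ = ["ExperimentConfig", "run_experiment", "noise_robustness_study"]


@dataclass
class ExperimentConfig:
    """Full description of one desk-scale experiment."""

    # cohort
    n_slides: int = 12
    n_normal_slides: int = 4  # tumor-free slides for slide-level evaluation
    slide_px: int = 384
    base_magnification: float = 20.0
    tumor_area_fraction: float = 0.35
    inclusion_rate: float = 0.25
    scatter_rate: float = 0.12
    dilation_radius_px: float = 6.0
    n_tumor_regions: int = 2
    # patching
    n_centers: int = 80
    min_distance: float = 24.0
    magnifications: tuple[float, ...] = (5.0, 20.0, 50.0)
    out_size: int = 64
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # screening
    screening_modes: tuple[str, ...] = ("raw", "patch")
    screening_threshold: float = 0.7
    screening_magnification: float = 20.0
    pretrain_epochs: int = 25
    # training
    loss_modes: tuple[str, ...] = ("hard", "static_smooth", "dynamic_smooth")
    static_eps: float = 0.2
    epochs: int = 30
    batch_size: int = 32
    # the desk-scale classifier trains from random initialisation, so it uses
    # a larger step size than a fine-tuned reference backbone would
    learning_rate: float = 1e-3
    # dihedral augmentation for the screening pretrain only: the screening
    # model must generalize rather than memorize its small training set,
    # while the comparison arms follow the plain training procedure
    augment_pretrain: bool = True
    augment_arms: bool = False
    autoencoder_epochs: int = 4
    autoencoder_tiles: int = 96
    # evaluation
    ratio_threshold: float = 0.04
    heatmap_window: int = 64
    heatmap_stride: int = 32
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for k in ("magnifications", "split_fractions", "screening_modes", "loss_modes"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class _Cohort:
    slides_by_id: dict[str, SlideImage]
    phantoms: dict[str, object]
    manifest: pd.DataFrame
    slide_truth: dict[str, int]  # 1 if the slide truly contains tumor


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def _build_cohort(config: ExperimentConfig, seed: int) -> _Cohort:
    spec_kwargs = dict(
        width_px=config.slide_px,
        height_px=config.slide_px,
        n_tumor_regions=config.n_tumor_regions,
        tumor_area_fraction=config.tumor_area_fraction,
        inclusion_rate=config.inclusion_rate,
        scatter_rate=config.scatter_rate,
        dilation_radius_px=config.dilation_radius_px,
    )
    slide_seeds = _seeds(seed, config.n_slides)
    # interleave tumor-free slides deterministically through the cohort
    normal_idx = set(
        np.linspace(0, config.n_slides - 1, config.n_normal_slides, dtype=int).tolist()
        if config.n_normal_slides
        else []
    )
    slides_by_id, phantoms, truth = {}, {}, {}
    pairs, clean = [], []
    for i, s in enumerate(slide_seeds):
        frac = 0.0 if i in normal_idx else config.tumor_area_fraction
        spec = PhantomSpec(**{**spec_kwargs, "tumor_area_fraction": frac})
        ph = generate_phantom(spec, seed=s)
        sid = f"phantom_{i:03d}"
        slide = SlideImage(ph.image, config.base_magnification, sid)
        slides_by_id[sid] = slide
        phantoms[sid] = ph
        truth[sid] = int(ph.true_mask.any())
        pairs.append((slide, AnnotationSet(ph.rough_annotation, "rough")))
        clean.append(AnnotationSet(ph.elaborate_annotation, "elaborate"))
    manifest = build_manifest(
        pairs,
        n_centers=config.n_centers,
        min_distance=config.min_distance,
        magnifications=config.magnifications,
        out_size=config.out_size,
        split_fractions=config.split_fractions,
        seed=seed,
        clean_annotations=clean,
    )
    return _Cohort(slides_by_id, phantoms, manifest, truth)


def true_noise_rate(manifest: pd.DataFrame, magnification: float = 20.0) -> float:
    """Fraction of train patches whose rough label disagrees with truth."""
    rows = manifest[
        (manifest["split"] == "train") & (manifest["magnification"] == magnification)
    ]
    if rows.empty:
        return float("nan")
    return float(np.mean(rows["label"].to_numpy() != rows["clean_label"].to_numpy()))


def _apply_screening(mode, model, cohort, config):
    m = cohort.manifest
    if mode == "raw":
        return m, None
    if mode == "patch":
        return patch_screen(
            model,
            m,
            cohort.slides_by_id,
            threshold=config.screening_threshold,
            magnification=config.screening_magnification,
            out_size=config.out_size,
        )
    if mode == "slide":
        return slide_screen(
            model,
            m,
            cohort.slides_by_id,
            acc_threshold=config.screening_threshold,
            magnification=config.screening_magnification,
            out_size=config.out_size,
        )
    raise ValueError(f"unknown screening mode {mode!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment grid; returns a JSON-serializable report."""
    (
        cohort_seed,
        pretrain_seed,
        ae_seed,
        train_seed,
        balance_seed,
    ) = _seeds(config.seed, 5)

    cohort = _build_cohort(config, cohort_seed)
    mag, out_size = config.screening_magnification, config.out_size

    # --- stage 1: pretrain the screening model on raw noisy labels
    # (class-balanced, so the preliminary model is not biased to a class)
    pretrain_manifest = balance_manifest(cohort.manifest, seed=balance_seed)
    screen_model, pretrain_val_acc, pretrain_hist = pretrain_screening_model(
        pretrain_manifest,
        cohort.slides_by_id,
        magnification=mag,
        out_size=out_size,
        train_config=TrainConfig(
            epochs=config.pretrain_epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=pretrain_seed,
            augment=config.augment_pretrain,
        ),
        seed=pretrain_seed,
    )

    # --- context-tile autoencoder (shared across arms), pretrained on raw train tiles
    need_dynamic = "dynamic_smooth" in config.loss_modes
    encoder = pconfig = None
    ae_history: list[float] = []
    if need_dynamic:
        pconfig = PolymerEncoderConfig(tile_size=int(1.5 * out_size))
        train_rows = cohort.manifest[
            (cohort.manifest["split"] == "train")
            & (cohort.manifest["magnification"] == mag)
        ].reset_index(drop=True)
        rng = np.random.default_rng(ae_seed)
        pick = rng.permutation(len(train_rows))[: config.autoencoder_tiles]
        tiles = np.stack(
            [
                polymer_to_input(
                    assemble_polymer(
                        cohort.slides_by_id[r.slide_id],
                        (r.center_x, r.center_y),
                        mag,
                        out_size,
                    ),
                    pconfig,
                )
                for r in train_rows.iloc[np.sort(pick)].itertuples()
            ]
        )
        encoder, _, ae_history = pretrain_polymer_encoder(
            tiles, pconfig, seed=ae_seed, epochs=config.autoencoder_epochs
        )

    # validation patches use exact labels (the validation set is curated)
    val_rows = cohort.manifest[
        (cohort.manifest["split"] == "val") & (cohort.manifest["magnification"] == mag)
    ]
    x_val = y_val = None
    if not val_rows.empty:
        x_val, vr = extract_patch_array(val_rows, cohort.slides_by_id, mag, out_size)
        y_val = vr["clean_label"].to_numpy()

    test_rows = cohort.manifest[
        (cohort.manifest["split"] == "test") & (cohort.manifest["magnification"] == mag)
    ]
    x_test, tr = extract_patch_array(test_rows, cohort.slides_by_id, mag, out_size)
    y_test = tr["clean_label"].to_numpy()

    # --- stage 2: screen, balance, train, evaluate per arm
    arms = []
    screening_reports = {}
    noise_rates = {"raw": true_noise_rate(cohort.manifest, mag)}
    best_models: dict[tuple[str, str], object] = {}
    for s_mode in config.screening_modes:
        try:
            screened, report = _apply_screening(s_mode, screen_model, cohort, config)
        except Exception as exc:  # pragma: no cover - stage diagnostics
            raise RuntimeError(f"screening stage '{s_mode}' failed: {exc}") from exc
        if report is not None:
            screening_reports[s_mode] = {
                "mode": report.mode,
                "threshold": report.threshold,
                "retained": report.retained,
                "removed": report.removed,
            }
        noise_rates[s_mode] = true_noise_rate(screened, mag)
        try:
            balanced = balance_manifest(screened, seed=balance_seed)
        except ValueError as exc:
            raise RuntimeError(
                f"balancing stage after '{s_mode}' screening failed: {exc}"
            ) from exc
        train_rows = balanced[
            (balanced["split"] == "train") & (balanced["magnification"] == mag)
        ]
        x_tr, rows_tr = extract_patch_array(train_rows, cohort.slides_by_id, mag, out_size)
        y_tr = rows_tr["label"].to_numpy()

        feats = None
        if need_dynamic:
            tiles = np.stack(
                [
                    polymer_to_input(
                        assemble_polymer(
                            cohort.slides_by_id[r.slide_id],
                            (r.center_x, r.center_y),
                            mag,
                            out_size,
                        ),
                        pconfig,
                    )
                    for r in rows_tr.itertuples()
                ]
            )
            feats = encode_tiles(encoder, tiles)
            # z-score the frozen features so the fc head trains at a
            # consistent scale across arms and seeds
            feats = (feats - feats.mean(axis=0)) / (feats.std(axis=0) + 1e-6)
            feats = feats.astype(np.float32)

        for l_mode in config.loss_modes:
            tc = TrainConfig(
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                epochs=config.epochs,
                loss_mode=l_mode,
                static_eps=config.static_eps,
                seed=train_seed,
                augment=config.augment_arms,
            )
            model = build_main_model(MainModelConfig(input_size=out_size), seed=train_seed)
            head = build_epsilon_head(pconfig, seed=train_seed) if l_mode == "dynamic_smooth" else None
            model, hist, extras = train_classifier(
                model,
                x_tr,
                y_tr,
                tc,
                x_val=x_val,
                y_val=y_val,
                polymer_features=feats if l_mode == "dynamic_smooth" else None,
                epsilon_head=head,
            )
            from .models import predict_proba

            p_test = predict_proba(model, x_test)
            metrics = classification_metrics(p_test, y_test)
            arm = {
                "screening": s_mode,
                "loss_mode": l_mode,
                "n_train": int(len(x_tr)),
                "train_noise_rate": float(
                    np.mean(rows_tr["label"].to_numpy() != rows_tr["clean_label"].to_numpy())
                ),
                "final_train_loss": float(hist["train_loss"].iloc[-1]),
                "best_val_acc": float(extras["best_val_acc"]),
                "test_accuracy": metrics["accuracy"],
                "test_auc": metrics["auc"],
                "test_f1": metrics["f1"],
            }
            if extras["eps_prime_last_epoch"] is not None:
                ep = extras["eps_prime_last_epoch"]
                arm["eps_prime_min"] = float(ep.min())
                arm["eps_prime_max"] = float(ep.max())
            arms.append(arm)
            best_models[(s_mode, l_mode)] = model

    # --- stage 3: slide-level diagnosis with the best arm's model
    pref = [
        ("patch", "dynamic_smooth"),
        ("patch", "static_smooth"),
        ("patch", "hard"),
    ] + list(best_models)
    final_key = next(k for k in pref if k in best_models)
    final_model = best_models[final_key]
    ratios, slide_truths, slide_calls = [], [], []
    for sid, slide in cohort.slides_by_id.items():
        centers, probs = predict_slide_patches(
            final_model,
            slide,
            window=config.heatmap_window,
            stride=config.heatmap_window // 2,
            out_size=out_size,
        )
        if len(probs) == 0:
            continue
        pred = classify_slide(centers, probs, config.ratio_threshold, sid)
        ratios.append(pred.cancer_ratio)
        slide_truths.append(cohort.slide_truth[sid])
        slide_calls.append(1 if pred.slide_call == "tumor" else 0)
    ratios = np.asarray(ratios)
    slide_truths_arr = np.asarray(slide_truths)
    slide_acc = float(np.mean(np.asarray(slide_calls) == slide_truths_arr))
    if len(np.unique(slide_truths_arr)) == 2:
        best_thr, _curve = sweep_ratio_threshold(ratios, slide_truths_arr)
    else:
        best_thr = float("nan")

    # --- stage 4: pixel-level heatmap on the first tumor-bearing test slide
    pixel_acc = float("nan")
    test_slides = tr["slide_id"].unique().tolist()
    tumor_test = [s for s in test_slides if cohort.slide_truth[s]]
    if tumor_test:
        sid = tumor_test[0]
        hm = pixel_heatmap(
            final_model,
            cohort.slides_by_id[sid],
            window=config.heatmap_window,
            stride=config.heatmap_stride,
            out_size=out_size,
        )
        pixel_acc = pixel_accuracy(hm, cohort.phantoms[sid].true_mask)

    report = {
        "config": config.to_dict(),
        "pretrain_val_acc": float(pretrain_val_acc),
        "autoencoder_final_error": float(ae_history[-1]) if ae_history else float("nan"),
        "noise_rates": {k: float(v) for k, v in noise_rates.items()},
        "screening_reports": screening_reports,
        "arms": arms,
        "slide_level": {
            "accuracy": slide_acc,
            "ratio_threshold": config.ratio_threshold,
            "optimal_threshold": best_thr,
            "model_arm": list(final_key),
            "n_slides": int(len(ratios)),
        },
        "pixel_accuracy": pixel_acc,
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)


def noise_robustness_study(
    base_config: ExperimentConfig | None = None, n_seeds: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Repeat the experiment grid over seeds; one row per (seed, arm).

    This is the desk-scale analogue of the published comparison grid:
    screening modes in columns, smoothing modes in rows, mean over seeds.
    """
    base = base_config or ExperimentConfig()
    rows = []
    for rep, s in enumerate(_seeds(seed, n_seeds)):
        cfg = ExperimentConfig.from_dict({**base.to_dict(), "seed": int(s)})
        rep_out = run_experiment(cfg)
        for arm in rep_out["arms"]:
            rows.append(
                {
                    "replicate": rep,
                    "seed": int(s),
                    "pretrain_val_acc": rep_out["pretrain_val_acc"],
                    "noise_raw": rep_out["noise_rates"]["raw"],
                    "noise_after": rep_out["noise_rates"].get(
                        arm["screening"], rep_out["noise_rates"]["raw"]
                    ),
                    "slide_accuracy": rep_out["slide_level"]["accuracy"],
                    "optimal_ratio_threshold": rep_out["slide_level"]["optimal_threshold"],
                    "pixel_accuracy": rep_out["pixel_accuracy"],
                    **arm,
                }
            )
    return pd.DataFrame(rows)
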