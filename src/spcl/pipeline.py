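"""End-to-end desk-scale experiment: synthesise slides, tile them, pretrain a
sample-positive encoder and probe it with linear evaluation on held-out
slides.

This is the package's reference experiment.  The full-scale study conditions
(512/128 px tiles at 20x, ResNet18, batch 128, 200 epochs) are supported via
the configuration surface but are not what this module runs; the sizes here
are chosen once for a single-CPU desk run and are documented in the methods
note: 8 slides of 640 px with 8 contiguous tissue regions and 4 texture
classes, 64 px large patches, 32 px small views, M = 4, a tiny 4-block CNN,
and a handful of epochs.  Evaluation patches always come from slides the
encoder never saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, make_augmenter
from .contrastive import (
    NetworkSpec, PretrainResult, TrainConfig, build_networks, pretrain,
)
from .errors import ParameterError
from .evaluation import EvalProtocol, compute_metrics, train_classifier
from .sampling import SamplerConfig
from .synthetic import (
    SyntheticSlide, generate_slide, make_class_library,
    make_labeled_patch_dataset, sample_large_patches,
)
from .tiling import compute_otsu_mask, extract_tile, sliding_window_tiles

__all__ = ["DeskConfig", "make_slides", "gather_large_patches",
           "random_init_result", "run_desk_experiment"]


@dataclass(frozen=True)
class DeskConfig:
    """Study conditions for the desk-scale experiment (fixed defaults)."""

    n_classes: int = 4
    n_slides: int = 8
    slide_size: int = 640
    background_border: int = 48
    num_regions: int = 8
    texture_scale: int = 8
    noise_sd: float = 12.0
    large_size: int = 64
    small_size: int = 32
    M: int = 4
    sampling_mode: str = "overlapping"
    batch_N: int = 8
    epochs: int = 8
    max_large_patches: int = 192
    min_tissue_fraction: float = 0.9
    labeled_per_class: int = 160
    tau: float = 0.1
    lr: float = 3e-3
    widths: tuple[int, ...] = (16, 32, 64, 128)
    # milder jitter/blur than the full-scale defaults: 32 px views of subtly
    # coloured texture classes under a small encoder and few epochs
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(
        crop_scale_range=(0.6, 1.0), hflip_p=0.5, vflip_p=0.5,
        color_jitter=(0.2, 0.2, 0.2, 0.05), color_jitter_p=0.8,
        grayscale_p=0.1, blur_p=0.2, blur_sigma_range=(0.1, 0.6), out_size=32))


def make_slides(seed: int, cfg: DeskConfig = DeskConfig()) -> list[SyntheticSlide]:
    """Generate the slide cohort for one experimental replicate."""
    library = make_class_library(cfg.n_classes, seed,
                                 texture_scale=cfg.texture_scale,
                                 noise_sd=cfg.noise_sd)
    return [
        generate_slide(cfg.slide_size, cfg.slide_size, cfg.num_regions, library,
                       seed=seed * 1000 + i,
                       background_border=cfg.background_border,
                       slide_id=f"s{seed}-{i}")
        for i in range(cfg.n_slides)
    ]


def split_slides(n_slides: int, seed: int) -> dict[str, list[int]]:
    """Slide-disjoint train/val/test split (5:1:2 for the default 8 slides)."""
    order = list(np.random.default_rng([seed, 13]).permutation(n_slides))
    n_test = max(1, round(n_slides * 0.25))
    n_val = max(1, round(n_slides * 0.125))
    return {"test": order[:n_test],
            "val": order[n_test:n_test + n_val],
            "train": order[n_test + n_val:]}


def gather_large_patches(slides: list[SyntheticSlide], source: str, seed: int,
                         cfg: DeskConfig = DeskConfig()) -> list[np.ndarray]:
    """Collect the large-patch pretraining set from a list of slides.

    `source` is "tiles" (Otsu mask + non-overlapping sliding window, the
    standard uniform construction), "pure" (class-pure rejection-sampled
    crops) or "boundary_mixed" (crops centred on class boundaries, the
    ablation condition).  Capped at `max_large_patches` by seeded
    subsampling.
    """
    rng = np.random.default_rng([seed, 29])
    patches: list[np.ndarray] = []
    if source == "tiles":
        for slide in slides:
            mask = compute_otsu_mask(slide.image, source_id=slide.slide_id)
            manifest = sliding_window_tiles(mask, cfg.large_size, cfg.large_size,
                                            cfg.min_tissue_fraction)
            patches.extend(extract_tile(slide.image, r) for r in manifest.records)
    elif source in ("pure", "boundary_mixed"):
        per_slide = int(np.ceil(cfg.max_large_patches / len(slides)))
        for i, slide in enumerate(slides):
            got = sample_large_patches(slide, cfg.large_size, per_slide,
                                       purity_mode=source, seed=seed * 100 + i)
            patches.extend(p.image for p in got)
    else:
        raise ParameterError(f"unknown large-patch source {source!r}")
    if len(patches) > cfg.max_large_patches:
        keep = rng.choice(len(patches), size=cfg.max_large_patches, replace=False)
        patches = [patches[i] for i in sorted(keep)]
    return patches


def random_init_result(seed: int, patches, cfg: DeskConfig = DeskConfig()
                       ) -> PretrainResult:
    """A freshly initialised (untrained) encoder packaged like a pretrained one.

    Serves as the no-pretraining control in representation-quality checks.
    """
    stack = np.stack(patches).astype(np.float64) / 255.0
    nets = build_networks(NetworkSpec(widths=cfg.widths, seed=seed), "sinclr")
    nets.train(False)
    return PretrainResult(encoder=nets.encoder,
                          input_mean=stack.mean(axis=(0, 1, 2)),
                          input_std=stack.std(axis=(0, 1, 2)) + 1e-6,
                          loss_trace=[])


def run_desk_experiment(seed: int, framework: str = "sinclr",
                        source: str = "tiles", sampling_mode: str | None = None,
                        degenerate_groups: bool = False,
                        cfg: DeskConfig = DeskConfig(),
                        slides: list[SyntheticSlide] | None = None,
                        include_random_baseline: bool = False) -> dict:
    """Full pipeline for one seed; returns metrics and the trained artefacts.

    Pretrains on large patches from the train+val slides only, then trains a
    linear probe on labelled patches and reports accuracy / macro-OVR AUC /
    macro-F1 on patches from the held-out test slides.
    """
    if slides is None:
        slides = make_slides(seed, cfg)
    split = split_slides(len(slides), seed)
    pretrain_slides = [slides[i] for i in split["train"] + split["val"]]

    patches = gather_large_patches(pretrain_slides, source, seed, cfg)
    sampler = SamplerConfig(large_size=cfg.large_size, small_size=cfg.small_size,
                            M=cfg.M, mode=sampling_mode or cfg.sampling_mode,
                            seed=seed)
    augmenter = make_augmenter(cfg.augment)
    train_cfg = TrainConfig(framework=framework, batch_N=cfg.batch_N,
                            epochs=cfg.epochs, lr=cfg.lr, tau=cfg.tau, seed=seed)
    result = pretrain(patches, sampler, augmenter,
                      NetworkSpec(widths=cfg.widths), train_cfg,
                      degenerate_groups=degenerate_groups)

    dataset = make_labeled_patch_dataset(
        slides, cfg.small_size, cfg.labeled_per_class, seed, split_slides=split)
    protocol = EvalProtocol(mode="linear", epochs=60, patience=8, lr=0.05,
                            seed=seed)
    clf = train_classifier(result,
                           (dataset["train"]["X"], dataset["train"]["y"]),
                           (dataset["val"]["X"], dataset["val"]["y"]),
                           protocol)
    proba = clf.predict_proba(dataset["test"]["X"])
    report = compute_metrics(dataset["test"]["y"], proba)

    out = {"f1": report.f1, "acc": report.acc, "auc": report.auc,
           "report": report, "result": result, "classifier": clf,
           "dataset": dataset, "slides": slides, "split": split,
           "loss_trace": result.loss_trace}
    if include_random_baseline:
        control = random_init_result(seed + 555, patches, cfg)
        clf0 = train_classifier(control,
                                (dataset["train"]["X"], dataset["train"]["y"]),
                                (dataset["val"]["X"], dataset["val"]["y"]),
                                protocol)
        rep0 = compute_metrics(dataset["test"]["y"],
                               clf0.predict_proba(dataset["test"]["X"]))
        out["random_baseline_f1"] = rep0.f1
    return out
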