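"""Synthetic tissue-texture slides for desk-scale experiments.

Real whole-slide images of non-diffuse carcinoma show a handful of tissue
classes (tumour, stroma, epithelium, necrosis) whose regions are spatially
contiguous: patches adjacent to a patch usually share its class.  That prior
is what sample-positive contrastive training exploits, so the generator's one
job is to reproduce it in a controllable way: a Voronoi partition of the
canvas into contiguous regions, each region painted with one class's colour
and texture, plus i.i.d. Gaussian pixel noise.  Everything is a pure function
of its arguments and a seed.

Colours are deliberately kept in a narrow, H&E-like luminance band (stained
tissue is mid-dark on a white background and inter-class colour contrast is
subtle); classes differ in chroma and in texture kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DataError, ParameterError, SamplingExhaustedError

__all__ = [
    "BACKGROUND_LABEL", "TEXTURE_KINDS", "TextureClassSpec", "SyntheticSlide",
    "LargePatch", "PatchDataset", "make_class_library", "generate_slide",
    "sample_large_patches", "make_labeled_patch_dataset",
]

BACKGROUND_LABEL = -1
TEXTURE_KINDS = ("blob", "stripe", "speckle", "smooth")

# Mid-luminance anchors (ITU-R 601 Y roughly 125-165), pairwise RGB distance
# comfortably above the per-seed jitter, all darker than the white background.
_PALETTE: tuple[tuple[int, int, int], ...] = (
    (168, 112, 180), (208, 130, 160), (140, 150, 120), (120, 140, 190),
    (190, 150, 120), (150, 120, 120), (120, 160, 160), (180, 140, 200),
    (200, 110, 130), (130, 130, 170), (160, 170, 140), (110, 150, 130),
    (170, 100, 140), (140, 110, 160), (190, 170, 160), (120, 120, 140),
)


@dataclass(frozen=True)
class TextureClassSpec:
    """Appearance of one synthetic tissue class."""

    class_id: int
    base_color: tuple[int, int, int]
    texture_kind: str
    texture_scale: int = 8
    noise_sd: float = 12.0

    def __post_init__(self):
        if self.texture_kind not in TEXTURE_KINDS:
            raise ParameterError(f"unknown texture kind {self.texture_kind!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.texture_scale < 1:
            raise ParameterError("texture_scale must be >= 1")


@dataclass
class SyntheticSlide:
    """RGB image plus aligned per-pixel class labels.

    ``label_mask`` holds class ids (``BACKGROUND_LABEL`` outside tissue);
    ``region_mask`` holds the Voronoi region index each tissue pixel belongs
    to, which is what "contiguous same-class region" tests count.
    """

    image: np.ndarray          # (H, W, 3) uint8
    label_mask: np.ndarray     # (H, W) int16
    region_mask: np.ndarray    # (H, W) int16, BACKGROUND_LABEL outside tissue
    region_seeds: list[tuple[int, int, int]]   # (x, y, class_id)
    rng_seed: int
    slide_id: str = "slide"
    library: list[TextureClassSpec] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape


class LargePatch:
    """A large crop with its majority class and class-purity fraction."""

    __slots__ = ("image", "mask", "majority_class", "purity", "x", "y")

    def __init__(self, image, mask, majority_class, purity, x, y):
        self.image = image
        self.mask = mask
        self.majority_class = int(majority_class)
        self.purity = float(purity)
        self.x = int(x)
        self.y = int(y)


@dataclass
class PatchDataset:
    """Balanced labelled small patches with a slide-disjoint split."""

    splits: dict[str, dict]    # split -> {"X", "y", "slide_ids"}
    patch_size: int
    class_ids: list[int]

    def __getitem__(self, split: str) -> dict:
        return self.splits[split]


def make_class_library(num_classes: int, seed: int,
                       texture_scale: int = 8,
                       noise_sd: float = 12.0) -> list[TextureClassSpec]:
    """Build `num_classes` texture specs with distinct colours and textures.

    Colour anchors are drawn without replacement from a fixed palette and
    jittered by the seed, so different seeds give different libraries while
    any one seed is fully reproducible.
    """
    if not 2 <= num_classes <= 16:
        raise ParameterError("num_classes must be between 2 and 16")
    rng = np.random.default_rng(seed)
    n_anchors = (num_classes + 1) // 2
    anchor_order = rng.permutation(len(_PALETTE))[:n_anchors]
    kind_order = rng.permutation(len(TEXTURE_KINDS))
    colors = []
    for anchor_idx in anchor_order:
        anchor = np.array(_PALETTE[anchor_idx], dtype=np.int64)
        jitter = rng.integers(-8, 9, size=3)
        colors.append(tuple(int(v) for v in np.clip(anchor + jitter, 40, 225)))
    specs = []
    for i in range(num_classes):
        # colour-twin pairing: classes 2j and 2j+1 share a colour and differ
        # only in texture, so chroma alone cannot solve the class task
        kind = TEXTURE_KINDS[kind_order[i % len(TEXTURE_KINDS)]]
        specs.append(TextureClassSpec(
            class_id=i, base_color=colors[i // 2], texture_kind=kind,
            texture_scale=texture_scale, noise_sd=noise_sd))
    return specs


def _render_texture(spec: TextureClassSpec, height: int, width: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Float RGB texture field for one class covering the whole canvas."""
    base = np.empty((height, width, 3), dtype=np.float32)
    base[:] = spec.base_color
    ts = spec.texture_scale
    if spec.texture_kind == "smooth":
        return base
    if spec.texture_kind == "stripe":
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:height, 0:width]
        wave = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / (2 * ts) + phase)
        return base + 18.0 * wave[..., None].astype(np.float32)
    if spec.texture_kind == "blob":
        noise = rng.standard_normal((height, width))
        smooth = ndimage.gaussian_filter(noise, sigma=ts)
        factor = np.where(smooth > 0, 0.82, 1.0).astype(np.float32)
        return base * factor[..., None]
    # speckle: dark dots at roughly texture_scale granularity
    ch = (height + ts - 1) // ts
    cw = (width + ts - 1) // ts
    coarse = rng.standard_normal((ch, cw))
    dots = np.kron(coarse > 1.0, np.ones((ts, ts)))[:height, :width]
    factor = np.where(dots > 0, 0.70, 1.0).astype(np.float32)
    return base * factor[..., None]


def generate_slide(width: int, height: int, num_regions: int,
                   library: list[TextureClassSpec], seed: int,
                   background_border: int = 0,
                   background_intensity: int = 245,
                   slide_id: str | None = None) -> SyntheticSlide:
    """Voronoi-partitioned synthetic slide with contiguous class regions.

    Region seed points are rejection-sampled with a minimum pairwise
    separation of three texture scales, which keeps every Voronoi cell's
    area above (texture_scale)^2 even when clipped at the canvas corner.
    Every class in `library` is assigned to at least one region.
    """
    if num_regions < len(library):
        raise ParameterError("num_regions must be >= number of classes")
    b = background_border
    ts = max(s.texture_scale for s in library)
    inner_w, inner_h = width - 2 * b, height - 2 * b
    min_sep = 3 * ts
    if inner_w <= 0 or inner_h <= 0 or inner_w * inner_h < num_regions * min_sep ** 2:
        raise ParameterError(
            f"image {width}x{height} (border {b}) too small for {num_regions} regions")
    rng = np.random.default_rng(seed)

    # region seed points with minimum separation
    points: list[tuple[int, int]] = []
    budget = 1000 * num_regions
    while len(points) < num_regions and budget > 0:
        budget -= 1
        x = int(rng.integers(b, width - b))
        y = int(rng.integers(b, height - b))
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep ** 2 for px, py in points):
            points.append((x, y))
    if len(points) < num_regions:
        raise SamplingExhaustedError("region_seeds", 1000 * num_regions)

    # class per region: every class at least once, remainder uniform
    class_ids = [s.class_id for s in library]
    assignment = list(class_ids) + list(rng.choice(class_ids, size=num_regions - len(class_ids)))
    assignment = [int(assignment[i]) for i in rng.permutation(num_regions)]

    tree = cKDTree(np.array(points, dtype=np.float64))
    yy, xx = np.mgrid[b:height - b, b:width - b]
    _, region_of_pixel = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
    region_inner = region_of_pixel.reshape(inner_h, inner_w).astype(np.int16)

    region_mask = np.full((height, width), BACKGROUND_LABEL, dtype=np.int16)
    region_mask[b:height - b, b:width - b] = region_inner
    class_of_region = np.array(assignment, dtype=np.int16)
    label_mask = np.full((height, width), BACKGROUND_LABEL, dtype=np.int16)
    label_mask[b:height - b, b:width - b] = class_of_region[region_inner]

    image = np.full((height, width, 3), float(background_intensity), dtype=np.float32)
    for spec in library:
        sel = label_mask == spec.class_id
        if not sel.any():
            continue
        tex_rng = np.random.default_rng([seed, 7919, spec.class_id])
        texture = _render_texture(spec, height, width, tex_rng)
        image[sel] = texture[sel]
    noise_sd = float(np.mean([s.noise_sd for s in library]))
    tissue = label_mask != BACKGROUND_LABEL
    image[tissue] += rng.normal(0.0, noise_sd, size=(int(tissue.sum()), 3)).astype(np.float32)
    image = np.clip(image, 0, 255).astype(np.uint8)

    seeds = [(px, py, int(assignment[i])) for i, (px, py) in enumerate(points)]
    return SyntheticSlide(
        image=image, label_mask=label_mask, region_mask=region_mask,
        region_seeds=seeds, rng_seed=seed,
        slide_id=slide_id or f"synthetic-{seed}", library=list(library))


def _crop_stats(mask: np.ndarray) -> tuple[int, float, int]:
    """(majority class, purity, number of distinct tissue classes) of a crop."""
    values, counts = np.unique(mask, return_counts=True)
    tissue = values != BACKGROUND_LABEL
    values, counts = values[tissue], counts[tissue]
    if len(values) == 0:
        return BACKGROUND_LABEL, 0.0, 0
    k = int(np.argmax(counts))
    return int(values[k]), float(counts[k] / mask.size), len(values)


def sample_large_patches(slide: SyntheticSlide, size: int, n: int,
                         purity_mode: str = "pure", seed: int = 0,
                         purity_threshold: float = 1.0,
                         max_attempts: int | None = None) -> list[LargePatch]:
    """Draw `n` large crops, either class-pure or centred on class boundaries.

    ``pure`` rejection-samples uniform positions until the crop's label mask
    is at least `purity_threshold` single-class (default exactly pure);
    ``boundary_mixed`` centres crops on pixels where two tissue classes meet,
    so every crop contains at least two classes — the ablation condition that
    deliberately violates the spatial-adjacency prior.
    """
    h, w = slide.shape
    if size > min(h, w):
        raise ParameterError(f"patch size {size} exceeds slide {w}x{h}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if purity_mode not in ("pure", "boundary_mixed"):
        raise ParameterError(f"unknown purity_mode {purity_mode!r}")
    budget = max_attempts if max_attempts is not None else 1000 * n
    rng = np.random.default_rng(seed)
    mask = slide.label_mask

    centers: np.ndarray | None = None
    if purity_mode == "boundary_mixed":
        m = mask
        boundary = np.zeros_like(m, dtype=bool)
        boundary[:, :-1] |= (m[:, :-1] != m[:, 1:]) & (m[:, :-1] >= 0) & (m[:, 1:] >= 0)
        boundary[:-1, :] |= (m[:-1, :] != m[1:, :]) & (m[:-1, :] >= 0) & (m[1:, :] >= 0)
        ys, xs = np.nonzero(boundary)
        if len(xs) == 0:
            raise DataError("slide has no class boundaries to centre on")
        centers = np.column_stack([xs, ys])

    out: list[LargePatch] = []
    attempts = 0
    while len(out) < n:
        if attempts >= budget:
            raise SamplingExhaustedError(purity_mode, attempts)
        attempts += 1
        if purity_mode == "pure":
            x = int(rng.integers(0, w - size + 1))
            y = int(rng.integers(0, h - size + 1))
        else:
            cx, cy = centers[rng.integers(0, len(centers))]
            x = int(np.clip(cx - size // 2, 0, w - size))
            y = int(np.clip(cy - size // 2, 0, h - size))
        sub = mask[y:y + size, x:x + size]
        if (sub == BACKGROUND_LABEL).any():
            continue
        majority, purity, n_classes = _crop_stats(sub)
        if purity_mode == "pure" and purity < purity_threshold:
            continue
        if purity_mode == "boundary_mixed" and n_classes < 2:
            continue
        crop = slide.image[y:y + size, x:x + size].copy()
        out.append(LargePatch(crop, sub.copy(), majority, purity, x, y))
    return out


def _pure_positions(mask: np.ndarray, class_id: int, size: int) -> np.ndarray:
    """All top-left (x, y) whose size x size crop is entirely `class_id`.

    Uses a summed-area table over the class indicator, so the check is exact.
    """
    ind = (mask == class_id).astype(np.int64)
    sat = np.zeros((ind.shape[0] + 1, ind.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = ind.cumsum(0).cumsum(1)
    h, w = mask.shape
    if h < size or w < size:
        return np.empty((0, 2), dtype=np.int64)
    counts = (sat[size:, size:] - sat[:-size, size:]
              - sat[size:, :-size] + sat[:-size, :-size])
    ys, xs = np.nonzero(counts == size * size)
    return np.column_stack([xs, ys])


def make_labeled_patch_dataset(slides: list[SyntheticSlide], patch_size: int,
                               per_class: int, seed: int,
                               split_slides: dict[str, list[int]] | None = None
                               ) -> PatchDataset:
    """Balanced class-pure labelled patches with a slide-disjoint split.

    Slides are partitioned into train/val/test (roughly 5:1:2 by default,
    echoing a by-case split where evaluation patches come from slides the
    model never saw); `per_class` patches of each class are drawn in total,
    allocated to splits in proportion to their slide counts.  Labels are the
    (single) class covering the patch, so they agree with the mask majority
    by construction.
    """
    if per_class < 1:
        raise ParameterError("per_class must be >= 1")
    n_slides = len(slides)
    if split_slides is None:
        if n_slides < 3:
            raise ParameterError("need at least 3 slides for a 3-way split")
        order = list(np.random.default_rng(seed).permutation(n_slides))
        n_test = max(1, round(n_slides * 0.25))
        n_val = max(1, round(n_slides * 0.125))
        split_slides = {
            "test": order[:n_test],
            "val": order[n_test:n_test + n_val],
            "train": order[n_test + n_val:],
        }
    class_ids = sorted({s.class_id for sl in slides for s in sl.library})
    rng = np.random.default_rng([seed, 104729])

    # allocate per_class across splits exactly (largest-remainder rounding)
    names = sorted(split_slides, key=lambda k: -len(split_slides[k]))
    total_split = sum(len(v) for v in split_slides.values())
    quota = {k: per_class * len(split_slides[k]) / total_split for k in names}
    alloc = {k: int(quota[k]) for k in names}
    for k in sorted(names, key=lambda k: quota[k] - alloc[k], reverse=True):
        if sum(alloc.values()) >= per_class:
            break
        alloc[k] += 1

    splits: dict[str, dict] = {}
    for split, idxs in split_slides.items():
        want = alloc[split]
        xs, ys, sids, origins = [], [], [], []
        for class_id in class_ids if want else []:
            pools = []
            for i in idxs:
                pos = _pure_positions(slides[i].label_mask, class_id, patch_size)
                if len(pos):
                    pools.append((i, pos))
            if not pools:
                raise DataError(
                    f"class {class_id} absent from slides of split {split!r}")
            for _ in range(want):
                i, pos = pools[rng.integers(0, len(pools))]
                x, y = pos[rng.integers(0, len(pos))]
                xs.append(slides[i].image[y:y + patch_size, x:x + patch_size])
                ys.append(class_id)
                sids.append(slides[i].slide_id)
                origins.append((i, int(x), int(y)))
        stacked = (np.stack(xs).astype(np.uint8) if xs
                   else np.empty((0, patch_size, patch_size, 3), dtype=np.uint8))
        splits[split] = {
            "X": stacked,
            "y": np.array(ys, dtype=np.int64),
            "slide_ids": np.array(sids),
            "origins": np.array(origins, dtype=np.int64).reshape(-1, 3),
        }
    return PatchDataset(splits=splits, patch_size=patch_size, class_ids=class_ids)
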