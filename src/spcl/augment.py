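"""Stochastic view generation, Aug(.).

The augmentation stack follows the SimCLR-family convention adapted to
histology: random resized crop, horizontal and vertical flips (tissue has no
canonical orientation), colour jitter, random grayscale and Gaussian blur.
Views come out as float32 RGB in [0, 1] at a fixed output size.  Each
augmenter owns a seeded RNG stream, so a fresh augmenter with the same seed
replays the same stochastic choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import gaussian
from skimage.transform import resize

from .errors import ParameterError

__all__ = ["AugmentConfig", "Augmenter", "make_augmenter", "augment_views"]


@dataclass(frozen=True)
class AugmentConfig:
    crop_scale_range: tuple[float, float] = (0.5, 1.0)   # area fraction
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    color_jitter: tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.1)
    color_jitter_p: float = 0.8
    grayscale_p: float = 0.2
    blur_p: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.1, 1.0)
    out_size: int = 32
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ParameterError("crop_scale_range must satisfy 0 < lo <= hi <= 1")
        for name in ("hflip_p", "vflip_p", "color_jitter_p", "grayscale_p", "blur_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.out_size < 8:
            raise ParameterError("out_size must be >= 8")

    @property
    def is_noop(self) -> bool:
        return (self.crop_scale_range == (1.0, 1.0)
                and self.hflip_p == 0 and self.vflip_p == 0
                and self.color_jitter_p == 0 and self.grayscale_p == 0
                and self.blur_p == 0)


_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float64)


class Augmenter:
    """Callable image -> view; owns the RNG stream declared by its config."""

    def __init__(self, config: AugmentConfig):
        self.config = config
        self.reseed(config.seed)

    def reseed(self, seed) -> None:
        self.rng = np.random.default_rng(seed)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        cfg = self.config
        rng = self.rng
        img = np.asarray(image)
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        else:
            img = img.astype(np.float32)
        h, w = img.shape[:2]

        # random resized crop (square aspect)
        lo, hi = cfg.crop_scale_range
        scale = rng.uniform(lo, hi)
        side = max(1, int(round(np.sqrt(scale) * min(h, w))))
        x = int(rng.integers(0, w - side + 1))
        y = int(rng.integers(0, h - side + 1))
        img = img[y:y + side, x:x + side]
        if side != cfg.out_size:
            img = resize(img, (cfg.out_size, cfg.out_size),
                         order=1, anti_aliasing=side > cfg.out_size,
                         preserve_range=True).astype(np.float32)

        if rng.random() < cfg.hflip_p:
            img = img[:, ::-1]
        if rng.random() < cfg.vflip_p:
            img = img[::-1, :]

        if cfg.color_jitter_p and rng.random() < cfg.color_jitter_p:
            img = self._jitter(img, rng)

        if cfg.grayscale_p and rng.random() < cfg.grayscale_p:
            gray = (img @ _LUMA).astype(np.float32)
            img = np.repeat(gray[..., None], 3, axis=2)

        if cfg.blur_p and rng.random() < cfg.blur_p:
            sigma = rng.uniform(*cfg.blur_sigma_range)
            img = gaussian(img, sigma=sigma, channel_axis=2,
                           preserve_range=True).astype(np.float32)

        return np.clip(np.ascontiguousarray(img), 0.0, 1.0).astype(np.float32)

    def _jitter(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        b, c, s, hue = self.config.color_jitter
        out = img.astype(np.float64)
        if b:
            out = out * rng.uniform(1 - b, 1 + b)
        if c:
            mean = (out @ _LUMA).mean()
            out = (out - mean) * rng.uniform(1 - c, 1 + c) + mean
        if s:
            gray = (out @ _LUMA)[..., None]
            out = gray + (out - gray) * rng.uniform(1 - s, 1 + s)
        if hue:
            shift = rng.uniform(-hue, hue)
            hsv = rgb2hsv(np.clip(out, 0, 1))
            hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
            out = hsv2rgb(hsv)
        return np.clip(out, 0.0, 1.0).astype(np.float32)


def make_augmenter(config: AugmentConfig) -> Augmenter:
    """Build the Aug(.) callable for a config (validates on construction)."""
    return Augmenter(config)


def augment_views(patch: np.ndarray, augmenter: Augmenter, k: int) -> list[np.ndarray]:
    """k independent stochastic views of one patch; k must be 1 or 2."""
    if k not in (1, 2):
        raise ParameterError("k must be 1 (single branch) or 2 (dual branch)")
    return [augmenter(patch) for _ in range(k)]
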