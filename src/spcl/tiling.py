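"""Tissue masking and sliding-window tile extraction.

A slide is reduced to a boolean tissue mask by Otsu thresholding of its
luminance (stained tissue is darker than the white slide background), then
scanned row-major with a fixed stride; tiles whose tissue fraction clears a
cutoff are recorded in a manifest.  With stride equal to the tile size the
tiles are pairwise disjoint, which is how both the small (128 px) and large
(512 px) pretraining tile sets are built at full scale.

Coordinates are 0-based with half-open boxes [x, x+size) x [y, y+size).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BoundsError, DegenerateHistogramError, ManifestParseError, ParameterError,
)

__all__ = [
    "TissueMask", "TileRecord", "TileManifest", "rgb_to_luminance",
    "otsu_threshold", "compute_otsu_mask", "sliding_window_tiles", "extract_tile",
    "write_manifest", "read_manifest",
]


@dataclass
class TissueMask:
    mask: np.ndarray           # (H, W) bool, True = tissue
    threshold: float           # grayscale value in [0, 255]
    source_id: str = "slide"

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class TileRecord:
    slide_id: str
    x: int
    y: int
    size: int
    tissue_fraction: float

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ParameterError("tile coordinates must be non-negative")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ParameterError("tissue_fraction must lie in [0, 1]")


@dataclass
class TileManifest:
    records: list[TileRecord]
    tile_size: int
    stride: int
    slides: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (isinstance(other, TileManifest)
                and self.tile_size == other.tile_size
                and self.stride == other.stride
                and tuple(self.slides) == tuple(other.slides)
                and list(self.records) == list(other.records))


def rgb_to_luminance(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an RGB uint8 image, rounded back to uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("expected an (H, W, 3) RGB image")
    y = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> float:
    """Otsu's threshold over the 256-bin histogram of 8-bit values.

    Maximises the between-class variance w0*w1*(mu0-mu1)^2 of the split
    {<= t} vs {> t}, computed in closed form over all 256 cut points.  When
    several thresholds tie (the variance is flat across empty bins, e.g. for
    a two-delta histogram), the midpoint of the maximal plateau is returned,
    so the threshold sits between the modes rather than on one of them.
    """
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    values = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum_mean = np.cumsum(hist * values)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (cum_mean[-1] - cum_mean) / w1
        variance = w0 * w1 * (mu0 - mu1) ** 2
    variance = np.nan_to_num(variance, nan=-1.0)
    best = variance.max()
    if best <= 0:
        raise DegenerateHistogramError("no threshold separates the histogram")
    plateau = np.flatnonzero(variance == best)
    return float((plateau[0] + plateau[-1]) // 2)


def compute_otsu_mask(image: np.ndarray, source_id: str = "slide",
                      invert: bool = False) -> TissueMask:
    """Otsu-threshold the luminance histogram and keep the dark side as tissue.

    The threshold maximises between-class variance of the 8-bit histogram;
    pixels with luma <= threshold are tissue (H&E on a white background),
    unless `invert` flips the polarity for light-on-dark imagery.
    """
    if np.asarray(image).size == 0:
        raise ParameterError("empty image")
    gray = rgb_to_luminance(image)
    if gray.min() == gray.max():
        raise DegenerateHistogramError(
            f"constant image (value {int(gray.min())}): no threshold separates classes")
    t = otsu_threshold(gray)
    tissue = gray > t if invert else gray <= t
    return TissueMask(mask=tissue, threshold=t, source_id=source_id)


def sliding_window_tiles(mask: TissueMask, tile_size: int, stride: int,
                         min_tissue_fraction: float = 0.5) -> TileManifest:
    """Row-major sliding-window scan keeping tiles with enough tissue.

    Partial tiles at the right/bottom edge are discarded; on a full-tissue
    mask the count is (floor((H-t)/stride)+1) * (floor((W-t)/stride)+1).
    Tissue fractions are computed exactly via a summed-area table.
    """
    h, w = mask.mask.shape
    if tile_size > min(h, w):
        raise ParameterError(f"tile_size {tile_size} exceeds mask {w}x{h}")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = mask.mask.astype(np.int64).cumsum(0).cumsum(1)
    area = tile_size * tile_size
    records = []
    for y in range(0, h - tile_size + 1, stride):
        for x in range(0, w - tile_size + 1, stride):
            s = (sat[y + tile_size, x + tile_size] - sat[y, x + tile_size]
                 - sat[y + tile_size, x] + sat[y, x])
            frac = s / area
            if frac >= min_tissue_fraction:
                records.append(TileRecord(mask.source_id, x, y, tile_size, float(frac)))
    return TileManifest(records=records, tile_size=tile_size, stride=stride,
                        slides=(mask.source_id,))


def extract_tile(image: np.ndarray, record: TileRecord) -> np.ndarray:
    """Exact pixel crop for a tile record; errors if the box leaves the image."""
    h, w = image.shape[:2]
    if record.x + record.size > w or record.y + record.size > h:
        raise BoundsError(
            f"tile ({record.x}, {record.y}, {record.size}) exceeds image {w}x{h}")
    return image[record.y:record.y + record.size,
                 record.x:record.x + record.size].copy()


_COLUMNS = ["slide_id", "x", "y", "size", "tissue_fraction"]


def write_manifest(manifest: TileManifest, path) -> None:
    """Write a manifest as CSV; tile geometry rides in '#' header comments.

    Tissue fractions are written with repr so the round-trip is value-exact.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# tile_size={manifest.tile_size}\n")
        fh.write(f"# stride={manifest.stride}\n")
        fh.write(f"# slides={','.join(manifest.slides)}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in manifest.records:
            writer.writerow([r.slide_id, r.x, r.y, r.size, repr(r.tissue_fraction)])


def read_manifest(path) -> TileManifest:
    meta = {"tile_size": None, "stride": None, "slides": ()}
    records: list[TileRecord] = []
    with open(path, newline="") as fh:
        header_seen = False
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key in ("tile_size", "stride"):
                    meta[key] = int(value)
                elif key == "slides":
                    meta["slides"] = tuple(v for v in value.split(",") if v)
                continue
            row = next(csv.reader([line]))
            if not header_seen:
                if row != _COLUMNS:
                    raise ManifestParseError(line_no, f"unexpected header {row!r}")
                header_seen = True
                continue
            try:
                records.append(TileRecord(
                    slide_id=row[0], x=int(row[1]), y=int(row[2]),
                    size=int(row[3]), tissue_fraction=float(row[4])))
            except (IndexError, ValueError, ParameterError) as exc:
                raise ManifestParseError(line_no, str(exc)) from exc
    if meta["tile_size"] is None or meta["stride"] is None:
        raise ManifestParseError(0, "missing tile_size/stride header comments")
    return TileManifest(records=records, tile_size=meta["tile_size"],
                        stride=meta["stride"], slides=meta["slides"])
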