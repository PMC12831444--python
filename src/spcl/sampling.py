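"""Sample-positive batch construction.

The sampling module Sam(.) draws M small patches from each of N large
patches.  Small patches from the same large patch are declared positives of
one another — the spatial-adjacency prior — and everything from a different
large patch is a negative.  Per anchor this yields 2M-1 positives and
2M(N-1) negatives in the dual-branch (two augmentations per crop) setting,
and M-1 / M(N-1) in the single-branch setting.

Two placement modes exist: overlapping (independent uniform boxes) and
non-overlapping (pairwise-disjoint boxes found by rejection sampling;
adjacency is allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SamplingExhaustedError

__all__ = [
    "SamplerConfig", "SPBatch", "PairIndex", "sample_boxes", "build_batch",
    "pair_counts", "build_pair_index",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Geometry and mode of the Sam(.) module."""

    large_size: int            # L, px
    small_size: int            # s, px
    M: int = 4                 # small patches per large patch
    mode: str = "overlapping"  # or "nonoverlapping"
    max_attempts: int = 100    # rejection budget per box (nonoverlapping)
    seed: int = 0

    def __post_init__(self):
        if self.small_size > self.large_size:
            raise ParameterError("small_size must not exceed large_size")
        if self.M < 2:
            raise ParameterError("M must be >= 2 (each anchor needs a sampled positive)")
        if self.mode not in ("overlapping", "nonoverlapping"):
            raise ParameterError(f"unknown sampling mode {self.mode!r}")
        if self.max_attempts < 1:
            raise ParameterError("max_attempts must be >= 1")


@dataclass
class SPBatch:
    """Augmented views tagged with the index of their source large patch."""

    views: np.ndarray          # (n_views, out, out, 3) float32
    group_ids: np.ndarray      # (n_views,) int
    branch_mode: str           # "single" | "dual"
    M: int
    N: int
    aug_set: np.ndarray | None = None   # (n_views,) 0/1, dual mode only

    def __len__(self) -> int:
        return len(self.group_ids)


@dataclass
class PairIndex:
    """Per-anchor positive sets P(i) and candidate sets A(i) = I \\ {i}."""

    n: int
    positives: list[np.ndarray]          # P(i), indices
    pos_mask: np.ndarray = field(repr=False, default=None)  # (n, n) bool

    def candidates(self, i: int) -> np.ndarray:
        return np.delete(np.arange(self.n), i)


def _boxes_disjoint(a: tuple[int, int], b: tuple[int, int], s: int) -> bool:
    """Half-open s x s boxes at top-left a and b have empty intersection."""
    ax, ay = a
    bx, by = b
    return ax + s <= bx or bx + s <= ax or ay + s <= by or by + s <= ay


def sample_boxes(config: SamplerConfig,
                 rng: np.random.Generator | None = None) -> list[tuple[int, int, int]]:
    """Place M small boxes inside one large patch.

    Overlapping mode draws positions independently and uniformly on the
    pixel grid [0, L-s]^2.  Non-overlapping mode resamples each colliding
    box up to `max_attempts` times until it is disjoint from all accepted
    boxes (touching edges is allowed); configurations with M*s^2 > L^2 are
    rejected as infeasible before any sampling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, s, m = config.large_size, config.small_size, config.M
    hi = L - s + 1
    if config.mode == "nonoverlapping" and m * s * s > L * L:
        raise ParameterError(
            f"infeasible non-overlapping config: {m} boxes of {s}px "
            f"exceed the {L}px patch area")
    boxes: list[tuple[int, int]] = []
    for _ in range(m):
        if config.mode == "overlapping":
            boxes.append((int(rng.integers(0, hi)), int(rng.integers(0, hi))))
            continue
        for attempt in range(config.max_attempts):
            cand = (int(rng.integers(0, hi)), int(rng.integers(0, hi)))
            if all(_boxes_disjoint(cand, b, s) for b in boxes):
                boxes.append(cand)
                break
        else:
            raise SamplingExhaustedError("nonoverlapping", config.max_attempts)
    return [(x, y, s) for x, y in boxes]


def build_batch(large_patches, config: SamplerConfig, augmenter,
                branch_mode: str = "dual",
                rng: np.random.Generator | None = None) -> SPBatch:
    """Sample, crop and augment a group-labelled batch from N large patches.

    Dual mode augments every crop twice (2MN views); single mode once (MN
    views).  View order is shuffled — group ids and augmentation-set tags
    stay aligned — so group structure does not interact with batch-statistic
    layers downstream.
    """
    n = len(large_patches)
    if n < 2:
        raise ParameterError("need N >= 2 large patches so negatives exist")
    if branch_mode not in ("single", "dual"):
        raise ParameterError(f"unknown branch_mode {branch_mode!r}")
    L = config.large_size
    for p in large_patches:
        if p.shape[0] != L or p.shape[1] != L:
            raise ParameterError(
                f"large patch of shape {p.shape[:2]} does not match L={L}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    views, groups, sets = [], [], []
    k = 2 if branch_mode == "dual" else 1
    for g, patch in enumerate(large_patches):
        for (x, y, s) in sample_boxes(config, rng):
            crop = patch[y:y + s, x:x + s]
            for j in range(k):
                views.append(augmenter(crop))
                groups.append(g)
                sets.append(j)
    order = rng.permutation(len(views))
    batch_views = np.stack([views[i] for i in order])
    return SPBatch(
        views=batch_views,
        group_ids=np.array(groups, dtype=np.int64)[order],
        branch_mode=branch_mode, M=config.M, N=n,
        aug_set=np.array(sets, dtype=np.int64)[order] if k == 2 else None)


def pair_counts(M: int, N: int, branch_mode: str) -> tuple[int, int]:
    """Positives and negatives per anchor: dual (2M-1, 2M(N-1)); single (M-1, M(N-1))."""
    if M < 2 or N < 2:
        raise ParameterError("pair counts require M >= 2 and N >= 2")
    if branch_mode == "dual":
        return 2 * M - 1, 2 * M * (N - 1)
    if branch_mode == "single":
        return M - 1, M * (N - 1)
    raise ParameterError(f"unknown branch_mode {branch_mode!r}")


def build_pair_index(batch: SPBatch) -> PairIndex:
    """Derive P(i) (same group, excluding self) and A(i) (everything else)."""
    return pair_index_from_groups(batch.group_ids)


def pair_index_from_groups(group_ids: np.ndarray) -> PairIndex:
    g = np.asarray(group_ids)
    n = len(g)
    same = g[:, None] == g[None, :]
    np.fill_diagonal(same, False)
    positives = [np.nonzero(same[i])[0] for i in range(n)]
    return PairIndex(n=n, positives=positives, pos_mask=same)
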