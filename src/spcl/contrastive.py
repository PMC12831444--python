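"""Contrastive core: SupCon loss over sample-positive groups and four
framework variants (SPSimCLR, SPMoCo-v3, SPSimSiam, SinCLR).

The objective is the supervised-contrastive loss applied to pseudo-labels
induced by the sampling module: views that share a source large patch share
a "label".  For anchor i with positive set P(i) and candidate set
A(i) = I \\ {i},

    L = sum_i  -1/|P(i)| sum_{p in P(i)} log  exp(z_i . z_p / tau)
                                             ----------------------------
                                             sum_{a in A(i)} exp(z_i . z_a / tau)

with z the L2-normalised projection-head outputs and tau > 0 a temperature.
With exactly one positive per anchor this reduces to InfoNCE.

Variants: SPSimCLR embeds all views with one shared network; SPMoCo-v3 keeps
a momentum (EMA) target network and contrasts online embeddings of one
augmentation set against target embeddings of the other, symmetrised;
SPSimSiam predicts stop-gradient embeddings of its positives (negative
cosine, no negatives); SinCLR is the single-branch variant — one
augmentation per crop, same loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (
    ConfigurationError, DataError, NumericalFailureError, ParameterError,
    StructureError,
)
from .sampling import PairIndex, SamplerConfig, SPBatch, build_batch, build_pair_index
from .augment import Augmenter

__all__ = [
    "EmbeddingBatch", "LossConfig", "NetworkSpec", "SPNetworks",
    "MomentumState", "TrainConfig", "PretrainResult", "supcon_loss",
    "infonce_reduction_check", "build_networks", "forward_framework",
    "momentum_update", "pretrain", "encode", "save_checkpoint",
    "load_checkpoint",
]

FRAMEWORKS = ("spsimclr", "spmoco_v3", "spsimsiam", "sinclr")


@dataclass
class EmbeddingBatch:
    """Unit-norm projected representations aligned with group ids."""

    z: np.ndarray              # (n, d) float
    group_ids: np.ndarray      # (n,) int

    def __post_init__(self):
        if self.z.shape[0] != len(self.group_ids):
            raise StructureError("z and group_ids lengths differ")


@dataclass(frozen=True)
class LossConfig:
    tau: float = 0.1

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError("temperature tau must be > 0")


@dataclass(frozen=True)
class NetworkSpec:
    encoder_arch: str = "tiny_cnn"
    widths: tuple[int, ...] = (16, 32, 64, 128)
    proj_dim: int = 128
    predictor_hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.encoder_arch != "tiny_cnn":
            raise ConfigurationError(
                f"unsupported encoder arch {self.encoder_arch!r}; "
                "this build provides the tiny_cnn backbone")

    @property
    def feature_dim(self) -> int:
        return self.widths[-1]


class SPNetworks:
    """Encoder + projector (+ predictor for the SimSiam variant)."""

    def __init__(self, spec: NetworkSpec, framework: str):
        if framework not in FRAMEWORKS:
            raise ConfigurationError(f"unknown framework {framework!r}")
        self.spec = spec
        self.framework = framework
        d = spec.feature_dim
        self.encoder = nn.TinyCNN(seed=spec.seed, widths=spec.widths)
        self.projector = nn.MLP((d, d, spec.proj_dim), seed=spec.seed + 1)
        self.predictor = (
            nn.MLP((spec.proj_dim, spec.predictor_hidden, spec.proj_dim),
                   seed=spec.seed + 2)
            if framework == "spsimsiam" else None)

    def modules(self) -> list[nn.Module]:
        mods = [self.encoder, self.projector]
        if self.predictor is not None:
            mods.append(self.predictor)
        return mods

    def parameters(self):
        return [p for m in self.modules() for p in m.parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.train(mode)
        return self

    def project(self, x: nn.Tensor) -> nn.Tensor:
        return nn.l2_normalize(self.projector(self.encoder(x)))


@dataclass
class MomentumState:
    """EMA target network for the MoCo-style variant."""

    target_encoder: nn.Module
    target_projector: nn.Module
    m: float = 0.99

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError("momentum coefficient must lie in [0, 1]")

    def project(self, x: nn.Tensor) -> nn.Tensor:
        return nn.l2_normalize(self.target_projector(self.target_encoder(x)))


@dataclass(frozen=True)
class TrainConfig:
    framework: str = "sinclr"
    batch_N: int = 8           # large patches per step
    epochs: int = 5
    lr: float = 1e-3           # Adam, desk-scale backbone
    weight_decay: float = 0.0
    momentum_m: float = 0.99   # EMA coefficient (spmoco_v3)
    tau: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ConfigurationError(f"unknown framework {self.framework!r}")
        if self.batch_N < 2:
            raise ParameterError("batch_N must be >= 2")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")

    @property
    def branch_mode(self) -> str:
        return "single" if self.framework == "sinclr" else "dual"


@dataclass
class PretrainResult:
    """Trained encoder plus the input statistics needed to reuse it."""

    encoder: nn.Module
    input_mean: np.ndarray     # per-channel, view scale [0, 1]
    input_std: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    config: TrainConfig | None = None


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_tensor(z) -> nn.Tensor:
    return z if isinstance(z, nn.Tensor) else nn.Tensor(np.asarray(z, dtype=np.float64))


def _check_unit_norm(z: np.ndarray, tol: float = 1e-5) -> None:
    norms = np.linalg.norm(z, axis=1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise StructureError("embeddings must be unit-norm (within 1e-5)")


def supcon_loss(batch: EmbeddingBatch, pairs: PairIndex | None = None,
                cfg: LossConfig = LossConfig(), reduction: str = "sum") -> nn.Tensor:
    """Supervised-contrastive loss over the batch's group structure.

    `reduction` is "sum" (the equation's sum over anchors), "mean", or
    "none" (per-anchor vector).  Accepts `z` as a plain array or an autograd
    tensor; the return value is an autograd tensor either way, so the loss
    is differentiable with respect to the embeddings.
    """
    z = _as_tensor(batch.z)
    _check_unit_norm(z.data)
    if pairs is None:
        from .sampling import pair_index_from_groups
        pairs = pair_index_from_groups(batch.group_ids)
    pos_mask = pairs.pos_mask.astype(np.float64)
    pos_counts = pos_mask.sum(axis=1)
    if np.any(pos_counts == 0):
        raise StructureError("every anchor needs at least one positive")
    n = pairs.n
    not_self = 1.0 - np.eye(n)

    sim = (z @ z.T) * (1.0 / cfg.tau)
    # stabilised log-sum-exp over A(i): shift by the detached row max
    shifted = sim.data + np.log(not_self + 1e-300)   # -inf-ish on the diagonal
    row_max = shifted.max(axis=1, keepdims=True)
    expo = ((sim - row_max) * not_self).exp() * not_self
    lse = expo.sum(axis=1, keepdims=True).log() + row_max
    log_prob = sim - lse                              # (n, n)
    per_anchor = ((log_prob * pos_mask).sum(axis=1)) * (-1.0 / pos_counts)
    if reduction == "none":
        return per_anchor
    if reduction == "mean":
        return per_anchor.mean()
    if reduction == "sum":
        return per_anchor.sum()
    raise ParameterError(f"unknown reduction {reduction!r}")


def infonce_reduction_check(batch: EmbeddingBatch, cfg: LossConfig = LossConfig()
                            ) -> float:
    """SupCon evaluated on a batch whose anchors each have exactly one positive.

    Raises if any anchor has |P(i)| != 1; in that regime SupCon coincides
    with the InfoNCE cross-entropy (asserted independently in the tests).
    """
    from .sampling import pair_index_from_groups
    pairs = pair_index_from_groups(batch.group_ids)
    counts = pairs.pos_mask.sum(axis=1)
    if np.any(counts != 1):
        raise StructureError("InfoNCE reduction needs exactly one positive per anchor")
    return float(supcon_loss(batch, pairs, cfg).data)


def _cross_supcon(anchors: nn.Tensor, candidates: nn.Tensor,
                  groups_a: np.ndarray, groups_c: np.ndarray,
                  tau: float) -> nn.Tensor:
    """Mean SupCon where anchors and candidates live in different branches.

    No self-exclusion: the candidate pool is the other branch, so every
    same-group candidate (including the sibling view of the same crop) is a
    positive and the whole pool is A(i).
    """
    pos = (groups_a[:, None] == groups_c[None, :]).astype(np.float64)
    sim = (anchors @ candidates.T) * (1.0 / tau)
    row_max = sim.data.max(axis=1, keepdims=True)
    lse = ((sim - row_max).exp()).sum(axis=1, keepdims=True).log() + row_max
    log_prob = sim - lse
    per_anchor = (log_prob * pos).sum(axis=1) * (-1.0 / pos.sum(axis=1))
    return per_anchor.mean()


# ---------------------------------------------------------------------------
# frameworks
# ---------------------------------------------------------------------------

def build_networks(spec: NetworkSpec, framework: str) -> SPNetworks:
    return SPNetworks(spec, framework)


def make_momentum_state(nets: SPNetworks, m: float = 0.99) -> MomentumState:
    target_enc = nn.TinyCNN(seed=nets.spec.seed, widths=nets.spec.widths)
    target_enc.load_state_dict(nets.encoder.state_dict())
    d = nets.spec.feature_dim
    target_proj = nn.MLP((d, d, nets.spec.proj_dim), seed=nets.spec.seed + 1)
    target_proj.load_state_dict(nets.projector.state_dict())
    for mod in (target_enc, target_proj):
        mod.set_requires_grad(False)
    return MomentumState(target_encoder=target_enc, target_projector=target_proj, m=m)


def momentum_update(online: SPNetworks, state: MomentumState) -> MomentumState:
    """EMA update theta_t <- m * theta_t + (1 - m) * theta_o, parameter-wise.

    Batch-norm running statistics are copied from the online network so the
    target stays a usable inference-mode network.
    """
    pairs = [(online.encoder, state.target_encoder),
             (online.projector, state.target_projector)]
    m = state.m
    for online_mod, target_mod in pairs:
        o_params = dict(online_mod.named_parameters())
        t_params = dict(target_mod.named_parameters())
        if set(o_params) != set(t_params):
            raise StructureError("online/target parameter names differ")
        for name, tp in t_params.items():
            op = o_params[name]
            if tp.data.shape != op.data.shape:
                raise StructureError(f"shape mismatch for parameter {name}")
            tp.data = m * tp.data + (1.0 - m) * op.data
        o_bufs = dict(online_mod.named_buffers())
        for prefix, mod in target_mod._modules_by_prefix():
            for key in mod._buffers:
                mod._buffers[key] = o_bufs[prefix + key].copy()
    return state


def _views_to_nchw(views: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    arr = (views.astype(np.float64) - mean) / std
    return arr.transpose(0, 3, 1, 2)


def forward_framework(views: SPBatch, nets: SPNetworks, framework: str,
                      momentum: MomentumState | None = None,
                      loss_cfg: LossConfig = LossConfig(),
                      input_mean: np.ndarray | None = None,
                      input_std: np.ndarray | None = None,
                      ) -> tuple[EmbeddingBatch, nn.Tensor]:
    """One framework forward pass: embeddings plus differentiable loss.

    The branch mode of `views` must match the framework (sinclr is single-
    branch, the rest dual).  The returned EmbeddingBatch carries the online
    embeddings as plain arrays; the loss tensor holds the graph.
    """
    if framework not in FRAMEWORKS:
        raise ConfigurationError(f"unknown framework {framework!r}")
    expected = "single" if framework == "sinclr" else "dual"
    if views.branch_mode != expected:
        raise ConfigurationError(
            f"{framework} expects {expected}-branch batches, got {views.branch_mode}")
    mean = input_mean if input_mean is not None else np.zeros(3)
    std = input_std if input_std is not None else np.ones(3)
    x = nn.Tensor(_views_to_nchw(views.views, mean, std))

    if framework in ("spsimclr", "sinclr"):
        z = nets.project(x)
        pairs = build_pair_index(views)
        batch = EmbeddingBatch(z=z, group_ids=views.group_ids)
        loss = supcon_loss(batch, pairs, loss_cfg, reduction="mean")
        return EmbeddingBatch(z=z.data.copy(), group_ids=views.group_ids.copy()), loss

    if framework == "spmoco_v3":
        if momentum is None:
            raise ConfigurationError("spmoco_v3 requires a MomentumState")
        set0 = views.aug_set == 0
        set1 = ~set0
        x0 = nn.Tensor(_views_to_nchw(views.views[set0], mean, std))
        x1 = nn.Tensor(_views_to_nchw(views.views[set1], mean, std))
        g0 = views.group_ids[set0]
        g1 = views.group_ids[set1]
        q0 = nets.project(x0)
        q1 = nets.project(x1)
        k0 = momentum.project(x0).detach()
        k1 = momentum.project(x1).detach()
        tau = loss_cfg.tau
        loss = (_cross_supcon(q0, k1, g0, g1, tau)
                + _cross_supcon(q1, k0, g1, g0, tau)) * 0.5
        z_all = np.concatenate([q0.data, q1.data])
        groups_all = np.concatenate([g0, g1])
        return EmbeddingBatch(z=z_all, group_ids=groups_all), loss

    # spsimsiam: predict stop-gradient embeddings of every SP positive
    z = nets.project(x)
    p = nn.l2_normalize(nets.predictor(z))
    z_sg = z.detach()
    pairs = build_pair_index(views)
    pos = pairs.pos_mask.astype(np.float64)
    cos = p @ z_sg.T
    loss = -(cos * pos).sum() * (1.0 / pos.sum())
    return EmbeddingBatch(z=z.data.copy(), group_ids=views.group_ids.copy()), loss


# ---------------------------------------------------------------------------
# pretraining loop
# ---------------------------------------------------------------------------

def pretrain(large_patches, sampler_cfg: SamplerConfig, augmenter: Augmenter,
             net_spec: NetworkSpec, train_cfg: TrainConfig,
             degenerate_groups: bool = False) -> PretrainResult:
    """Self-supervised pretraining over sample-positive batches.

    Runs `epochs` passes over the large patches in a seeded random order,
    N at a time; each step samples M crops per patch, augments them, runs
    the framework forward and takes an Adam step.  The projector (and
    predictor) are discarded: only the encoder and the per-channel input
    statistics survive in the result, along with the per-step loss trace.

    `degenerate_groups` relabels every crop as its own group, which turns
    the dual-branch objective into the plain augmentation-pair contrastive
    baseline (SimCLR) on identical data — used for the ablation comparisons.
    """
    patches = list(large_patches)
    if len(patches) == 0:
        raise DataError("no large patches to pretrain on")
    if len(patches) < 2:
        raise DataError("need at least 2 large patches so negatives exist")
    if degenerate_groups and train_cfg.branch_mode == "single":
        raise ConfigurationError(
            "degenerate groups need dual-branch batches: a single view per "
            "crop would leave anchors without positives")
    rng = np.random.default_rng(train_cfg.seed)
    augmenter.reseed(int(rng.integers(0, 2 ** 31)))

    stack = np.stack(patches).astype(np.float64) / 255.0
    input_mean = stack.mean(axis=(0, 1, 2))
    input_std = stack.std(axis=(0, 1, 2)) + 1e-6

    spec = NetworkSpec(**{**net_spec.__dict__, "seed": int(rng.integers(0, 2 ** 31))})
    nets = build_networks(spec, train_cfg.framework)
    momentum = (make_momentum_state(nets, train_cfg.momentum_m)
                if train_cfg.framework == "spmoco_v3" else None)
    opt = nn.Adam(nets.parameters(), lr=train_cfg.lr,
                  weight_decay=train_cfg.weight_decay)
    loss_cfg = LossConfig(tau=train_cfg.tau)

    trace: list[float] = []
    step = 0
    nets.train(True)
    for _ in range(train_cfg.epochs):
        order = rng.permutation(len(patches))
        for start in range(0, len(patches) - train_cfg.batch_N + 1, train_cfg.batch_N):
            chunk = [patches[i] for i in order[start:start + train_cfg.batch_N]]
            if degenerate_groups:
                # one group per crop: only augmentation siblings are positives
                batch = _relabel_per_crop(chunk, sampler_cfg, augmenter,
                                          train_cfg.branch_mode, rng)
            else:
                batch = build_batch(chunk, sampler_cfg, augmenter,
                                    branch_mode=train_cfg.branch_mode, rng=rng)
            emb, loss = forward_framework(
                batch, nets, train_cfg.framework, momentum, loss_cfg,
                input_mean, input_std)
            if not np.isfinite(loss.data):
                raise NumericalFailureError(step)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if momentum is not None:
                momentum_update(nets, momentum)
            trace.append(float(loss.data))
            step += 1
    nets.train(False)
    return PretrainResult(encoder=nets.encoder, input_mean=input_mean,
                          input_std=input_std, loss_trace=trace,
                          config=train_cfg)


def _relabel_per_crop(chunk, sampler_cfg: SamplerConfig, augmenter: Augmenter,
                      branch_mode: str, rng: np.random.Generator) -> SPBatch:
    """Build a batch whose groups are individual crops (plain-SimCLR baseline)."""
    from .sampling import sample_boxes
    views, groups, sets = [], [], []
    k = 2 if branch_mode == "dual" else 1
    crop_id = 0
    for patch in chunk:
        for (x, y, s) in sample_boxes(sampler_cfg, rng):
            crop = patch[y:y + s, x:x + s]
            for j in range(k):
                views.append(augmenter(crop))
                groups.append(crop_id)
                sets.append(j)
            crop_id += 1
    order = rng.permutation(len(views))
    return SPBatch(
        views=np.stack([views[i] for i in order]),
        group_ids=np.array(groups, dtype=np.int64)[order],
        branch_mode=branch_mode, M=sampler_cfg.M, N=len(chunk),
        aug_set=np.array(sets, dtype=np.int64)[order] if k == 2 else None)


CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(result: PretrainResult, path) -> None:
    """Serialise encoder weights + input stats + config to a single .npz file."""
    import json

    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "feature_dim": result.encoder.feature_dim,
        "widths": [int(w.shape[0]) for name, w in
                   result.encoder.named_parameters() if name.endswith("weight")
                   and w.data.ndim == 4],
        "train_config": None if result.config is None else result.config.__dict__,
    }
    arrays = {f"enc.{k}": v for k, v in result.encoder.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        input_mean=result.input_mean, input_std=result.input_std,
        loss_trace=np.array(result.loss_trace), **arrays)


def load_checkpoint(path) -> PretrainResult:
    """Rebuild a PretrainResult saved by :func:`save_checkpoint`."""
    import json

    from . import nn as _nn

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise DataError(
                f"unsupported checkpoint format {meta['format_version']}")
        encoder = _nn.TinyCNN(seed=0, widths=tuple(meta["widths"]))
        encoder.load_state_dict({k[len("enc."):]: data[k] for k in data.files
                                 if k.startswith("enc.")})
        encoder.train(False)
        cfg = (TrainConfig(**meta["train_config"])
               if meta["train_config"] else None)
        return PretrainResult(encoder=encoder,
                              input_mean=data["input_mean"],
                              input_std=data["input_std"],
                              loss_trace=data["loss_trace"].tolist(),
                              config=cfg)


def encode(result: PretrainResult, patches: np.ndarray,
           batch_size: int = 256) -> np.ndarray:
    """Backbone features (pre-projection) for a stack of patches, eval mode.

    `patches` is (n, s, s, 3) uint8 or float-[0,1]; the result's stored
    input statistics are applied, so encodings are deterministic.
    """
    arr = np.asarray(patches)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    result.encoder.train(False)
    out = []
    for start in range(0, len(arr), batch_size):
        x = nn.Tensor(_views_to_nchw(arr[start:start + batch_size],
                                     result.input_mean, result.input_std))
        out.append(result.encoder(x).data)
    return np.concatenate(out) if out else np.empty((0, result.encoder.feature_dim))
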