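"""Network modules: conv/linear layers, batch norm, and the encoder/head stacks.

Parameter initialisation is He-normal and fully seeded, so two modules built
from the same seed are bit-identical — the determinism contracts of the
training loop lean on this.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, conv2d

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm", "ReLU", "Sequential",
    "GlobalAvgPool", "TinyCNN", "MLP", "l2_normalize",
]


class Module:
    """Base class: attribute-scanned parameter/buffer registry, train/eval mode."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- registry -------------------------------------------------------------

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in self._buffers.items():
            yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- state ---------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for prefix, module in self._modules_by_prefix():
            for key in module._buffers:
                module._buffers[key] = np.array(state[prefix + key], dtype=np.float64)

    def _modules_by_prefix(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children():
            yield from child._modules_by_prefix(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm(Module):
    """Batch normalisation over (N, C, H, W) or (N, C) input.

    Training mode normalises with batch statistics and updates exponential
    running estimates; eval mode uses the running estimates, so inference is
    deterministic regardless of batch composition.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.ndim == 4
        axes = (0, 2, 3) if spatial else (0,)
        shape = (1, -1, 1, 1) if spatial else (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(-1))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.reshape(-1))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
            centred = x - mu
        inv = (var + self.eps) ** -0.5
        gamma = self.gamma.reshape(shape)
        beta = self.beta.reshape(shape)
        return centred * inv * gamma + beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class TinyCNN(Module):
    """Four stride-2 conv/BN/ReLU blocks with global average pooling.

    The desk-scale encoder backbone: a 32x32 RGB view passes through feature
    maps of 16/8/4/2 px and comes out as a `feature_dim`-vector.
    """

    def __init__(self, seed: int = 0, widths: tuple[int, ...] = (16, 32, 64, 128)):
        super().__init__()
        rng = np.random.default_rng(seed)
        blocks: list[Module] = []
        in_ch = 3
        for w in widths:
            blocks += [Conv2d(in_ch, w, 3, rng, stride=2, padding=1), BatchNorm(w), ReLU()]
            in_ch = w
        blocks.append(GlobalAvgPool())
        self.layers = blocks
        self.feature_dim = widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """Linear stack with ReLU between layers and optional BN on hidden layers."""

    def __init__(self, widths: tuple[int, ...], seed: int = 0, batch_norm: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed)
        layers: list[Module] = []
        for i in range(len(widths) - 1):
            layers.append(Linear(widths[i], widths[i + 1], rng))
            if i < len(widths) - 2:
                if batch_norm:
                    layers.append(BatchNorm(widths[i + 1]))
                layers.append(ReLU())
        self.layers = layers
        self.out_dim = widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-wise L2 normalisation, differentiable."""
    sq = (z * z).sum(axis=1, keepdims=True)
    return z * ((sq + eps) ** -0.5)
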