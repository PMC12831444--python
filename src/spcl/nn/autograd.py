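"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records, for every produced
value, closures that push the upstream gradient to the operands.  The op set
is deliberately small — elementwise arithmetic, matmul, reductions, shape
ops, relu/exp/log and a strided 2-D convolution — which is all the encoder,
projection heads and contrastive losses in this package need.  Gradients are
exact (finite-difference checked in the test suite), broadcasting follows
numpy semantics, and ``detach`` implements the stop-gradient primitive that
the SimSiam-style framework relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _ensure(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- introspection --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad:
                    stack.append((parent, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        """Return a view of the same data cut off from the graph (stop-gradient)."""
        return Tensor(self.data)

    # -- elementwise arithmetic ------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._ensure(other)

        def backward(grad):
            self._accum(_unbroadcast(grad, self.shape))
            other._accum(_unbroadcast(grad, other.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad):
            self._accum(-grad)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._ensure(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._ensure(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._ensure(other)

        def backward(grad):
            self._accum(_unbroadcast(grad * other.data, self.shape))
            other._accum(_unbroadcast(grad * self.data, other.shape))

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * (Tensor._ensure(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._ensure(other) * (self ** -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out_data = self.data ** exponent

        def backward(grad):
            self._accum(grad * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(out_data, (self,), backward)

    # -- matmul ---------------------------------------------------------------

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._ensure(other)

        def backward(grad):
            self._accum(_unbroadcast(grad @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ grad, other.shape))

        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad):
            self._accum(grad * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad):
            self._accum(grad * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad):
            self._accum(grad / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    # -- reductions and shape ops ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(grad):
            self._accum(grad.reshape(old_shape))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(grad):
            self._accum(grad.transpose(inv))

        return Tensor._result(self.data.transpose(axes), (self,), backward)

    @property
    def T(self) -> "Tensor":
        return self.transpose()


class Parameter(Tensor):
    """A trainable tensor; modules collect these for their optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW input via im2col.

    ``weight`` has shape (out_ch, in_ch, kh, kw).  The backward pass scatters
    column gradients back with a kh*kw loop of strided slice additions, which
    is exact: within one (i, j) offset the strided windows are disjoint.
    """
    n, c, h, w = x.shape
    oc, ic, kh, kw = weight.shape
    if ic != c:
        raise ValueError(f"channel mismatch: input {c} vs weight {ic}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    wmat = weight.data.reshape(oc, -1)
    out_data = cols @ wmat.T                             # (n, ho*wo, oc)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 2, 1).reshape(n, oc, ho, wo)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad):
        g = grad.reshape(n, oc, ho * wo).transpose(0, 2, 1)   # (n, ho*wo, oc)
        if bias is not None:
            bias._accum(g.sum(axis=(0, 1)))
        weight._accum(np.tensordot(g, cols, axes=([0, 1], [0, 1])).reshape(weight.shape))
        if x.requires_grad:
            dcols = g @ wmat                                   # (n, ho*wo, c*kh*kw)
            dwin = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * stride:stride,
                        j:j + wo * stride:stride] += dwin[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)

    return Tensor._result(out_data, parents, backward)
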