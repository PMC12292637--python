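"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the operations applied to it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients.
Only the primitives the package's networks need are provided (elementwise
arithmetic with broadcasting, matmul, reductions, reshaping, SiLU/sigmoid/
tanh/ReLU, log-softmax, 2-D convolution, nearest-neighbour upsampling,
concatenation and zero-padding).

All data is float64: the networks here are desk-scale and exactness of
gradient checks matters more than throughput.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "log_softmax",
    "pad2d",
    "relu",
    "sigmoid",
    "silu",
    "softmax",
    "tanh",
    "upsample_nearest2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        """A view of the same values cut out of the autodiff graph."""
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            yield _unbroadcast(g, self.shape)
            yield _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            yield -g

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            yield _unbroadcast(g * other.data, self.shape)
            yield _unbroadcast(g * self.data, other.shape)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            yield _unbroadcast(g / other.data, self.shape)
            yield _unbroadcast(-g * self.data / other.data**2, other.shape)

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, out):
            yield g * exponent * self.data ** (exponent - 1)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            yield g @ other.data.T
            yield self.data.T @ g

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions and shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                yield np.broadcast_to(g, self.shape).copy()
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                yield np.broadcast_to(gg, self.shape).copy()

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, out):
            yield g.reshape(self.shape)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, out):
            yield g.transpose(inv)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- nonlinear primitives ------------------------------------------------

    def exp(self):
        def backward(g, out):
            yield g * out.data

        return Tensor._make(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            yield g / self.data

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            yield g / (2.0 * out.data)

        return Tensor._make(np.sqrt(self.data), (self,), backward)

    # -- autodiff driver -----------------------------------------------------

    def backward(self) -> None:
        """Accumulate ``grad`` on every reachable tensor; self must be scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (diffusion loops)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- free-function primitives ---------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, out):
        yield g * mask

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = _expit(x.data)

    def backward(g, out):
        yield g * s * (1.0 - s)

    return Tensor._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g, out):
        yield g * (1.0 - t * t)

    return Tensor._make(t, (x,), backward)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the activation used throughout the models here."""
    s = _expit(x.data)

    def backward(g, out):
        yield g * (s + x.data * s * (1.0 - s))

    return Tensor._make(x.data * s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logsum = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - logsum

    def backward(g, out):
        p = np.exp(out.data)
        yield g - p * g.sum(axis=axis, keepdims=True)

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        yield from np.split(g, splits, axis=axis)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two (spatial) axes of an (N, C, H, W) tensor."""
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]

    def backward(g, out):
        sl = tuple([slice(None)] * (x.ndim - 2) + [slice(pad, -pad)] * 2)
        yield g[sl]

    return Tensor._make(np.pad(x.data, width), (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of an (N, C, H, W) tensor."""
    up = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g, out):
        n, c, h, w = x.shape
        yield g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))

    return Tensor._make(up, (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of (N, C, H, W) input with (O, C, kh, kw) kernels.

    Implemented by an im2col lowering to a single matmul; the backward pass
    scatters window gradients back with one vectorized add per kernel tap.
    """
    n, c, _, _ = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ci}")
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, ho, wo, _, _ = windows.shape
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    w2 = w.data.reshape(o, -1)
    out = cols @ w2.T
    if b is not None:
        out = out + b.data.reshape(1, o)
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g, out_t):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        # input gradient: scatter each kernel tap back onto the padded grid
        gcols = (g2 @ w2).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gcols[
                    :, :, :, :, i, j
                ]
        if padding:
            gx = gxp[:, :, padding:-padding, padding:-padding]
        else:
            gx = gxp
        yield gx
        yield (g2.T @ cols).reshape(w.shape)
        if b is not None:
            yield g2.sum(axis=0)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)
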