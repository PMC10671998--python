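"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module is the numerical core the detector is built on: a small tape-based
autodiff engine providing exactly the primitives the model needs (dense
algebra, softmax/attention, layer normalization, strided 2-D convolution,
nearest-neighbour resampling, separable linear filters for the structural
similarity loss) plus Adam/AdamW optimizers.  Everything is float64 and
CPU-only; shapes are small (token grids, not megapixel images), so clarity is
favoured over throughput.

Gradients are accumulated by topological sort of the recorded graph.  All
primitives are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "softmax",
    "gelu",
    "layer_norm",
    "conv2d_same",
    "take",
    "uniform_filter_valid",
    "gaussian_blur",
    "Adam",
    "AdamW",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes numpy prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def erf(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * 2.0 / np.sqrt(np.pi) * np.exp(-self.data**2))

        return Tensor._make(_erf(self.data), (self,), backward)

    def maximum(self, other):
        """Elementwise max; on ties the gradient flows to `self`."""
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data >= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), backward)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor._make(self.data[key], (self,), backward)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def take(x: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Gather along an axis (numpy take); used for nearest-index resampling."""
    indices = np.asarray(indices, dtype=np.intp)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            key = [slice(None)] * x.data.ndim
            key[axis] = indices
            np.add.at(full, tuple(key), g)
            x._accum(full)

    return Tensor._make(np.take(x.data, indices, axis=axis), (x,), backward)


# ---------------------------------------------------------------------------
# composite nonlinearities


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtract a stop-gradient max for stability; it cancels in the ratio
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def gelu(x: Tensor) -> Tensor:
    """Gaussian Error Linear Unit, exact erf form."""
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / ((var + eps) ** 0.5) * gain + bias


# ---------------------------------------------------------------------------
# structured linear operators


def conv2d_same(x: Tensor, kernel: Tensor, bias: Tensor | None = None,
                stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), zero-padded so the output grid is
    ceil(H/stride) x ceil(W/stride).

    x: (H, W, C_in); kernel: (kh, kw, C_in, C_out); bias: (C_out,).
    """
    H, W, cin = x.data.shape
    kh, kw, kcin, cout = kernel.data.shape
    if kcin != cin:
        raise ValueError(f"kernel expects {kcin} input channels, image has {cin}")
    out_h = -(-H // stride)
    out_w = -(-W // stride)
    pad_h = max((out_h - 1) * stride + kh - H, 0)
    pad_w = max((out_w - 1) * stride + kw - W, 0)
    pt, pl = pad_h // 2, pad_w // 2
    xp = np.pad(x.data, ((pt, pad_h - pt), (pl, pad_w - pl), (0, 0)))

    out = np.zeros((out_h, out_w, cout))
    for a in range(kh):
        for b in range(kw):
            xs = xp[a:a + out_h * stride:stride, b:b + out_w * stride:stride, :]
            out += xs @ kernel.data[a, b]

    def backward(g):
        if kernel.requires_grad:
            dk = np.zeros_like(kernel.data)
            for a in range(kh):
                for b in range(kw):
                    xs = xp[a:a + out_h * stride:stride,
                            b:b + out_w * stride:stride, :]
                    dk[a, b] = np.einsum("ijc,ijo->co", xs, g)
            kernel._accum(dk)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    dxp[a:a + out_h * stride:stride,
                        b:b + out_w * stride:stride, :] += g @ kernel.data[a, b].T
            x._accum(dxp[pt:pt + H, pl:pl + W, :])

    parents = (x, kernel)
    res = Tensor._make(out, parents, backward)
    if bias is not None:
        res = res + bias
    return res


def _window_sum(x: np.ndarray, size: int) -> np.ndarray:
    """Valid sliding-window sum over the two leading axes."""
    c = np.cumsum(x, axis=0)
    c = np.vstack([np.zeros((1,) + x.shape[1:]), c])
    rows = c[size:] - c[:-size]
    c = np.cumsum(rows, axis=1)
    c = np.concatenate([np.zeros((rows.shape[0], 1) + x.shape[2:]), c], axis=1)
    return c[:, size:] - c[:, :-size]


def uniform_filter_valid(x: Tensor, size: int) -> Tensor:
    """Mean filter returning only fully-covered (valid) windows."""
    out = _window_sum(x.data, size) / (size * size)

    def backward(g):
        if x.requires_grad:
            gp = np.pad(g, ((size - 1, size - 1), (size - 1, size - 1)))
            x._accum(_window_sum(gp, size) / (size * size))

    return Tensor._make(out, (x,), backward)


def gaussian_blur(x: Tensor, sigma: float, truncate: float = 4.0) -> Tensor:
    """Gaussian filter with zero (constant) boundary; self-adjoint, so the
    backward pass is the same filter applied to the upstream gradient."""
    def blur(a):
        return ndimage.gaussian_filter(a, sigma=sigma, mode="constant",
                                       truncate=truncate)

    def backward(g):
        if x.requires_grad:
            x._accum(blur(g))

    return Tensor._make(blur(x.data), (x,), backward)


# ---------------------------------------------------------------------------
# optimizers


class Adam:
    """Adam with optional decoupled weight decay (AdamW when decay > 0 via
    the subclass) and global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW(Adam):
    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        super().__init__(params, lr=lr, betas=betas, eps=eps,
                         weight_decay=weight_decay)
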