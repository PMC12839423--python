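"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` records the
operation that produced it and a closure that routes the upstream gradient
to its inputs. It supports exactly the operations the detection blocks in
this package need — broadcast arithmetic, matmul, (grouped) 2-D
convolution, reductions, reshapes, concatenation, nearest-neighbour
upsampling and average pooling — in float64 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "relu",
    "gelu",
    "silu",
    "sigmoid",
    "softmax",
    "exp",
    "log",
    "sqrt",
    "arctan",
    "maximum",
    "minimum",
    "clip",
    "where",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # force `ndarray <op> Tensor` to defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def back(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def back(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p), "only scalar exponents are supported"

        def back(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), back)

    def __matmul__(self, other):
        other = as_tensor(other)

        def back(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), back)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def back(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)

    def __getitem__(self, idx):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), back)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise functions
# ---------------------------------------------------------------------------


def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.exp(t.data)

    def back(g):
        t._accum(g * out_data)

    return Tensor._make(out_data, (t,), back)


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)

    def back(g):
        t._accum(g / t.data)

    return Tensor._make(np.log(t.data), (t,), back)


def sqrt(t: Tensor) -> Tensor:
    return as_tensor(t) ** 0.5


def arctan(t: Tensor) -> Tensor:
    t = as_tensor(t)

    def back(g):
        t._accum(g / (1.0 + t.data * t.data))

    return Tensor._make(np.arctan(t.data), (t,), back)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0

    def back(g):
        t._accum(g * mask)

    return Tensor._make(t.data * mask, (t,), back)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = _sp.expit(t.data)

    def back(g):
        t._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (t,), back)


def gelu(t: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    t = as_tensor(t)
    x = t.data
    cdf = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))

    def back(g):
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        t._accum(g * (cdf + x * pdf))

    return Tensor._make(x * cdf, (t,), back)


def silu(t: Tensor) -> Tensor:
    return as_tensor(t) * sigmoid(t)


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    amax = a.data >= b.data

    def back(g):
        a._accum(g * amax)
        b._accum(g * (~amax))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), back)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    amin = a.data <= b.data

    def back(g):
        a._accum(g * amin)
        b._accum(g * (~amin))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), back)


def clip(t, lo, hi) -> Tensor:
    return minimum(maximum(t, lo), hi)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)

    def back(g):
        a._accum(g * cond)
        b._accum(g * (~cond))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), back)


def softmax(t: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Numerically stabilised softmax (max-shift, epsilon denominator)."""
    t = as_tensor(t)
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / (e.sum(axis=axis, keepdims=True) + eps)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
    )


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, C, Ho, Wo, k, k) strided view."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout, no bias.

    ``weight`` has shape (C_out, C_in // groups, k, k); depthwise convolution
    is ``groups == C_in`` with one filter per channel.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    k, s, p, g = kh, stride, padding, groups
    if C % g or Cout % g or C // g != Cin_g:
        raise ValueError(
            f"channel mismatch: input {C}, weight {weight.data.shape}, groups {g}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = _windows(xp, k, s)  # (B, C, Ho, Wo, k, k)
    Ho, Wo = win.shape[2], win.shape[3]
    wing = win.reshape(B, g, Cin_g, Ho, Wo, k, k)
    wg = weight.data.reshape(g, Cout // g, Cin_g, k, k)
    out_data = np.einsum("bgihwkl,goikl->bgohw", wing, wg, optimize=True)
    out_data = out_data.reshape(B, Cout, Ho, Wo)

    def back(gout):
        gout_g = gout.reshape(B, g, Cout // g, Ho, Wo)
        if weight.requires_grad:
            dw = np.einsum("bgihwkl,bgohw->goikl", wing, gout_g, optimize=True)
            weight._accum(dw.reshape(Cout, Cin_g, k, k))
        if x.requires_grad:
            dwin = np.einsum("bgohw,goikl->bgihwkl", gout_g, wg, optimize=True)
            dwin = dwin.reshape(B, C, Ho, Wo, k, k)
            dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + Ho * s:s, kj:kj + Wo * s:s] += dwin[..., ki, kj]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return Tensor._make(out_data, (x, weight), back)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError("spatial dims must be divisible by the pool size")
    r = x.data.reshape(B, C, H // k, k, W // k, k)
    out_data = r.mean(axis=(3, 5))

    def back(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)

    return Tensor._make(out_data, (x,), back)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)
    B, C, H, W = x.data.shape

    def back(g):
        r = g.reshape(B, C, H, scale, W, scale)
        x._accum(r.sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), back)
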