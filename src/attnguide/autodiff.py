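"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The training loop needs gradients of a composite objective (cross-entropy
plus a soft-IoU attention term built from class-activation maps) with
respect to every network parameter *and* the intermediate feature maps.
No deep-learning framework is assumed to be available at run time, so this
module provides a small, float64, single-threaded tape: enough operations
for strided convolutions, global pooling, linear heads, bilinear
upsampling, min-max normalisation and logistic/soft-IoU arithmetic.

Only the operations used by the package are implemented; each op stores a
closure that scatters the upstream gradient back to its parents.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "tsum",
    "tmean",
    "amin",
    "amax",
    "matmul",
    "conv2d",
    "upsample_bilinear",
    "cross_entropy",
    "bilinear_resize",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` so it matches ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
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

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor._from_op(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise functions
# ---------------------------------------------------------------------------

def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0
    out_data = np.where(mask, t.data, 0.0)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * mask)

    return Tensor._from_op(out_data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    # numerically stable logistic
    out_data = np.empty_like(t.data)
    pos = t.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-t.data[pos]))
    ez = np.exp(t.data[~pos])
    out_data[~pos] = ez / (1.0 + ez)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (t,), backward)


def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.exp(t.data)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * out_data)

    return Tensor._from_op(out_data, (t,), backward)


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.log(t.data)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g / t.data)

    return Tensor._from_op(out_data, (t,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = as_tensor(t)
    out_data = t.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not t.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % t.data.ndim for a in axes)
            shape = tuple(
                1 if i in axes else s for i, s in enumerate(t.data.shape)
            )
            g = g.reshape(shape)
        t._accumulate(np.broadcast_to(g, t.data.shape).copy())

    return Tensor._from_op(out_data, (t,), backward)


def tmean(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = as_tensor(t)
    if axis is None:
        n = t.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([t.data.shape[a] for a in axes]))
    return tsum(t, axis=axis, keepdims=keepdims) * (1.0 / n)


def _extremum(t: Tensor, fn) -> Tensor:
    t = as_tensor(t)
    val = fn(t.data)
    mask = t.data == val

    def backward(g):
        if t.requires_grad:
            # ties share the (sub)gradient equally
            t._accumulate(np.asarray(g) * mask / mask.sum())

    return Tensor._from_op(val, (t,), backward)


def amin(t: Tensor) -> Tensor:
    """Global minimum (subgradient split over ties)."""
    return _extremum(t, np.min)


def amax(t: Tensor) -> Tensor:
    """Global maximum (subgradient split over ties)."""
    return _extremum(t, np.max)


# ---------------------------------------------------------------------------
# linear algebra / network layers
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor._from_op(out_data, (a, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """2-D valid convolution (cross-correlation), NCHW layout."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    s = int(stride)
    ho = (h - kh) // s + 1
    wo = (wid - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s, :, :]  # (n, c, ho, wo, kh, kw)
    out_data = np.einsum("nchwij,fcij->nfhw", view, w.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                        "nfhw,fc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accumulate(dx)
        if w.requires_grad:
            w._accumulate(np.einsum("nfhw,nchwij->fcij", g, view, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out_data, parents, backward)


# ---------------------------------------------------------------------------
# bilinear resampling (shared by the array and tensor paths)
# ---------------------------------------------------------------------------

def _resize_grid(n_in: int, n_out: int):
    """align-corners sample positions; returns (i0, i1, frac)."""
    if n_out == 1 or n_in == 1:
        pos = np.zeros(n_out)
    else:
        pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.floor(pos).astype(np.intp)
    i0 = np.minimum(i0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, pos - i0


def bilinear_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D array with align-corners bilinear interpolation."""
    a = np.asarray(a, dtype=np.float64)
    hh, ww = shape
    y0, y1, fy = _resize_grid(a.shape[0], hh)
    x0, x1, fx = _resize_grid(a.shape[1], ww)
    fy = fy[:, None]
    fx = fx[None, :]
    top = a[np.ix_(y0, x0)] * (1 - fx) + a[np.ix_(y0, x1)] * fx
    bot = a[np.ix_(y1, x0)] * (1 - fx) + a[np.ix_(y1, x1)] * fx
    return top * (1 - fy) + bot * fy


def upsample_bilinear(t: Tensor, shape: tuple[int, int]) -> Tensor:
    """Differentiable 2-D bilinear resize (align corners)."""
    t = as_tensor(t)
    if t.data.ndim != 2:
        raise ValueError("upsample_bilinear expects a 2-D tensor")
    h_in, w_in = t.data.shape
    hh, ww = shape
    y0, y1, fy = _resize_grid(h_in, hh)
    x0, x1, fx = _resize_grid(w_in, ww)
    fy2 = fy[:, None]
    fx2 = fx[None, :]
    out_data = (
        t.data[np.ix_(y0, x0)] * (1 - fy2) * (1 - fx2)
        + t.data[np.ix_(y0, x1)] * (1 - fy2) * fx2
        + t.data[np.ix_(y1, x0)] * fy2 * (1 - fx2)
        + t.data[np.ix_(y1, x1)] * fy2 * fx2
    )

    def backward(g):
        if not t.requires_grad:
            return
        dt = np.zeros_like(t.data)
        yi0 = y0[:, None]
        yi1 = y1[:, None]
        xi0 = x0[None, :]
        xi1 = x1[None, :]
        np.add.at(dt, (yi0, xi0), g * (1 - fy2) * (1 - fx2))
        np.add.at(dt, (yi0, xi1), g * (1 - fy2) * fx2)
        np.add.at(dt, (yi1, xi0), g * fy2 * (1 - fx2))
        np.add.at(dt, (yi1, xi1), g * fy2 * fx2)
        t._accumulate(dt)

    return Tensor._from_op(out_data, (t,), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch.

    ``logits`` has shape (N, K); ``targets`` is an int array of class
    indices in [0, K).  Uses the log-sum-exp stabilisation.
    """
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.intp)
    n, k = logits.data.shape
    if targets.shape != (n,):
        raise ValueError("targets must have shape (N,)")
    if targets.min() < 0 or targets.max() >= k:
        raise ValueError("class index out of range")
    z = logits.data
    m = z.max(axis=1, keepdims=True)
    ez = np.exp(z - m)
    sez = ez.sum(axis=1, keepdims=True)
    log_probs = (z - m) - np.log(sez)
    loss = -log_probs[np.arange(n), targets].mean()
    softmax = ez / sez

    def backward(g):
        if logits.requires_grad:
            d = softmax.copy()
            d[np.arange(n), targets] -= 1.0
            logits._accumulate(float(g) * d / n)

    return Tensor._from_op(loss, (logits,), backward)
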