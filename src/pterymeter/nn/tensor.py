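"""Minimal reverse-mode automatic differentiation over numpy arrays.

Defines a :class:`Tensor` wrapping an ``ndarray`` together with the handful
of differentiable operations the segmentation networks need: broadcast
arithmetic, reductions, elementwise nonlinearities, channel concatenation,
3x3/1x1 convolution, 2x2 max pooling and fixed-matrix spatial resampling.
Gradients are accumulated by a topological backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "max_pool2", "upsample2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    # -- reductions -----------------------------------------------------------
    def sum(self):
        out = Tensor._make(self.data.sum(), (self,), None)
        out._backward = lambda g: (np.broadcast_to(g, self.data.shape),)
        return out

    def mean(self):
        n = self.data.size
        out = Tensor._make(self.data.mean(), (self,), None)
        out._backward = lambda g: (np.broadcast_to(g / n, self.data.shape),)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor._make(s, (self,), None)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def clip(self, lo: float, hi: float):
        clipped = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor._make(clipped, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- structural ops ----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor._make(data, tuple(tensors), None)
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patch matrix, stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 'same' convolution; ``weight`` is (F, C, k, k), ``bias`` (F,)."""
    f, c, k, _ = weight.data.shape
    pad = k // 2
    n, _, h, w = x.data.shape
    cols = _im2col(x.data, k, pad)                       # (N, Ck^2, HW)
    wmat = weight.data.reshape(f, c * k * k)
    y = np.matmul(wmat, cols) + bias.data[None, :, None]  # (N, F, HW)
    out = Tensor._make(y.reshape(n, f, h, w), (x, weight, bias), None)

    def backward(g):
        gm = g.reshape(n, f, h * w)
        dw = np.einsum("nfp,ncp->fc", gm, cols).reshape(weight.data.shape)
        db = gm.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, gm)
        dx = _col2im(dcols, x.data.shape, k, pad)
        return dx, dw, db

    out._backward = backward
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties share the gradient equally."""
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    out = Tensor._make(y, (x,), None)

    def backward(g):
        mask = xr == y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (g[:, :, :, None, :, None] / counts)
        return (dxr.reshape(n, c, h, w),)

    out._backward = backward
    return out


def _interp_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    """Row-stochastic 1-D resampling matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    if mode == "nearest":
        idx = np.clip(np.round(src).astype(int), 0, n_in - 1)
        m[np.arange(n_out), idx] = 1.0
    else:  # linear
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        m[np.arange(n_out), lo] += 1.0 - t
        m[np.arange(n_out), hi] += t
    return m


_INTERP_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _interp(n_out: int, n_in: int, mode: str) -> np.ndarray:
    key = (n_out, n_in, mode)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in, mode)
    return _INTERP_CACHE[key]


def upsample2(x: Tensor, mode: str = "bilinear") -> Tensor:
    """Double both spatial dimensions; exact linear operator, exact adjoint."""
    n, c, h, w = x.data.shape
    kind = "linear" if mode == "bilinear" else "nearest"
    mh = _interp(2 * h, h, kind).astype(x.data.dtype)
    mw = _interp(2 * w, w, kind).astype(x.data.dtype)
    y = np.matmul(np.matmul(mh, x.data), mw.T)
    out = Tensor._make(y, (x,), None)
    out._backward = lambda g: (np.matmul(np.matmul(mh.T, g), mw),)
    return out
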