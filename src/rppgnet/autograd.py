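"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in this package is small enough that a dedicated tensor engine —
a :class:`Tensor` wrapper plus the handful of primitives a 3-D convolutional
recurrent network needs (grouped convolution, elementwise nonlinearities,
reductions, shape ops) — is both sufficient and dependency-free.  Convolutions
are lowered to ``sliding_window_view`` + ``einsum`` so the heavy lifting runs
through BLAS.

Gradients are accumulated by a topological sweep from the loss; correctness is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "conv3d",
    "temporal_dilate",
    "pad3d",
    "gradcheck",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here can be thousands of nodes deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients: only leaves keep .grad
                if node._parents:
                    node.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other, dtype=self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, dtype=self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.shape)
                    )
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other, dtype=self.dtype) / self

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # ---------------------------------------------------------- nonlinearity
    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        y = np.clip(self.data, lo, hi)
        out = _make(y, (self,))
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def relu6(self) -> "Tensor":
        return self.clip(0.0, 6.0)

    def hswish(self) -> "Tensor":
        """x * relu6(x + 3) / 6 — the hard approximation of swish."""
        return self * (self + 3.0).relu6() * (1.0 / 6.0)

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        out = _make(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                gg = g
                if not keepdims and axis is not None:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = tuple(np.argsort(axes))
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g):
                gx = np.zeros_like(self.data)
                gx[idx] += g
                self._accumulate(gx)
            out._backward = bw
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.number):
        arr = arr.astype(dtype)
    return Tensor(arr)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def pad3d(x: Tensor, pad: tuple[int, int, int]) -> Tensor:
    """Zero-pad the trailing (T, H, W) axes of a (..., T, H, W) tensor."""
    pt, ph, pw = pad
    if pt == ph == pw == 0:
        return x
    spec = [(0, 0)] * (x.ndim - 3) + [(pt, pt), (ph, ph), (pw, pw)]
    out = _make(np.pad(x.data, spec), (x,))
    if out.requires_grad:
        sl = tuple(
            [slice(None)] * (x.ndim - 3)
            + [
                slice(pt, pt + x.shape[-3]),
                slice(ph, ph + x.shape[-2]),
                slice(pw, pw + x.shape[-1]),
            ]
        )
        out._backward = lambda g: x._accumulate(g[sl])
    return out


def temporal_dilate(x: Tensor, factor: int) -> Tensor:
    """Insert ``factor - 1`` zeros between consecutive temporal samples.

    Maps (B, C, T, H, W) to (B, C, (T-1)*factor + 1, H, W); used to express a
    strided transposed convolution as a dilation followed by a unit-stride
    convolution with the flipped kernel.
    """
    if factor == 1:
        return x
    B, C, T, H, W = x.shape
    data = np.zeros((B, C, (T - 1) * factor + 1, H, W), dtype=x.dtype)
    data[:, :, ::factor] = x.data
    out = _make(data, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g[:, :, ::factor])
    return out


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: tuple[int, int, int] = (1, 1, 1),
    padding: tuple[int, int, int] = (0, 0, 0),
    groups: int = 1,
) -> Tensor:
    """Grouped 3-D cross-correlation.

    x: (B, C, T, H, W); w: (N, C // groups, kt, kh, kw); b: (N,) or None.
    ``groups == C`` with ``N == C`` gives a depth-wise convolution,
    ``kt == kh == kw == 1`` a point-wise one.
    """
    B, C, T, H, W = x.shape
    N, Cg, kt, kh, kw = w.shape
    g = groups
    if C % g or N % g or Cg != C // g:
        raise ValueError(f"incompatible channel grouping: C={C}, N={N}, groups={g}")
    st, sh, sw = stride
    if (
        (kt, kh, kw) == (1, 1, 1)
        and stride == (1, 1, 1)
        and padding == (0, 0, 0)
    ):
        return _conv_pointwise(x, w, b, g)
    xp = pad3d(x, padding)
    xpd = xp.data
    v = sliding_window_view(xpd, (kt, kh, kw), axis=(2, 3, 4))
    v = v[:, :, ::st, ::sh, ::sw]
    To, Ho, Wo = v.shape[2:5]
    v = v.reshape(B, g, Cg, To, Ho, Wo, kt, kh, kw)
    wg = w.data.reshape(g, N // g, Cg, kt, kh, kw)
    out_data = np.einsum("bgcthwijk,gncijk->bgnthw", v, wg, optimize=True)
    out_data = out_data.reshape(B, N, To, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, N, 1, 1, 1)

    parents = (xp, w) if b is None else (xp, w, b)
    out = _make(np.ascontiguousarray(out_data), parents)
    if out.requires_grad:
        def bw(gout):
            go = gout.reshape(B, g, N // g, To, Ho, Wo)
            if b is not None and b.requires_grad:
                b._accumulate(gout.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                gw = np.einsum("bgcthwijk,bgnthw->gncijk", v, go, optimize=True)
                w._accumulate(gw.reshape(w.shape))
            if xp.requires_grad:
                contrib = np.einsum("bgnthw,gncijk->bgcthwijk", go, wg, optimize=True)
                gxp = np.zeros_like(xpd)
                gv = gxp.reshape(B, g, Cg, *xpd.shape[2:])
                for i in range(kt):
                    for j in range(kh):
                        for k in range(kw):
                            gv[
                                :, :, :,
                                i : i + st * To : st,
                                j : j + sh * Ho : sh,
                                k : k + sw * Wo : sw,
                            ] += contrib[..., i, j, k]
                xp._accumulate(gxp)
        out._backward = bw
    return out


def _conv_pointwise(x: Tensor, w: Tensor, b: Tensor | None, g: int) -> Tensor:
    """1x1x1 unit-stride convolution as a batched matmul (BLAS fast path)."""
    B, C, T, H, W = x.shape
    N = w.shape[0]
    Cg, Ng = C // g, N // g
    P = T * H * W
    xv = np.ascontiguousarray(x.data).reshape(B, g, Cg, P)
    wm = w.data.reshape(g, Ng, Cg)
    out_data = np.matmul(wm[None], xv)  # (B, g, Ng, P)
    out_data = out_data.reshape(B, N, T, H, W)
    if b is not None:
        out_data += b.data.reshape(1, N, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out.requires_grad:
        def bw(gout):
            go = gout.reshape(B, g, Ng, P)
            if b is not None and b.requires_grad:
                b._accumulate(gout.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                gw = np.matmul(go, xv.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.matmul(wm.transpose(0, 2, 1)[None], go)
                x._accumulate(gx.reshape(x.shape))
        out._backward = bw
    return out


def gradcheck(
    fn: Callable[..., Tensor],
    inputs: Iterable[Tensor],
    eps: float = 1e-5,
    rtol: float = 1e-3,
    atol: float = 1e-4,
) -> bool:
    """Compare analytic gradients of scalar ``fn(*inputs)`` with central
    finite differences.  Inputs must be float64 for meaningful comparison."""
    inputs = list(inputs)
    for t in inputs:
        t.zero_grad()
    out = fn(*inputs)
    out.backward()
    for t in inputs:
        if not t.requires_grad:
            continue
        analytic = t.grad if t.grad is not None else np.zeros_like(t.data)
        numeric = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        nflat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn(*inputs).item()
            flat[i] = orig - eps
            fm = fn(*inputs).item()
            flat[i] = orig
            nflat[i] = (fp - fm) / (2 * eps)
        if not np.allclose(analytic, numeric, rtol=rtol, atol=atol):
            return False
    return True
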