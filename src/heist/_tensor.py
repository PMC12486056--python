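"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the encoder, decoder and pretraining
objectives.  It implements exactly the operator set those components need:
broadcast-aware elementwise arithmetic, 2-D matmul, reductions, row
gather/scatter, and sorted-segment sums (the primitive behind sparse
graph attention).  Gradients are accumulated by walking the tape in
reverse topological order.

Arrays are float32 by default; index arrays are int64.  Scatter-adds for
large gathers go through a cached CSR selection matrix, which is an order
of magnitude faster than ``np.add.at`` at graph-attention sizes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

DTYPE = np.float32

__all__ = [
    "Tensor", "as_tensor", "parameter", "no_grad",
    "matmul", "bmm", "masked_attention", "exp", "log", "sqrt", "tanh",
    "sigmoid", "relu",
    "softplus", "tsum", "tmean", "reshape", "transpose", "take",
    "repeat_rows", "segment_sum", "concat", "square", "l2_normalize",
    "layer_norm", "Adam",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager: ops inside build no tape (forward values only)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


class Tensor:
    """A node in the autodiff tape wrapping a numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        if _GRAD_ENABLED:
            self._parents = parents
            self._backward = backward
            self.requires_grad = (requires_grad
                                  or any(p.requires_grad for p in parents))
        else:
            self._parents = ()
            self._backward = None
            self.requires_grad = False

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic sugar -------------------------------------------------
    def __add__(self, other):
        return _elementwise_add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _elementwise_mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return _elementwise_mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return as_tensor(other) * _reciprocal(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, c):
        return _powc(self, float(c))

    # -- backward pass ----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate grads/tape references as we go
            if node is not self and node._backward is not None:
                node._parents = ()
                node._backward = None

    def item(self):
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def parameter(data, rng=None, shape=None, scale=None) -> Tensor:
    """A leaf tensor that accumulates gradients.

    ``parameter(rng=rng, shape=(m, n))`` draws Glorot-scaled normal values.
    """
    if data is None:
        fan = shape[0] if len(shape) else 1
        s = scale if scale is not None else (1.0 / np.sqrt(max(fan, 1)))
        data = rng.standard_normal(shape) * s
    t = Tensor(np.asarray(data, dtype=DTYPE))
    t.requires_grad = True
    return t


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g, dtype=DTYPE), t.data.shape)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or g is t.data else g
    else:
        t.grad += g


# -- primitives -----------------------------------------------------------

def _elementwise_add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._backward = lambda g: (_accum(a, g), _accum(b, g))
    return out


def _elementwise_mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out._backward = lambda g: (_accum(a, g * b.data), _accum(b, g * a.data))
    return out


def _reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data
    out = Tensor(inv, (a,))
    out._backward = lambda g: _accum(a, -g * inv * inv)
    return out


def _powc(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data ** c, (a,))
    out._backward = lambda g: _accum(a, g * c * a.data ** (c - 1.0))
    return out


def square(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data * a.data, (a,))
    out._backward = lambda g: _accum(a, 2.0 * g * a.data)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def back(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = back
    return out


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Stacked matmul with numpy broadcasting over batch dimensions."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def back(g):
        if a.requires_grad:
            _accum(a, g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            _accum(b, np.swapaxes(a.data, -1, -2) @ g)

    out._backward = back
    return out


def masked_attention(q: Tensor, k: Tensor, v: Tensor, bias: np.ndarray,
                     scale: float) -> Tensor:
    """Fused softmax attention out = softmax(q kᵀ · scale + bias) v.

    Operates on stacked (..., n, dh) operands; ``bias`` is a constant
    additive mask (broadcastable).  Fusing keeps only the attention
    weights on the tape instead of every intermediate score tensor,
    which matters when n² is large.
    """
    qd = np.ascontiguousarray(q.data)
    kd = np.ascontiguousarray(k.data)
    vd = np.ascontiguousarray(v.data)
    s = qd @ kd.swapaxes(-1, -2)
    s *= scale
    s += bias
    s -= s.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=-1, keepdims=True)
    alpha = s
    out = Tensor(alpha @ vd, (q, k, v))

    def back(g):
        g = np.ascontiguousarray(g)
        if v.requires_grad:
            _accum(v, alpha.swapaxes(-1, -2) @ g)
        if q.requires_grad or k.requires_grad:
            ga = g @ vd.swapaxes(-1, -2)
            ga *= alpha
            ga -= alpha * ga.sum(axis=-1, keepdims=True)
            if q.requires_grad:
                _accum(q, (ga @ kd) * scale)
            if k.requires_grad:
                _accum(k, (ga.swapaxes(-1, -2) @ qd) * scale)

    out._backward = back
    return out


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    out = Tensor(e, (a,))
    out._backward = lambda g: _accum(a, g * e)
    return out


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), (a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def sqrt(a: Tensor) -> Tensor:
    a = as_tensor(a)
    r = np.sqrt(a.data)
    out = Tensor(r, (a,))
    out._backward = lambda g: _accum(a, g * 0.5 / np.maximum(r, 1e-12))
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))
    out._backward = lambda g: _accum(a, g * (1.0 - t * t))
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def softplus(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.logaddexp(0.0, a.data), (a,))
    s = 1.0 / (1.0 + np.exp(-a.data))
    out._backward = lambda g: _accum(a, g * s)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def back(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = back
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out._backward = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


def transpose(a: Tensor, axes=None) -> Tensor:
    out = Tensor(a.data.transpose(axes), (a,))
    inv = None if axes is None else np.argsort(axes)
    out._backward = lambda g: _accum(a, g.transpose(inv))
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = back
    return out


# scatter matrices are cached keyed by the identity of the index array;
# holding a reference to the array keeps the id valid.
_SCATTER_CACHE: dict = {}
_SCATTER_CACHE_MAX = 64


def _scatter_matrix(idx: np.ndarray, n_rows: int) -> sp.csr_matrix:
    key = (id(idx), n_rows)
    hit = _SCATTER_CACHE.get(key)
    if hit is not None:
        return hit[1]
    mat = sp.csr_matrix(
        (np.ones(idx.size, dtype=DTYPE), (idx, np.arange(idx.size))),
        shape=(n_rows, idx.size),
    )
    if len(_SCATTER_CACHE) >= _SCATTER_CACHE_MAX:
        _SCATTER_CACHE.clear()
    _SCATTER_CACHE[key] = (idx, mat)
    return mat


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``a[idx]`` along axis 0; backward is a scatter-add."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], (a,))
    n = a.data.shape[0]

    def back(g):
        if not a.requires_grad:
            return
        if idx.size * max(1, int(np.prod(g.shape[1:]))) > 200_000:
            mat = _scatter_matrix(idx, n)
            _accum(a, (mat @ g.reshape(idx.size, -1)).reshape((n,) + g.shape[1:]))
        else:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            _accum(a, acc)

    out._backward = back
    return out


def repeat_rows(a: Tensor, r: int) -> Tensor:
    """Repeat each row of ``a`` r times (np.repeat along axis 0)."""
    out = Tensor(np.repeat(a.data, r, axis=0), (a,))

    def back(g):
        _accum(a, g.reshape((a.data.shape[0], r) + a.data.shape[1:]).sum(axis=1))

    out._backward = back
    return out


def segment_sum(a: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Sum rows of ``a`` grouped by the *sorted* segment-id array ``seg``.

    ``seg`` must be non-decreasing; empty segments yield zero rows.
    Backward is a plain gather, which is what makes the sorted layout
    worth maintaining.
    """
    seg = np.asarray(seg, dtype=np.int64)
    out_data = np.zeros((n_seg,) + a.data.shape[1:], dtype=DTYPE)
    if seg.size:
        starts = np.searchsorted(seg, np.arange(n_seg))
        counts = np.diff(np.append(starts, seg.size))
        nonempty = counts > 0
        if nonempty.any():
            out_data[nonempty] = np.add.reduceat(a.data, starts[nonempty], axis=0)
    out = Tensor(out_data, (a,))
    out._backward = lambda g: _accum(a, g[seg])
    return out


def segment_max_const(x: np.ndarray, seg: np.ndarray, n_seg: int) -> np.ndarray:
    """Per-segment max of a plain array (no gradient; used for stable softmax)."""
    out = np.full((n_seg,) + x.shape[1:], -np.inf, dtype=x.dtype)
    if seg.size:
        starts = np.searchsorted(seg, np.arange(n_seg))
        counts = np.diff(np.append(starts, seg.size))
        nonempty = counts > 0
        if nonempty.any():
            out[nonempty] = np.maximum.reduceat(x, starts[nonempty], axis=0)
    return out


# -- composites -----------------------------------------------------------

def l2_normalize(a: Tensor, axis=-1, eps=1e-8) -> Tensor:
    nrm = sqrt(tsum(square(a), axis=axis, keepdims=True) + eps)
    return a / nrm


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps=1e-5) -> Tensor:
    mu = tmean(a, axis=-1, keepdims=True)
    xc = a - mu
    var = tmean(square(xc), axis=-1, keepdims=True)
    return xc / sqrt(var + eps) * gamma + beta


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, clip_norm=5.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.vdot(g, g)) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
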