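"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph classifiers in :mod:`fcgnn.models` are small (hundreds of nodes,
a few dense matrix products per layer), so a compact tape-based engine over
``numpy.ndarray`` is sufficient: every operation records its parents and a
closure that accumulates gradients into them. Only the operations those
models need are implemented. Gradients are checked against central finite
differences in the test suite.

Conventions
-----------
* ``Tensor.data`` is a ``float64`` ndarray (``float32`` is preserved for
  memory-bound evaluation passes); scalars are 0-d arrays.
* Broadcasting follows NumPy; backward passes sum gradients over broadcast
  axes (:func:`_unbroadcast`).
* ``no_grad()`` disables tape recording, used for evaluation-mode forward
  passes (and makes them allocation-light).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables gradient tape recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 expanded by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------
    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # operators are defined at module level and attached below


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    """Build a result tensor, recording the tape only when needed."""
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

    return _make(data, (a, b), bw)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), bw)


def matmul(a, b) -> Tensor:
    """Matrix product with NumPy batch-dimension broadcasting."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data**exponent

    def bw(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1))

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        a._accumulate(g * data)

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bw)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - data**2))

    return _make(data, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg_part = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    data = np.where(a.data > 0, a.data, neg_part)

    def bw(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, neg_part + alpha))

    return _make(data, (a,), bw)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    data = np.where(a.data > 0, a.data, slope * a.data)

    def bw(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, slope))

    return _make(data, (a,), bw)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.data.size / max(data.size, 1)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape) / denom)

    return _make(data, (a,), bw)


def tmax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Maximum over one axis; ties share the gradient equally."""
    a = _as_tensor(a)
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)
    out = data if keepdims else np.squeeze(data, axis=axis)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(g * mask)

    return _make(out, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        a._accumulate(p * (g - dot))

    return _make(p, (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(ts, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(data, ts, bw)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.data.shape

    def bw(g):
        a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), bw)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        a._accumulate(np.swapaxes(g, ax1, ax2))

    return _make(np.swapaxes(a.data, ax1, ax2), (a,), bw)


def gather_nodes(x, idx: np.ndarray) -> Tensor:
    """Select node rows: ``x`` is (B, N, F), ``idx`` is (B, K) -> (B, K, F).

    Backward scatter-adds into the selected rows (indices within one batch
    element are assumed distinct, as produced by top-k selection).
    """
    x = _as_tensor(x)
    B = x.data.shape[0]
    batch = np.arange(B)[:, None]
    data = x.data[batch, idx]

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (batch, idx), g)
        x._accumulate(gx)

    return _make(data, (x,), bw)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or ``p == 0``."""
    a = _as_tensor(a)
    if not training or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)

    def bw(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Numerically stable (log-sum-exp); gradient is ``(p - onehot) / B``.
    """
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    logp = z - lse
    B = z.shape[0]
    nll = -logp[np.arange(B), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(B), labels] -= 1.0
        logits._accumulate(g * p / B)

    return _make(np.asarray(nll), (logits,), bw)


# attach operator overloads
Tensor.__add__ = lambda self, o: add(self, o)
Tensor.__radd__ = lambda self, o: add(o, self)
Tensor.__sub__ = lambda self, o: sub(self, o)
Tensor.__rsub__ = lambda self, o: sub(o, self)
Tensor.__mul__ = lambda self, o: mul(self, o)
Tensor.__rmul__ = lambda self, o: mul(o, self)
Tensor.__truediv__ = lambda self, o: div(self, o)
Tensor.__rtruediv__ = lambda self, o: div(o, self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__matmul__ = lambda self, o: matmul(self, o)
Tensor.__rmatmul__ = lambda self, o: matmul(o, self)
Tensor.__pow__ = lambda self, e: power(self, e)
Tensor.sum = tsum
Tensor.mean = tmean
Tensor.max = tmax
Tensor.reshape = reshape


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Fan-based uniform initialization, U(-limit, limit), limit = sqrt(6/(fi+fo))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)
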