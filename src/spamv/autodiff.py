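"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the encoders, decoders and loss terms are built
on.  It implements a dynamically built tape of :class:`Tensor` nodes with
broadcasting-aware gradients, plus the handful of segment operations a
graph attention layer needs (gather, segment-sum, segment-softmax).

Only what the model uses is implemented; the point is a small, auditable
surface whose gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["Tensor", "concatenate", "gather", "segment_sum", "no_grad_context"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            # defer the copy: the stored array may alias a child's grad, so
            # it is never mutated in place until we own a fresh buffer
            self.grad = g
            self._grad_owned = False
        elif getattr(self, "_grad_owned", False):
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free the tape as we go
                node._backward = None

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g)
            other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def log1p(self):
        def backward(g):
            self._accumulate(g / (1.0 + self.data))

        return self._make(np.log1p(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accumulate(g * sig)

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        return self._make(
            np.where(self.data > 0, self.data, slope * self.data), (self,), backward
        )

    def lgamma(self):
        def backward(g):
            self._accumulate(g * digamma(self.data))

        return self._make(gammaln(self.data), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.shape, axis)))
        return out

    def softmax(self, axis: int):
        m = np.max(self.data, axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, shape):
        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self):
        def backward(g):
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return self._make(self.data[idx], (self,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row-gather t[idx] with scatter-add backward."""
    return t[np.asarray(idx)]


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids)
    out_shape = (num_segments,) + t.data.shape[1:]
    data = np.zeros(out_shape)
    np.add.at(data, segment_ids, t.data)

    def backward(g):
        t._accumulate(g[segment_ids])

    return t._make(data, (t,), backward)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of 1-D `scores` within each segment (e.g. attention over
    incoming edges of each node)."""
    segment_ids = np.asarray(segment_ids)
    # subtract per-segment max (constant shift; no gradient needed)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    shifted = scores - Tensor(seg_max[segment_ids])
    e = shifted.exp()
    denom = segment_sum1d(e, segment_ids, num_segments)
    return e / gather1d(denom, segment_ids)


def no_grad_context(t: Tensor) -> Tensor:  # small alias used in a few call sites
    return t.detach()


# ---------------------------------------------------------------------------
# sparse-backed gather/scatter (fast path for graph message passing)
# ---------------------------------------------------------------------------

def spmm(s, st, t: Tensor) -> Tensor:
    """`s @ t` for a constant scipy sparse matrix `s`; `st` is its
    precomputed transpose (used in the backward pass)."""

    def backward(g):
        t._accumulate(st @ g)

    return t._make(s @ t.data, (t,), backward)


def gather1d(t: Tensor, idx: np.ndarray) -> Tensor:
    """1-D row gather with bincount-based scatter-add backward."""
    idx = np.asarray(idx)
    n = t.data.shape[0]

    def backward(g):
        t._accumulate(np.bincount(idx, weights=g, minlength=n))

    return t._make(t.data[idx], (t,), backward)


def segment_sum1d(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment sum of a 1-D tensor (bincount forward, gather backward)."""
    segment_ids = np.asarray(segment_ids)

    def backward(g):
        t._accumulate(g[segment_ids])

    return t._make(
        np.bincount(segment_ids, weights=t.data, minlength=num_segments), (t,), backward
    )
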