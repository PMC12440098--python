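"""Neural-network building blocks on the autodiff core.

Layers used by the model: dense layers, 2-layer MLPs, single-head graph
attention layers, and an Adam optimizer with global-norm gradient clipping.
Initialization is Glorot-uniform from an explicit NumPy Generator so that a
seed fully determines the parameter state.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gather1d, segment_softmax, spmm

__all__ = ["Parameter", "Module", "Linear", "MLP", "GATLayer", "GraphOps", "Adam",
           "param_hash"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with named recursion."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor, frozen: bool = False) -> Tensor:
        W = self.W.detach() if frozen else self.W
        b = self.b.detach() if frozen else self.b
        return x @ W + b


class MLP(Module):
    """2-layer perceptron with ELU hidden activation.

    `head` selects the output nonlinearity: None, "softplus", or
    "softmax" (row softmax).
    """

    def __init__(self, rng, d_in: int, d_hidden: int, d_out: int, head: str | None = None):
        self.fc1 = Linear(rng, d_in, d_hidden)
        self.fc2 = Linear(rng, d_hidden, d_out)
        self.head = head

    def __call__(self, x: Tensor, frozen: bool = False) -> Tensor:
        h = self.fc1(x, frozen=frozen).elu()
        out = self.fc2(h, frozen=frozen)
        if self.head == "softplus":
            out = out.softplus()
        elif self.head == "softmax":
            out = out.softmax(axis=1)
        return out


class GraphOps:
    """Precomputed sparse gather/scatter operators for one directed edge
    list (built once per graph; reused every forward/backward pass)."""

    def __init__(self, src: np.ndarray, dst: np.ndarray, n: int):
        from scipy import sparse

        self.src = np.asarray(src)
        self.dst = np.asarray(dst)
        self.n = int(n)
        e = len(self.src)
        ones = np.ones(e)
        self._g_src = sparse.csr_matrix((ones, (np.arange(e), self.src)), shape=(e, n))
        self._g_src_t = self._g_src.T.tocsr()
        self._scat = sparse.csr_matrix((ones, (self.dst, np.arange(e))), shape=(n, e))
        self._scat_t = self._scat.T.tocsr()
        # fused attention aggregation: A[v, u] = alpha of edge u->v.  The
        # directed edge list has no duplicate pairs, so a csr template with
        # edge ids as values gives the data-order permutation once.
        ids = sparse.coo_matrix(
            (np.arange(1, e + 1, dtype=float), (self.dst, self.src)), shape=(n, n)
        )
        a = ids.tocsr()
        self._attn = a.copy()
        self._attn_perm = a.data.astype(np.int64) - 1
        at = ids.T.tocsr()
        self._attn_t = at.copy()
        self._attn_t_perm = at.data.astype(np.int64) - 1

    def gather_src(self, h: Tensor) -> Tensor:
        return spmm(self._g_src, self._g_src_t, h)

    def scatter_dst(self, m: Tensor) -> Tensor:
        return spmm(self._scat, self._scat_t, m)

    def attn_aggregate(self, alpha: Tensor, h: Tensor) -> Tensor:
        """out_v = sum over incoming edges e=(u -> v) of alpha_e * h_u,
        computed as one sparse matmul."""
        self._attn.data = alpha.data[self._attn_perm]
        out_data = self._attn @ h.data
        src, dst = self.src, self.dst

        def backward(g):
            self._attn_t.data = alpha.data[self._attn_t_perm]
            h._accumulate(self._attn_t @ g)
            alpha._accumulate(np.einsum("ej,ej->e", h.data[src], g[dst]))

        return h._make(out_data, (alpha, h), backward)


class GATLayer(Module):
    """Single-head graph attention layer.

    Attention over each node's in-neighborhood (self-loop included by the
    caller's edge list): e_uv = LeakyReLU(a_src·Wh_u + a_dst·Wh_v),
    alpha = softmax over incoming edges of v, out_v = sum_u alpha_uv Wh_u.
    """

    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.a_src = Parameter(glorot(rng, d_out, 1, shape=(d_out,)))
        self.a_dst = Parameter(glorot(rng, d_out, 1, shape=(d_out,)))

    def attention(self, x: Tensor, gops: GraphOps) -> Tensor:
        h = x @ self.W
        es = (h * self.a_src.reshape((1, -1))).sum(axis=1)
        ed = (h * self.a_dst.reshape((1, -1))).sum(axis=1)
        scores = (gather1d(es, gops.src) + gather1d(ed, gops.dst)).leaky_relu(0.2)
        return segment_softmax(scores, gops.dst, gops.n)

    def __call__(self, x: Tensor, gops: GraphOps) -> Tensor:
        h = x @ self.W
        es = (h * self.a_src.reshape((1, -1))).sum(axis=1)
        ed = (h * self.a_dst.reshape((1, -1))).sum(axis=1)
        scores = (gather1d(es, gops.src) + gather1d(ed, gops.dst)).leaky_relu(0.2)
        alpha = segment_softmax(scores, gops.dst, gops.n)
        return gops.attn_aggregate(alpha, h)


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def param_hash(module: Module) -> int:
    """Order-stable hash of all parameter values (for freeze contracts)."""
    import hashlib

    h = hashlib.sha256()
    for a in module.state_arrays():
        h.update(np.ascontiguousarray(a).tobytes())
    return int.from_bytes(h.digest()[:8], "big")
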