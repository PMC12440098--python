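"""The two-mode multi-view VAE.

Per modality, two independent 2-layer graph-attention encoders produce
Gaussian posteriors for the shared latent z_s and the private latent
z_p_i; the per-modality shared posteriors are aggregated by a uniform
mixture-of-experts.  Decoding is mode-specific: clustering mode uses a
Gaussian likelihood with a 2-layer MLP mean and a learnable per-feature
scale; topic mode uses a Gamma-Poisson likelihood whose mean factorizes
as library_size * softmax([z_s, z_p_i]) @ softmax(beta_i)^T with a
regularized-horseshoe prior on the loadings beta_i.  Auxiliary
"measurement" MLPs predict the other modality from each private latent;
their output variance is the leakage penalty used by the objectives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .autodiff import Tensor, concatenate
from .datatypes import LatentPosteriors, NeighborGraph, SpatialMultiOmics
from .nn import GATLayer, Linear, MLP, Module, Parameter

__all__ = [
    "ModelConfig",
    "GaussianPosterior",
    "MixturePosterior",
    "SpaMVModel",
    "encode",
    "moe_combine",
    "decode_clustering",
    "decode_topic",
    "horseshoe_prior_logp",
    "measurement_forward",
    "normal_logpdf",
    "nb_logpmf",
    "halfcauchy_logpdf",
    "invgamma_logpdf",
]

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# densities (autodiff-aware)
# ---------------------------------------------------------------------------

def normal_logpdf(x, mu, sigma):
    x, mu, sigma = Tensor._lift(x), Tensor._lift(mu), Tensor._lift(sigma)
    return (
        -0.5 * LOG_2PI - sigma.log() - (x - mu) ** 2.0 / (2.0 * sigma**2.0)
    )


def nb_logpmf(x, mu, alpha):
    """Gamma-Poisson log-pmf with mean mu and shape (dispersion) alpha."""
    x, mu, alpha = Tensor._lift(x), Tensor._lift(mu), Tensor._lift(alpha)
    t = (alpha + mu).log()
    return (
        (x + alpha).lgamma()
        - alpha.lgamma()
        - (x + 1.0).lgamma()
        + alpha * (alpha.log() - t)
        + x * (mu.log() - t)
    )


def halfcauchy_logpdf(x):
    """HalfCauchy(scale=1): log(2 / (pi (1 + x^2)))."""
    x = Tensor._lift(x)
    return float(np.log(2.0 / np.pi)) - (x**2.0).log1p()


def invgamma_logpdf(x, a: float = 0.5, b: float = 0.5):
    from scipy.special import gammaln

    x = Tensor._lift(x)
    return float(a * np.log(b) - gammaln(a)) - (a + 1.0) * x.log() - b / x


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

class GaussianPosterior(NamedTuple):
    mu: Tensor
    sigma: Tensor

    def sample(self, rng: np.random.Generator) -> Tensor:
        eps = rng.standard_normal(self.mu.shape)
        return self.mu + self.sigma * Tensor(eps)

    def detached(self) -> "GaussianPosterior":
        return GaussianPosterior(self.mu.detach(), self.sigma.detach())

    def log_density(self, z) -> Tensor:
        """Per-spot log density (summed over latent dims)."""
        return normal_logpdf(z, self.mu, self.sigma).sum(axis=1)


class MixturePosterior:
    """Uniform mixture of Gaussian experts over the same latent space."""

    def __init__(self, experts: list[GaussianPosterior]):
        dims = {e.mu.shape for e in experts}
        if len(dims) != 1:
            raise ValueError("experts must share latent dimensions")
        self.experts = experts

    @property
    def m(self) -> int:
        return len(self.experts)

    def sample_stratified(self, rng: np.random.Generator) -> list[Tensor]:
        """One reparameterized draw per expert (stratified over experts)."""
        return [e.sample(rng) for e in self.experts]

    def sample(self, rng: np.random.Generator) -> Tensor:
        """Per-spot draw with the expert chosen uniformly per spot."""
        zs = self.sample_stratified(rng)
        if self.m == 1:
            return zs[0]
        pick = rng.integers(self.m, size=zs[0].shape[0])
        out = np.zeros(zs[0].shape)
        parents = []
        for i, z in enumerate(zs):
            mask = pick == i
            out[mask] = z.data[mask]
            parents.append((z, mask))

        res = Tensor(out)
        res.requires_grad = True
        res._parents = tuple(z for z, _ in parents)

        def backward(g):
            for z, mask in parents:
                gz = np.zeros_like(g)
                gz[mask] = g[mask]
                z._accumulate(gz)

        res._backward = backward
        return res

    def log_density(self, z) -> Tensor:
        """Per-spot log density of the uniform mixture."""
        per_expert = [e.log_density(z).reshape((-1, 1)) for e in self.experts]
        stacked = concatenate(per_expert, axis=1)
        return stacked.logsumexp(axis=1) - float(np.log(self.m))

    def mean(self) -> np.ndarray:
        return np.mean([e.mu.data for e in self.experts], axis=0)


def moe_combine(posteriors: list[GaussianPosterior]) -> MixturePosterior:
    return MixturePosterior(posteriors)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    mode: str = "clustering"          # clustering | topic
    d_s: int | None = None            # default 32 (clustering) / 10 (topic)
    d_p: int | None = None
    hidden: int = 128
    gat_layers: int = 2               # architecture uses 2; recorded for provenance
    heads: int = 1
    w: list[float] | None = None      # None: balance modalities by feature count
    alpha: list[float] = field(default_factory=lambda: [1.0, 1.0])
    learning_rate: float = 3e-3
    measurement_learning_rate: float = 1e-3
    epochs: int = 400
    epochs_phase2: int = 400
    start_epoch: int | None = None    # default 200 (clustering) / 10 (topic)
    reinit_every: int = 100
    inner_epochs: int = 100
    sigma_floor: float = 1e-4
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("clustering", "topic"):
            raise ValueError("mode must be 'clustering' or 'topic'")
        if self.d_s is None:
            self.d_s = 32 if self.mode == "clustering" else 10
        if self.d_p is None:
            self.d_p = 32 if self.mode == "clustering" else 10
        if self.start_epoch is None:
            self.start_epoch = 200 if self.mode == "clustering" else 10
        if self.d_s < 1 or self.d_p < 1:
            raise ValueError("latent dims must be >= 1")
        if self.w is not None and any(x < 0 for x in self.w):
            raise ValueError("weights must be non-negative")
        if any(x < 0 for x in self.alpha):
            raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class GATEncoder(Module):
    """2-layer GAT stack emitting a Gaussian (mu, sigma) per spot; sigma is
    softplus-floored to avoid posterior collapse."""

    def __init__(self, rng, d_in: int, hidden: int, d_out: int, sigma_floor: float):
        self.gat1 = GATLayer(rng, d_in, hidden)
        self.gat2 = GATLayer(rng, hidden, 2 * d_out)
        self.d_out = d_out
        self.sigma_floor = sigma_floor

    def __call__(self, x: Tensor, gops) -> GaussianPosterior:
        h = self.gat1(x, gops).elu()
        out = self.gat2(h, gops)
        mu = out[:, : self.d_out]
        sigma = out[:, self.d_out :].softplus() + self.sigma_floor
        return GaussianPosterior(mu, sigma)


def graph_ops(graph: NeighborGraph):
    """Directed-edge gather/scatter operators, cached on the graph."""
    from .nn import GraphOps

    ops = getattr(graph, "_gat_ops", None)
    if ops is None:
        src, dst = graph.directed(self_loops=True)
        ops = GraphOps(src, dst, graph.n_spots)
        graph._gat_ops = ops
    return ops


def encode(encoder_pair, x: np.ndarray, graph: NeighborGraph):
    """Run a modality's (shared, private) encoder pair on its mixed graph."""
    if x.shape[0] != graph.n_spots:
        raise ValueError("matrix and graph disagree on the number of spots")
    gops = graph_ops(graph)
    xt = Tensor(np.asarray(x, dtype=float))
    shared_enc, private_enc = encoder_pair
    return shared_enc(xt, gops), private_enc(xt, gops)


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

class ClusteringDecoder(Module):
    """Gaussian decoder: 2-layer MLP mean, learnable per-feature log-scale."""

    def __init__(self, rng, d_latent: int, hidden: int, n_features: int):
        self.mlp = MLP(rng, d_latent, hidden, n_features)
        self.log_sigma = Parameter(np.zeros(n_features))

    def log_likelihood(self, x: np.ndarray, z: Tensor) -> Tensor:
        """Per-spot Gaussian log-likelihood (summed over features)."""
        mean = self.mlp(z)
        sigma = self.log_sigma.exp().reshape((1, -1))
        return normal_logpdf(Tensor(x), mean, sigma).sum(axis=1)


def decode_clustering(decoder: ClusteringDecoder, x: np.ndarray, z_s: Tensor,
                      z_p: Tensor) -> Tensor:
    return decoder.log_likelihood(x, concatenate([z_s, z_p], axis=1))


class _NormalGuide(Module):
    """Mean-field Gaussian guide for a real-valued variable; entropy is
    analytic, samples are reparameterized."""

    def __init__(self, shape, init_mean, init_log_s: float = np.log(0.1)):
        self.m = Parameter(np.broadcast_to(np.asarray(init_mean, dtype=float), shape).copy())
        self.log_s = Parameter(np.full(shape, init_log_s))

    def sample(self, rng) -> Tensor:
        eps = rng.standard_normal(self.m.shape)
        return self.m + self.log_s.exp() * Tensor(eps)

    def entropy(self) -> Tensor:
        return (0.5 * (LOG_2PI + 1.0) + self.log_s).sum()


class _LogNormalGuide(_NormalGuide):
    """Mean-field log-normal guide for a positive scale variable.

    Entropy of LogNormal(m, s) is m + 1/2 log(2 pi e s^2)."""

    def __init__(self, shape, init_mean: float | np.ndarray = 0.0,
                 init_log_s: float = np.log(0.1)):
        super().__init__(shape, init_mean, init_log_s)

    def sample(self, rng) -> Tensor:
        eps = rng.standard_normal(self.m.shape)
        return (self.m + self.log_s.exp() * Tensor(eps)).exp()

    def entropy(self) -> Tensor:
        return (self.m + 0.5 * (LOG_2PI + 1.0) + self.log_s).sum()


class TopicDecoder(Module):
    """Gamma-Poisson topic decoder with a regularized-horseshoe prior.

    beta (features x T) and the per-feature log-dispersion are point
    parameters; the horseshoe scale hierarchy (local lambda, per-feature
    delta, per-topic tau, slab width c) and the per-feature loading mean
    r_f carry mean-field guides (log-normal for positive scales, normal
    for r_f) sampled once per step.
    """

    def __init__(self, rng, n_features: int, n_topics: int, log_xbar: np.ndarray):
        self.n_features = n_features
        self.n_topics = n_topics
        self.log_xbar = np.asarray(log_xbar, dtype=float)
        init_beta = np.tile(self.log_xbar[:, None], (1, n_topics))
        init_beta = init_beta + 0.05 * rng.standard_normal(init_beta.shape)
        self.beta = Parameter(init_beta)
        self.log_alpha = Parameter(np.full(n_features, np.log(10.0)))
        self.guide_r = _NormalGuide((n_features,), self.log_xbar)
        self.guide_c = _LogNormalGuide(())
        self.guide_delta = _LogNormalGuide((n_features,))
        self.guide_tau = _LogNormalGuide((n_topics,))
        self.guide_lambda = _LogNormalGuide((n_features, n_topics))

    def beta_softmax(self) -> np.ndarray:
        b = self.beta.data
        e = np.exp(b - b.max(axis=0, keepdims=True))
        return e / e.sum(axis=0, keepdims=True)

    def sample_guides(self, rng) -> tuple[dict, Tensor]:
        """One reparameterized draw per guide; returns (samples, total
        guide entropy) so the objective can form logp + entropy."""
        entropy = Tensor(0.0)
        samples = {}
        for name, guide in (
            ("r", self.guide_r),
            ("c", self.guide_c),
            ("delta", self.guide_delta),
            ("tau", self.guide_tau),
            ("lambda", self.guide_lambda),
        ):
            samples[name] = guide.sample(rng)
            entropy = entropy + guide.entropy()
        return samples, entropy

    def log_likelihood(self, counts: np.ndarray, z_s: Tensor, z_p: Tensor,
                       library_size: np.ndarray) -> Tensor:
        """Per-spot Gamma-Poisson log-likelihood (summed over features)."""
        return decode_topic(self, z_s, z_p, counts, library_size)


_LGAMMA_CACHE: dict = {}


def _lgamma_xp1(counts: np.ndarray) -> np.ndarray:
    """Cached lgamma(x + 1) for repeatedly decoded count matrices."""
    from scipy.special import gammaln

    key = (counts.__array_interface__["data"][0], counts.shape)
    hit = _LGAMMA_CACHE.get(key)
    if hit is None or hit[0] is not counts:
        if len(_LGAMMA_CACHE) > 8:
            _LGAMMA_CACHE.clear()
        hit = (counts, gammaln(counts + 1.0))
        _LGAMMA_CACHE[key] = hit
    return hit[1]


def _nb_loglik_rows(x: np.ndarray, lib: np.ndarray, mu_raw: Tensor,
                    alpha: Tensor) -> Tensor:
    """Per-spot Gamma-Poisson log-likelihood sum_f log NB(x | lib*mu_raw,
    alpha), as one fused op with analytic gradients (the elementwise
    composite would allocate dozens of spots x features temporaries)."""
    from scipy.special import digamma, gammaln

    a = alpha.data.reshape(1, -1)
    mu = lib * mu_raw.data
    t = a + mu
    log_t = np.log(t)
    ll = (
        gammaln(x + a)
        - gammaln(a)
        - _lgamma_xp1(x)
        + a * (np.log(a) - log_t)
        + x * (np.log(mu) - log_t)
    )

    def backward(g):
        gg = g.reshape(-1, 1)
        mu_raw._accumulate(gg * lib * (x / mu - (x + a) / t))
        ga = gg * (digamma(x + a) - digamma(a) + np.log(a) - log_t + 1.0 - (a + x) / t)
        alpha._accumulate(ga.sum(axis=0).reshape(alpha.data.shape))

    return mu_raw._make(ll.sum(axis=1), (mu_raw, alpha), backward)


def decode_topic(decoder: TopicDecoder, z_s: Tensor, z_p: Tensor,
                 counts: np.ndarray, library_size: np.ndarray) -> Tensor:
    """Gamma-Poisson log-likelihood with mean
    library_size * softmax([z_s, z_p]) @ softmax(beta)^T."""
    library_size = np.asarray(library_size, dtype=float).reshape(-1, 1)
    if np.any(library_size <= 0):
        raise ValueError("library sizes must be positive")
    z = concatenate([z_s, z_p], axis=1)
    theta = z.softmax(axis=1)                     # spots x T
    b = decoder.beta.softmax(axis=0)              # features x T, column-stochastic
    mu_raw = theta @ b.T                          # spots x features (pre-library)
    alpha = decoder.log_alpha.exp()
    return _nb_loglik_rows(
        np.asarray(counts, dtype=float), library_size, mu_raw, alpha
    )


def horseshoe_prior_logp(decoder: TopicDecoder, samples: dict) -> Tensor:
    """Joint log-density of beta and the horseshoe hierarchy at the sampled
    guide values: Normal(beta | r_f, regularized scale), Normal(r_f | log
    xbar_f, 1), InverseGamma(1/2, 1/2) on c, HalfCauchy(1) on delta, tau
    and lambda."""
    r = samples["r"]
    c = samples["c"]
    delta = samples["delta"]
    tau = samples["tau"]
    lam = samples["lambda"]
    for name in ("c", "delta", "tau", "lambda"):
        if np.any(samples[name].data <= 0):
            raise ValueError(f"{name} must be positive")
    local2 = (
        delta.reshape((-1, 1)) ** 2.0
        * tau.reshape((1, -1)) ** 2.0
        * lam**2.0
    )
    c2 = c**2.0
    scale2 = c2 * local2 / (c2 + local2)
    logp = normal_logpdf(decoder.beta, r.reshape((-1, 1)), scale2.sqrt()).sum()
    logp = logp + normal_logpdf(r, Tensor(decoder.log_xbar), 1.0).sum()
    logp = logp + invgamma_logpdf(c, 0.5, 0.5).sum()
    logp = logp + halfcauchy_logpdf(delta).sum()
    logp = logp + halfcauchy_logpdf(tau).sum()
    logp = logp + halfcauchy_logpdf(lam).sum()
    return logp


# ---------------------------------------------------------------------------
# measurement models
# ---------------------------------------------------------------------------

class MeasurementModel(Module):
    """2-layer MLP from a private latent to the other modality; softplus
    head in clustering mode, library-size-scaled softmax head in topic
    mode."""

    def __init__(self, rng, d_in: int, hidden: int, d_out: int, mode: str):
        head = "softplus" if mode == "clustering" else "softmax"
        self.mlp = MLP(rng, d_in, hidden, d_out, head=head)
        self.mode = mode

    def __call__(self, z: Tensor, library_size: np.ndarray | None = None,
                 frozen: bool = False) -> Tensor:
        out = self.mlp(z, frozen=frozen)
        if self.mode == "topic":
            if library_size is None:
                raise ValueError("topic-mode measurement model needs library sizes")
            out = out * Tensor(np.asarray(library_size, dtype=float).reshape(-1, 1))
        return out

    def reinitialize(self, rng):
        fresh = MeasurementModel(rng, self.mlp.fc1.W.shape[0], self.mlp.fc1.W.shape[1],
                                 self.mlp.fc2.W.shape[1], self.mode)
        self.load_state_arrays(fresh.state_arrays())


def measurement_forward(model: MeasurementModel, z_p: Tensor,
                        library_size: np.ndarray | None = None,
                        frozen: bool = False) -> Tensor:
    return model(z_p, library_size=library_size, frozen=frozen)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class SpaMVModel(Module):
    """Everything trainable, wired per modality."""

    def __init__(self, config: ModelConfig, input_dims: list[int],
                 output_dims: list[int] | None = None,
                 log_xbar: list[np.ndarray] | None = None):
        self.input_dims = list(input_dims)
        self.output_dims = list(output_dims) if output_dims is not None else list(input_dims)
        if config.w is None:
            # modalities with fewer features contribute proportionally less
            # log-likelihood; balance the reconstruction terms by default
            from dataclasses import replace

            top = max(self.output_dims)
            config = replace(config, w=[top / d for d in self.output_dims])
        self.config = config
        self.m = len(input_dims)
        rng = np.random.default_rng(config.seed)
        d_s, d_p, hidden = config.d_s, config.d_p, config.hidden

        self.shared_encoders = [
            GATEncoder(rng, d_in, hidden, d_s, config.sigma_floor)
            for d_in in self.input_dims
        ]
        self.private_encoders = [
            GATEncoder(rng, d_in, hidden, d_p, config.sigma_floor)
            for d_in in self.input_dims
        ]
        if config.mode == "clustering":
            self.decoders = [
                ClusteringDecoder(rng, d_s + d_p, hidden, d_out)
                for d_out in self.output_dims
            ]
        else:
            if log_xbar is None:
                raise ValueError("topic mode needs per-feature log mean counts")
            self.decoders = [
                TopicDecoder(rng, d_out, d_s + d_p, lx)
                for d_out, lx in zip(self.output_dims, log_xbar)
            ]
        # measurement models M[i][j]: private latent of i -> modality j (j != i)
        self.measurements = [
            {
                j: MeasurementModel(rng, d_p, hidden, self.output_dims[j], config.mode)
                for j in range(self.m)
                if j != i
            }
            for i in range(self.m)
        ]

    # -- parameter groups --------------------------------------------------
    def main_parameters(self) -> list[Parameter]:
        out = []
        for enc in self.shared_encoders + self.private_encoders:
            out.extend(enc.parameters())
        for dec in self.decoders:
            out.extend(dec.parameters())
        return out

    def phase2_parameters(self) -> list[Parameter]:
        """Shared encoders and decoders only (private encoders frozen)."""
        out = []
        for enc in self.shared_encoders:
            out.extend(enc.parameters())
        for dec in self.decoders:
            out.extend(dec.parameters())
        return out

    def measurement_parameters(self) -> list[Parameter]:
        out = []
        for row in self.measurements:
            for mm in row.values():
                out.extend(mm.parameters())
        return out

    def parameters(self) -> list[Parameter]:
        out = self.main_parameters()
        out.extend(self.measurement_parameters())
        return out

    # -- forward pieces ----------------------------------------------------
    def encode_all(self, data: SpatialMultiOmics,
                   graphs: list[NeighborGraph]) -> list[tuple]:
        """Per modality: (shared posterior, private posterior)."""
        return [
            encode((self.shared_encoders[i], self.private_encoders[i]),
                   data.matrices[i], graphs[i])
            for i in range(self.m)
        ]

    def posteriors(self, data: SpatialMultiOmics,
                   graphs: list[NeighborGraph]) -> LatentPosteriors:
        pairs = self.encode_all(data, graphs)
        return LatentPosteriors(
            mu_s=[p[0].mu.data.copy() for p in pairs],
            sigma_s=[p[0].sigma.data.copy() for p in pairs],
            mu_p=[p[1].mu.data.copy() for p in pairs],
            sigma_p=[p[1].sigma.data.copy() for p in pairs],
        )

    # -- persistence -------------------------------------------------------
    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        meta = {
            "config": asdict(self.config),
            "input_dims": self.input_dims,
            "output_dims": self.output_dims,
            "log_xbar": [
                d.log_xbar.tolist() for d in self.decoders
            ] if self.config.mode == "topic" else None,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SpaMVModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
        config = ModelConfig(**meta["config"])
        log_xbar = (
            [np.asarray(x) for x in meta["log_xbar"]] if meta["log_xbar"] else None
        )
        model = cls(config, meta["input_dims"], meta["output_dims"], log_xbar)
        model.load_state_arrays(arrays)
        return model
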