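"""Loss terms and phase totals.

Gradient-flow contracts, which the tests assert by parameter hashing:

* self-reconstruction samples z_s from a *detached* shared posterior, so
  its gradient reaches the private encoder and decoder only;
* cross-reconstruction replaces the private latent with fresh standard
  normal noise, so it trains the shared encoder of the source modality
  and the decoder of the target modality;
* the measurement MSE sees a detached private latent (it trains only the
  measurement MLP), while the variance penalty runs the measurement MLP
  with frozen weights (it trains only the private encoder).

Phase 1 minimizes the weighted reconstruction + leakage-variance terms
averaged over modalities plus the KL terms; phase 2 (topic mode only)
adds the HSIC dependence penalty between every shared/private pair while
the private encoders are held fixed by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .datatypes import NeighborGraph, SpatialMultiOmics
from .model_core import (
    GaussianPosterior,
    MeasurementModel,
    MixturePosterior,
    SpaMVModel,
    TopicDecoder,
    decode_clustering,
    decode_topic,
    horseshoe_prior_logp,
    moe_combine,
    normal_logpdf,
)

__all__ = [
    "LossReport",
    "self_recon_loss",
    "cross_recon_loss",
    "measurement_losses",
    "kl_terms",
    "hsic",
    "total_loss_phase1",
    "total_loss_phase2",
]


@dataclass
class LossReport:
    """Per-term scalars for one training step (all on the mean-per-spot
    scale); ``total`` is the assembled phase objective."""

    self_recon: list[float] = field(default_factory=list)
    cross_recon: dict = field(default_factory=dict)      # (j, i) -> float
    kl_shared: float = 0.0
    kl_private: list[float] = field(default_factory=list)
    measure_mse: dict = field(default_factory=dict)      # (i, j) -> float
    measure_var: dict = field(default_factory=dict)      # (i, j) -> float
    hsic: dict = field(default_factory=dict)             # (i, j) -> float
    horseshoe: list[float] = field(default_factory=list)
    w: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    phase: int = 1
    total: float = 0.0

    def assemble(self) -> float:
        """Re-sum the stored components with the stored weights (the
        bookkeeping identity the total must satisfy)."""
        m = len(self.self_recon)
        acc = 0.0
        for j in range(m):
            acc += self.w[j] * self.self_recon[j]
            for i in range(m):
                if i != j:
                    acc += self.w[i] * self.cross_recon[(j, i)]
                    acc += self.alpha[i] * self.measure_var[(i, j)]
        acc /= m
        acc += self.kl_shared + sum(self.kl_private) + sum(self.horseshoe)
        if self.phase == 2:
            acc += sum(self.hsic.values())
        return acc

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "self_recon": self.self_recon,
            "cross_recon": {f"{j}->{i}": v for (j, i), v in self.cross_recon.items()},
            "kl_shared": self.kl_shared,
            "kl_private": self.kl_private,
            "measure_mse": {f"{i}->{j}": v for (i, j), v in self.measure_mse.items()},
            "measure_var": {f"{i}->{j}": v for (i, j), v in self.measure_var.items()},
            "hsic": {f"{i},{j}": v for (i, j), v in self.hsic.items()},
            "horseshoe": self.horseshoe,
            "total": self.total,
        }


def _recon_loglik(decoder, target, z_s, z_p, library_size=None) -> Tensor:
    if isinstance(decoder, TopicDecoder):
        return decode_topic(decoder, z_s, z_p, target, library_size)
    return decode_clustering(decoder, target, z_s, z_p)


def self_recon_loss(decoder, target, shared_post: GaussianPosterior,
                    private_post: GaussianPosterior, rng,
                    library_size=None) -> Tensor:
    """Negative self-reconstruction log-likelihood with the shared
    posterior gradient stopped (mean over spots)."""
    z_s = shared_post.detached().sample(rng)
    z_p = private_post.sample(rng)
    return -_recon_loglik(decoder, target, z_s, z_p, library_size).mean()


def cross_recon_loss(decoder, target, shared_post_other: GaussianPosterior,
                     d_p: int, rng, library_size=None) -> Tensor:
    """Negative cross-reconstruction log-likelihood: z_s comes from the
    other modality's shared posterior (gradients flow), the private slot
    is filled by fresh standard normal noise."""
    z_s = shared_post_other.sample(rng)
    n = z_s.shape[0]
    r = Tensor(rng.standard_normal((n, d_p)))
    return -_recon_loglik(decoder, target, z_s, r, library_size).mean()


def measurement_losses(model_ij: MeasurementModel, z_p: Tensor, target,
                       library_size=None) -> tuple[Tensor, Tensor]:
    """(mse, var): the MSE trains the measurement MLP on a detached latent;
    the output variance (population denominator, summed over output dims)
    is computed with frozen MLP weights so it penalizes only the encoder."""
    target = np.asarray(target, dtype=float)
    pred = model_ij(z_p.detach(), library_size=library_size, frozen=False)
    mse = ((pred - Tensor(target)) ** 2.0).mean()
    out = model_ij(z_p, library_size=library_size, frozen=True)
    centered = out - out.mean(axis=0, keepdims=True)
    var = (centered**2.0).mean(axis=0).sum()
    return mse, var


def _kl_gaussian_standard(post: GaussianPosterior) -> Tensor:
    """Closed-form KL(N(mu, sigma) || N(0, I)) per spot, mean over spots."""
    mu, sigma = post.mu, post.sigma
    per_spot = 0.5 * (mu**2.0 + sigma**2.0 - 1.0 - 2.0 * sigma.log()).sum(axis=1)
    return per_spot.mean()


def kl_terms(mixture: MixturePosterior, private_posts: list[GaussianPosterior],
             rng) -> tuple[Tensor, list[Tensor]]:
    """KL of the mixture shared posterior against N(0, I) by a stratified
    Monte-Carlo estimate (one draw per expert), and closed-form KLs for
    the Gaussian private posteriors.  All on the mean-per-spot scale."""
    draws = mixture.sample_stratified(rng)
    acc = None
    for z in draws:
        log_q = mixture.log_density(z)
        log_p = normal_logpdf(z, 0.0, 1.0).sum(axis=1)
        term = (log_q - log_p).mean()
        acc = term if acc is None else acc + term
    kl_shared = acc * (1.0 / mixture.m)
    kl_private = [_kl_gaussian_standard(p) for p in private_posts]
    return kl_shared, kl_private


def hsic(z_a: Tensor, z_b: Tensor) -> Tensor:
    """Biased HSIC with unit-bandwidth Gaussian kernels
    K_mn = exp(-||a_m - a_n||^2): trace(K H L H) / (N - 1)^2.

    Implemented as one fused op with analytic gradients (the N x N
    kernel matrices would otherwise spawn many large autodiff temps).
    """
    z_a, z_b = Tensor._lift(z_a), Tensor._lift(z_b)
    n = z_a.shape[0]
    if n < 2:
        raise ValueError("HSIC needs at least 2 samples")

    def kernel(a: np.ndarray) -> np.ndarray:
        sq = (a**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (a @ a.T)
        return np.exp(-d2)

    def center(k: np.ndarray) -> np.ndarray:
        row = k.mean(axis=0, keepdims=True)
        col = k.mean(axis=1, keepdims=True)
        return k - row - col + k.mean()

    k = kernel(z_a.data)
    l = kernel(z_b.data)
    kc = center(k)
    lc = center(l)
    scale = 1.0 / (n - 1) ** 2
    # H idempotent, K and L symmetric: trace(K H L H) = sum(HKH * HLH)
    value = float((kc * lc).sum()) * scale

    def backward(g):
        gs = float(g) * scale
        # dS/dK = H L H (centering of the cofactor), then through exp(-d2)
        for z, cof, kern in ((z_a, lc, k), (z_b, kc, l)):
            w = gs * cof * kern
            deg = w.sum(axis=1, keepdims=True)
            z._accumulate(-4.0 * (deg * z.data - w @ z.data))

    return z_a._make(np.array(value), (z_a, z_b), backward)


# ---------------------------------------------------------------------------
# phase totals
# ---------------------------------------------------------------------------

def _phase_total(model: SpaMVModel, data: SpatialMultiOmics,
                 graphs: list[NeighborGraph], rng, phase: int,
                 measure_active: bool = True) -> tuple[Tensor, LossReport]:
    cfg = model.config
    m = model.m
    topic = cfg.mode == "topic"
    targets = data.counts if topic else data.matrices
    libs = data.library_sizes if topic else [None] * m

    pairs = model.encode_all(data, graphs)
    shared_posts = [p[0] for p in pairs]
    private_posts = [p[1] for p in pairs]
    mixture = moe_combine(shared_posts)
    z_p_samples = [private_posts[i].sample(rng) for i in range(m)]

    report = LossReport(w=list(cfg.w), alpha=list(cfg.alpha), phase=phase)
    total = Tensor(0.0)

    recon_acc = Tensor(0.0)
    for j in range(m):
        l_self = -(_recon_loglik(
            model.decoders[j], targets[j],
            shared_posts[j].detached().sample(rng), z_p_samples[j], libs[j],
        ).mean())
        report.self_recon.append(l_self.item())
        recon_acc = recon_acc + cfg.w[j] * l_self
        for i in range(m):
            if i == j:
                continue
            l_cross = cross_recon_loss(
                model.decoders[i], targets[i], shared_posts[j], cfg.d_p, rng, libs[i]
            )
            report.cross_recon[(j, i)] = l_cross.item()
            recon_acc = recon_acc + cfg.w[i] * l_cross
            # the variance penalty only makes sense once the measurement
            # MLPs are being trained: an untrained random map's output
            # variance would indiscriminately suppress the private latents
            if measure_active:
                out = model.measurements[i][j](
                    z_p_samples[i], library_size=libs[j], frozen=True
                )
                centered = out - out.mean(axis=0, keepdims=True)
                var = (centered**2.0).mean(axis=0).sum()
                report.measure_var[(i, j)] = var.item()
                recon_acc = recon_acc + cfg.alpha[i] * var
            else:
                report.measure_var[(i, j)] = 0.0
    total = total + recon_acc * (1.0 / m)

    kl_s, kl_p = kl_terms(mixture, private_posts, rng)
    report.kl_shared = kl_s.item()
    report.kl_private = [k.item() for k in kl_p]
    total = total + kl_s
    for k in kl_p:
        total = total + k

    if topic:
        n = data.n_spots
        for dec in model.decoders:
            samples, entropy = dec.sample_guides(rng)
            hs = -(horseshoe_prior_logp(dec, samples) + entropy) * (1.0 / n)
            report.horseshoe.append(hs.item())
            total = total + hs

    if phase == 2:
        z_s_samples = [shared_posts[i].sample(rng) for i in range(m)]
        for i in range(m):
            for j in range(m):
                h = hsic(z_s_samples[i], z_p_samples[j])
                report.hsic[(i, j)] = h.item()
                total = total + h

    report.total = total.item()
    return total, report


def total_loss_phase1(model, data, graphs, rng,
                      measure_active: bool = True) -> tuple[Tensor, LossReport]:
    return _phase_total(model, data, graphs, rng, phase=1,
                        measure_active=measure_active)


def total_loss_phase2(model, data, graphs, rng) -> tuple[Tensor, LossReport]:
    return _phase_total(model, data, graphs, rng, phase=2)
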