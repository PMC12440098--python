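"""Loss terms: density/variance oracles and gradient-flow contracts."""

import numpy as np
import pytest
from scipy import stats

from spamv.autodiff import Tensor
from spamv.datatypes import NeighborGraph, SpatialMultiOmics
from spamv.model_core import (
    GaussianPosterior,
    MeasurementModel,
    ModelConfig,
    SpaMVModel,
    moe_combine,
)
from spamv.nn import Adam, param_hash
from spamv.objectives import (
    cross_recon_loss,
    hsic,
    kl_terms,
    measurement_losses,
    self_recon_loss,
    total_loss_phase1,
    total_loss_phase2,
)
from spamv.preprocessing import build_graphs
from spamv.synthetic_data import SimParams, simulate


def _tiny_setup(mode="clustering", seed=0, n=16):
    """Small two-modality dataset + model for contract tests."""
    rng = np.random.default_rng(seed)
    coords = np.array([[i // 4, i % 4] for i in range(n)], dtype=float)
    mats = [rng.standard_normal((n, 6)), rng.standard_normal((n, 4))]
    counts = [rng.poisson(5.0, (n, 6)).astype(float) + 1.0,
              rng.poisson(5.0, (n, 4)).astype(float) + 1.0]
    data = SpatialMultiOmics(
        matrices=mats if mode == "clustering" else [np.log1p(c) for c in counts],
        coords=coords,
        feature_names=[[f"a{j}" for j in range(6)], [f"b{j}" for j in range(4)]],
        spot_ids=[f"s{i}" for i in range(n)],
        modality_kinds=["transcriptome", "metabolome"],
        counts=counts if mode == "topic" else None,
        library_sizes=[c.sum(1) for c in counts] if mode == "topic" else None,
    )
    graphs = build_graphs(data)
    cfg = ModelConfig(mode=mode, d_s=3, d_p=2, hidden=8, seed=seed)
    log_xbar = [np.log(c.mean(0)) for c in counts] if mode == "topic" else None
    model = SpaMVModel(cfg, [6, 4], [6, 4] if mode == "clustering" else [6, 4],
                       log_xbar=log_xbar)
    return model, data, graphs


class TestHsic:
    def test_constant_samples_give_zero(self):
        z = Tensor(np.ones((10, 3)))
        assert abs(hsic(z, z).item()) < 1e-12

    def test_two_sample_hand_computation(self):
        a = np.array([[0.0], [1.0]])
        b = np.array([[2.0], [2.5]])
        got = hsic(Tensor(a), Tensor(b)).item()
        # N=2: H = [[.5,-.5],[-.5,.5]]; K = [[1,k],[k,1]], L = [[1,l],[l,1]]
        k = np.exp(-1.0)
        l = np.exp(-0.25)
        kc = np.array([[1 - k, k - 1], [k - 1, 1 - k]]) * 0.5
        lc = np.array([[1 - l, l - 1], [l - 1, 1 - l]]) * 0.5
        expect = (kc * lc).sum() / (2 - 1) ** 2
        assert abs(got - expect) < 1e-12

    def test_matches_explicit_double_sum_oracle(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 50):
            a = rng.standard_normal((n, 3))
            b = 0.5 * a[:, :2] + rng.standard_normal((n, 2))
            k = np.exp(-((a[:, None, :] - a[None, :, :]) ** 2).sum(-1))
            l = np.exp(-((b[:, None, :] - b[None, :, :]) ** 2).sum(-1))
            h = np.eye(n) - np.ones((n, n)) / n
            expect = np.trace(k @ h @ l @ h) / (n - 1) ** 2
            assert abs(hsic(Tensor(a), Tensor(b)).item() - expect) < 1e-10

    def test_nonnegative_up_to_numerical_floor(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.standard_normal((30, 2))
            b = rng.standard_normal((30, 4))
            assert hsic(Tensor(a), Tensor(b)).item() >= -1e-10

    def test_independent_permutation_below_null_quantile(self):
        rng = np.random.default_rng(2)
        n = 500
        z = rng.standard_normal((n, 3))
        zp = z[rng.permutation(n)]
        stat = hsic(Tensor(z), Tensor(zp)).item()
        null = [
            hsic(Tensor(z), Tensor(zp[rng.permutation(n)])).item() for _ in range(99)
        ]
        assert stat < np.quantile(null, 0.95)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            hsic(Tensor(np.ones((1, 2))), Tensor(np.ones((1, 2))))


class TestKl:
    def test_standard_normal_posterior_gives_zero(self):
        post = GaussianPosterior(Tensor(np.zeros((5, 3))), Tensor(np.ones((5, 3))))
        _, kl_p = kl_terms(moe_combine([post]), [post], np.random.default_rng(0))
        assert abs(kl_p[0].item()) < 1e-12

    def test_unit_sigma_closed_form(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((7, 4))
        post = GaussianPosterior(Tensor(mu), Tensor(np.ones((7, 4))))
        _, kl_p = kl_terms(moe_combine([post]), [post], rng)
        expect = ((mu**2).sum(axis=1) / 2).mean()
        assert abs(kl_p[0].item() - expect) < 1e-12

    def test_single_expert_mc_converges_to_closed_form(self):
        # one expert replicated over many "spots": the mean over spots of the
        # single-draw estimator is a 1e4-sample MC estimate
        rng = np.random.default_rng(4)
        n = 10**4
        mu = np.tile([0.7, -0.4], (n, 1))
        sig = np.tile([1.3, 0.6], (n, 1))
        post = GaussianPosterior(Tensor(mu), Tensor(sig))
        kl_s, _ = kl_terms(moe_combine([post]), [], rng)
        closed = 0.5 * (mu[0] ** 2 + sig[0] ** 2 - 1 - 2 * np.log(sig[0])).sum()
        # SE of the per-spot KL integrand, estimated by simulation
        draws = mu[0] + sig[0] * rng.standard_normal((n, 2))
        integrand = (
            stats.norm.logpdf(draws, mu[0], sig[0]) - stats.norm.logpdf(draws)
        ).sum(axis=1)
        se = integrand.std() / np.sqrt(n)
        assert abs(kl_s.item() - closed) < 3 * se


class TestGradientFlow:
    def test_self_recon_stops_shared_encoder(self):
        model, data, graphs = _tiny_setup()
        pairs = model.encode_all(data, graphs)
        rng = np.random.default_rng(0)
        loss = self_recon_loss(model.decoders[0], data.matrices[0],
                               pairs[0][0], pairs[0][1], rng)
        loss.backward()
        shared_grads = [p.grad for enc in model.shared_encoders
                        for p in enc.parameters()]
        assert all(g is None for g in shared_grads)
        private_grads = [p.grad for p in model.private_encoders[0].parameters()]
        assert any(g is not None and np.abs(g).max() > 0 for g in private_grads)
        # one optimizer step on this loss leaves shared encoders bit-identical
        before = param_hash(model.shared_encoders[0])
        opt = Adam(model.main_parameters(), lr=1e-2)
        opt.step()
        assert param_hash(model.shared_encoders[0]) == before

    def test_cross_recon_trains_source_shared_encoder_only(self):
        model, data, graphs = _tiny_setup()
        pairs = model.encode_all(data, graphs)
        rng = np.random.default_rng(0)
        # reconstruct modality 0 from modality 1's shared posterior
        loss = cross_recon_loss(model.decoders[0], data.matrices[0],
                                pairs[1][0], model.config.d_p, rng)
        loss.backward()
        assert any(p.grad is not None for p in model.shared_encoders[1].parameters())
        assert all(p.grad is None for p in model.shared_encoders[0].parameters())
        for enc in model.private_encoders:
            assert all(p.grad is None for p in enc.parameters())
        assert any(p.grad is not None for p in model.decoders[0].parameters())

    def test_measurement_mse_trains_only_measurement_model(self):
        rng = np.random.default_rng(5)
        mm = MeasurementModel(rng, 2, 4, 3, mode="clustering")
        z = Tensor(rng.standard_normal((6, 2)), requires_grad=True)
        x = rng.standard_normal((6, 3))
        mse, _ = measurement_losses(mm, z, x)
        mse.backward()
        assert z.grad is None
        assert any(p.grad is not None for p in mm.parameters())

    def test_variance_penalty_trains_only_the_latent(self):
        rng = np.random.default_rng(6)
        mm = MeasurementModel(rng, 2, 4, 3, mode="clustering")
        z = Tensor(rng.standard_normal((6, 2)), requires_grad=True)
        _, var = measurement_losses(mm, z, rng.standard_normal((6, 3)))
        var.backward()
        assert z.grad is not None and np.abs(z.grad).max() > 0
        assert all(p.grad is None for p in mm.parameters())

    def test_variance_zero_for_constant_map_or_constant_latent(self):
        rng = np.random.default_rng(7)
        mm = MeasurementModel(rng, 2, 4, 3, mode="clustering")
        # constant latent across spots -> zero variance regardless of weights
        z = Tensor(np.tile([0.3, -0.8], (5, 1)))
        _, var = measurement_losses(mm, z, rng.standard_normal((5, 3)))
        assert abs(var.item()) < 1e-20
        # constant map (zero first-layer weights) -> zero variance
        mm.mlp.fc1.W.data[:] = 0.0
        z2 = Tensor(rng.standard_normal((5, 2)))
        _, var2 = measurement_losses(mm, z2, rng.standard_normal((5, 3)))
        assert abs(var2.item()) < 1e-20

    def test_variance_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        mm = MeasurementModel(rng, 2, 4, 3, mode="clustering")
        z = Tensor(rng.standard_normal((4, 2)))
        _, var = measurement_losses(mm, z, rng.standard_normal((4, 3)))
        out = mm(z).data
        expect = out.var(axis=0).sum()  # population variance, summed over dims
        assert abs(var.item() - expect) < 1e-12


class TestPhaseTotals:
    @pytest.mark.parametrize("mode", ["clustering", "topic"])
    def test_total_is_bookkeeping_sum_of_parts(self, mode):
        model, data, graphs = _tiny_setup(mode=mode)
        total, report = total_loss_phase1(model, data, graphs, np.random.default_rng(0))
        assert np.isfinite(total.item())
        assert abs(report.total - report.assemble()) < 1e-9

    def test_phase2_total_includes_hsic(self):
        model, data, graphs = _tiny_setup(mode="topic")
        total, report = total_loss_phase2(model, data, graphs, np.random.default_rng(0))
        assert report.phase == 2
        assert len(report.hsic) == 4  # all (i, j) pairs for m=2
        assert abs(report.total - report.assemble()) < 1e-9

    def test_assemble_symmetric_under_modality_relabeling(self):
        model, data, graphs = _tiny_setup()
        _, report = total_loss_phase1(model, data, graphs, np.random.default_rng(0))
        swapped = type(report)(
            self_recon=report.self_recon[::-1],
            cross_recon={(1 - j, 1 - i): v for (j, i), v in report.cross_recon.items()},
            kl_shared=report.kl_shared,
            kl_private=report.kl_private[::-1],
            measure_var={(1 - i, 1 - j): v for (i, j), v in report.measure_var.items()},
            hsic={},
            horseshoe=report.horseshoe[::-1],
            w=report.w[::-1],
            alpha=report.alpha[::-1],
            phase=1,
        )
        assert abs(report.assemble() - swapped.assemble()) < 1e-12

    def test_cross_noise_has_no_encoder_gradient_path(self):
        # with all reconstruction weights zero except one cross term, only
        # the source shared encoder and the target decoder can move
        model, data, graphs = _tiny_setup()
        pairs = model.encode_all(data, graphs)
        rng = np.random.default_rng(1)
        loss = cross_recon_loss(model.decoders[1], data.matrices[1],
                                pairs[0][0], model.config.d_p, rng)
        loss.backward()
        assert all(p.grad is None for enc in model.private_encoders
                   for p in enc.parameters())
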