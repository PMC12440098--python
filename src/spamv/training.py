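"""Two-phase training loop.

Phase 1 jointly trains encoders, decoders and (after a warm-up epoch)
the measurement MLPs: the main objective is optimized every epoch with
Adam; once past ``start_epoch`` (200 in clustering mode, 10 in topic
mode) the measurement models take one inner MSE epoch per outer epoch,
and are re-initialized and re-trained for 100 inner epochs whenever the
epoch index is divisible by 100 (escaping degenerate local optima).
Topic mode then runs a second phase in which the private encoders are
frozen and the HSIC dependence penalty is added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .datatypes import NeighborGraph, SpatialMultiOmics
from .model_core import ModelConfig, SpaMVModel
from .nn import Adam
from .objectives import LossReport, total_loss_phase1, total_loss_phase2

__all__ = ["TrainState", "fit", "freeze_private_encoders"]


@dataclass
class TrainState:
    epoch: int = 0
    phase: int = 1
    history: list[LossReport] = field(default_factory=list)


def freeze_private_encoders(model: SpaMVModel) -> SpaMVModel:
    """Mark the private encoders as frozen: phase-2 optimization only sees
    the shared encoders and decoders (see
    :meth:`SpaMVModel.phase2_parameters`)."""
    model._private_frozen = True
    return model


def _check_finite(total: Tensor, report: LossReport, state: TrainState):
    if not np.isfinite(total.item()):
        raise RuntimeError(
            "non-finite loss at epoch "
            f"{state.epoch} (phase {state.phase}): {json.dumps(report.to_dict())}"
        )


def _train_measurements(model: SpaMVModel, data: SpatialMultiOmics,
                        graphs: list[NeighborGraph], opt: Adam, n_inner: int,
                        rng: np.random.Generator) -> dict:
    """Inner MSE epochs for all measurement models; the main model is held
    fixed (latents are drawn from the current posteriors, detached)."""
    topic = model.config.mode == "topic"
    targets = data.counts if topic else data.matrices
    libs = data.library_sizes if topic else [None] * model.m
    post = model.posteriors(data, graphs)
    mse_report = {}
    for _ in range(n_inner):
        opt.zero_grad()
        loss = Tensor(0.0)
        for i in range(model.m):
            z = post.mu_p[i] + post.sigma_p[i] * rng.standard_normal(post.mu_p[i].shape)
            zt = Tensor(z)
            for j, mm in model.measurements[i].items():
                pred = mm(zt, library_size=libs[j], frozen=False)
                mse = ((pred - Tensor(np.asarray(targets[j], dtype=float))) ** 2.0).mean()
                mse_report[(i, j)] = mse.item()
                loss = loss + mse
        loss.backward()
        opt.step()
    return mse_report


def fit(
    data: SpatialMultiOmics,
    graphs: list[NeighborGraph],
    config: ModelConfig,
    log_path=None,
) -> tuple[SpaMVModel, list[LossReport]]:
    """Run the full training schedule on preprocessed data; reproducible
    from ``config.seed``.  Returns the trained model and the per-epoch
    loss history (also streamed to ``log_path`` as JSONL if given)."""
    topic = config.mode == "topic"
    input_dims = [m.shape[1] for m in data.matrices]
    if topic:
        if data.counts is None or data.library_sizes is None:
            raise ValueError("topic mode needs preprocess_topic output (counts kept)")
        output_dims = [c.shape[1] for c in data.counts]
        log_xbar = [np.log(np.asarray(c, float).mean(axis=0) + 1e-8) for c in data.counts]
    else:
        output_dims = input_dims
        log_xbar = None

    model = SpaMVModel(config, input_dims, output_dims, log_xbar)
    rng = np.random.default_rng(config.seed)
    opt_main = Adam(model.main_parameters(), lr=config.learning_rate,
                    clip_norm=config.grad_clip)
    opt_meas = Adam(model.measurement_parameters(),
                    lr=config.measurement_learning_rate, clip_norm=config.grad_clip)
    state = TrainState()
    log_file = open(log_path, "w") if log_path is not None else None

    def emit(report: LossReport):
        state.history.append(report)
        if log_file is not None:
            log_file.write(json.dumps({"epoch": state.epoch, **report.to_dict()}) + "\n")

    try:
        for epoch in range(config.epochs):
            state.epoch = epoch
            opt_main.zero_grad()
            total, report = total_loss_phase1(
                model, data, graphs, rng,
                measure_active=epoch > config.start_epoch,
            )
            _check_finite(total, report, state)
            total.backward()
            opt_main.step()

            if epoch > config.start_epoch:
                if epoch % config.reinit_every == 0:
                    reinit_rng = np.random.default_rng(rng.integers(2**31))
                    for row in model.measurements:
                        for mm in row.values():
                            mm.reinitialize(reinit_rng)
                    opt_meas = Adam(model.measurement_parameters(),
                                    lr=config.measurement_learning_rate,
                                    clip_norm=config.grad_clip)
                    n_inner = config.inner_epochs
                else:
                    n_inner = 1
                report.measure_mse = _train_measurements(
                    model, data, graphs, opt_meas, n_inner, rng
                )
            emit(report)

        if topic:
            state.phase = 2
            freeze_private_encoders(model)
            opt2 = Adam(model.phase2_parameters(), lr=config.learning_rate,
                        clip_norm=config.grad_clip)
            for epoch in range(config.epochs_phase2):
                state.epoch = epoch
                opt2.zero_grad()
                total, report = total_loss_phase2(model, data, graphs, rng)
                _check_finite(total, report, state)
                total.backward()
                opt2.step()
                emit(report)
    finally:
        if log_file is not None:
            log_file.close()

    return model, state.history
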