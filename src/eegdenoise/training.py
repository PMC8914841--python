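"""WGAN training loop for the denoiser.

The critic loss is L_D = -mean(D(y)) + mean(D(G(S))) and the generator loss
L_G = -alpha * mean(D(G(S))) + beta * MSE(y, G(S)): the adversarial term
pushes generated trials toward the critic's notion of clean data while the
MSE term anchors them to the paired clean target. Training alternates critic
updates (with weight clipping, the Wasserstein-critic Lipschitz surrogate)
and generator updates, both under RMSProp, and stops when the held-out
reconstruction error and the critic's score of generated data both plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gan_model import DenoiserModel
from .nn import RMSProp, clip_weights
from .setet_norm import SampEnParams, SetetConfig, setet_normalize
from .synth import PairedDataset
from .types import Trial


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    eta is the RMSProp learning rate for both networks; alpha and beta
    balance the generator's adversarial and reconstruction terms (0.1 and 1:
    reconstruction dominates, the critic nudges). clip_value is the WGAN
    weight-clipping bound. Training stops after max_epochs or when both the
    held-out MSE and the mean critic score of generated data change by less
    than rel_tol (relative) across a window of `patience` epochs.
    """

    eta: float = 2e-4
    alpha: float = 0.1
    beta: float = 1.0
    max_epochs: int = 500
    batch_size: int = 32
    clip_value: float = 0.01
    critic_steps: int = 1
    patience: int = 20
    rel_tol: float = 1e-3
    holdout_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.clip_value <= 0:
            raise ValueError("eta and clip_value must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1 or self.critic_steps < 1:
            raise ValueError("batch_size, max_epochs, critic_steps must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch monitoring series; all lists share one length."""

    loss_d: list[float] = field(default_factory=list)
    loss_g: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)
    mean_dy: list[float] = field(default_factory=list)
    mean_dgs: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"

    @property
    def n_epochs(self) -> int:
        return len(self.loss_d)


def discriminator_loss(dy: np.ndarray, dgs: np.ndarray) -> float:
    """Critic loss: -mean(D(y)) + mean(D(GS))."""
    dy, dgs = np.asarray(dy, dtype=float), np.asarray(dgs, dtype=float)
    if dy.size == 0 or dgs.size == 0:
        raise ValueError("empty score batch")
    return float(-dy.mean() + dgs.mean())


def generator_loss(dgs: np.ndarray, y: np.ndarray, gs: np.ndarray,
                   alpha: float = 0.1, beta: float = 1.0) -> float:
    """Generator loss: -alpha * mean(D(GS)) + beta * reconstruction error.

    The reconstruction term is the squared residual summed per trial and
    divided by the channel count (the same reduction as the monitoring MSE),
    averaged over the batch. With the printed alpha = 0.1, beta = 1 this
    keeps reconstruction dominant and the critic a nudge, which is the
    regime in which the denoiser retains signal rather than wandering.
    """
    y, gs = np.asarray(y, dtype=float), np.asarray(gs, dtype=float)
    if y.shape != gs.shape:
        raise ValueError(f"clean and generated shapes differ: {y.shape} vs {gs.shape}")
    dgs = np.asarray(dgs, dtype=float)
    if dgs.size == 0:
        raise ValueError("empty score batch")
    n_channels = y.shape[-2] if y.ndim >= 2 else 1
    per_trial = (y - gs).reshape(y.shape[0], -1) ** 2
    mse_term = float(per_trial.sum(axis=1).mean() / n_channels)
    return float(-alpha * dgs.mean() + beta * mse_term)


def mse_epoch(u: Sequence[np.ndarray] | np.ndarray, v) -> float:
    """Monitoring error: mean over trials of sum_c ||U_kc - V_kc||^2 / N.

    The inner time sum is unnormalized; N is the channel count.
    """
    ua = np.stack([np.asarray(t, dtype=float) for t in u])
    va = np.stack([np.asarray(t, dtype=float) for t in v])
    if ua.shape != va.shape:
        raise ValueError(f"misaligned trial lists: {ua.shape} vs {va.shape}")
    if ua.ndim != 3 or ua.shape[0] < 1:
        raise ValueError("need at least one trial of shape (C, T)")
    n = ua.shape[1]
    return float((((ua - va) ** 2).sum(axis=(1, 2)) / n).mean())


def _normalized_pairs(pairs: PairedDataset, setet: SetetConfig,
                      sampen: SampEnParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SETET-normalize each noisy trial; scale its clean partner by the same m."""
    s_list, y_list, ms = [], [], []
    for clean, noisy in zip(pairs.clean, pairs.noisy):
        res = setet_normalize(noisy, setet, sampen)
        s_list.append(res.S.data)
        y_list.append(clean.data / res.m)
        ms.append(res.m)
    return np.stack(s_list), np.stack(y_list), np.array(ms)


def _plateaued(series: list[float], patience: int, rel_tol: float) -> bool:
    if len(series) < patience:
        return False
    window = np.array(series[-patience:])
    scale = max(float(np.max(np.abs(window))), 1e-12)
    return float(window.max() - window.min()) / scale < rel_tol


def train(pairs: PairedDataset, model: DenoiserModel,
          config: TrainConfig = TrainConfig()) -> tuple[DenoiserModel, TrainingHistory]:
    """Alternating WGAN training on SETET-normalized pairs.

    Returns the model (updated in place) and the per-epoch history. Raises
    on non-finite losses, naming the epoch.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    s_all, y_all, _ = _normalized_pairs(pairs, model.setet, model.sampen)

    rng = np.random.default_rng(config.seed)
    n = len(pairs)
    n_hold = (0 if config.holdout_frac <= 0 or n <= 2
              else max(1, int(round(config.holdout_frac * n))))
    perm = rng.permutation(n)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    s_tr, y_tr = s_all[train_idx], y_all[train_idx]
    s_ho, y_ho = s_all[hold_idx], y_all[hold_idx]

    opt_g = RMSProp(model.generator, lr=config.eta)
    opt_d = RMSProp(model.discriminator, lr=config.eta)
    history = TrainingHistory()
    gen, disc = model.generator, model.discriminator

    n_tr = len(train_idx)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_tr)
        ep_ld, ep_lg, ep_dy, ep_dgs = [], [], [], []
        for start in range(0, n_tr, config.batch_size):
            idx = order[start:start + config.batch_size]
            s = s_tr[idx][:, None]
            y = y_tr[idx][:, None]
            b = len(idx)

            for _ in range(config.critic_steps):
                gs = gen.forward(s, train=False)
                dy = disc.forward(y, train=True)
                disc.backward(-np.ones_like(dy) / b)
                gd_y = {name: g.copy() for name, _, g in disc.named_parameters()}
                dgs = disc.forward(gs, train=True)
                disc.backward(np.ones_like(dgs) / b)
                for name, _, g in disc.named_parameters():
                    g += gd_y[name]
                opt_d.step()
                clip_weights(disc, config.clip_value)
                ld = discriminator_loss(dy[:, 0, 0, 0], dgs[:, 0, 0, 0])

            gs = gen.forward(s, train=True)
            dgs = disc.forward(gs, train=True)
            lg = generator_loss(dgs[:, 0, 0, 0], y, gs, config.alpha, config.beta)
            grad_gs_adv = disc.backward(-config.alpha * np.ones_like(dgs) / b)
            grad_gs_mse = config.beta * 2.0 * (gs - y) / (b * gs.shape[2])
            gen.backward(grad_gs_adv + grad_gs_mse)
            opt_g.step()

            if not (math.isfinite(ld) and math.isfinite(lg)):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: L_D={ld}, L_G={lg}")
            ep_ld.append(ld)
            ep_lg.append(lg)
            ep_dy.append(float(dy.mean()))
            ep_dgs.append(float(dgs.mean()))

        history.loss_d.append(float(np.mean(ep_ld)))
        history.loss_g.append(float(np.mean(ep_lg)))
        history.mean_dy.append(float(np.mean(ep_dy)))
        history.mean_dgs.append(float(np.mean(ep_dgs)))
        if n_hold:
            gs_ho = gen.forward(s_ho[:, None], train=False)[:, 0]
            history.mse.append(mse_epoch(y_ho, gs_ho))
        else:
            gs_tr = gen.forward(s_tr[:, None], train=False)[:, 0]
            history.mse.append(mse_epoch(y_tr, gs_tr))

        if (_plateaued(history.mse, config.patience, config.rel_tol)
                and _plateaued(history.mean_dgs, config.patience, config.rel_tol)):
            history.stop_reason = f"plateau at epoch {epoch + 1}"
            break

    return model, history


def denoise(model: DenoiserModel, x: Trial | Sequence[Trial],
            setet: SetetConfig | None = None,
            sampen: SampEnParams | None = None) -> Trial | list[Trial]:
    """Denoise preprocessed trials: normalize, generate, denormalize by the same m."""
    setet = setet if setet is not None else model.setet
    sampen = sampen if sampen is not None else model.sampen
    single = isinstance(x, Trial)
    trials = [x] if single else list(x)
    out: list[Trial] = []
    for t in trials:
        if t.data.shape != model.input_shape:
            raise ValueError(
                f"trial shape {t.data.shape} does not match model input "
                f"{model.input_shape}")
        res = setet_normalize(t, setet, sampen)
        gs = model.generator.forward(res.S.data[None, None], train=False)[0, 0]
        out.append(t.with_data(gs * res.m))
    return out[0] if single else out
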