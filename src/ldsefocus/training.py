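"""MSE training loop: Adam, step-decay learning rate, plateau stopping.

Labels (defocus distances in um) are normalised to [-1, 1] over the
network's configured axial range before the loss is computed; the
normalisation is exact bookkeeping — MSE on normalised labels equals MSE
on raw labels divided by the square of the scale.  Training stops when
the best test loss has not improved by more than 1% (relative) for a
configurable number of epochs, and the weights returned are those of the
best test-loss epoch, not the last one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ldsefocus.nn.network import LDSENet

__all__ = ["TrainConfig", "LossTrace", "mse_loss", "Adam", "train"]


def mse_loss(d_true: np.ndarray, d_pred: np.ndarray) -> float:
    """Mean squared error ``(1/n) sum (D_t - D_p)^2``.

    Zero iff the vectors are identical; invariant to a simultaneous
    permutation of both.
    """
    d_true = np.asarray(d_true, dtype=np.float64)
    d_pred = np.asarray(d_pred, dtype=np.float64)
    if d_true.shape != d_pred.shape:
        raise ValueError(f"shape mismatch: {d_true.shape} vs {d_pred.shape}")
    if d_true.size == 0:
        raise ValueError("mse_loss of empty vectors is undefined")
    return float(np.mean((d_true - d_pred) ** 2))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation regimen.

    Defaults: Adam at learning rate 1e-3, batches of 50 tiles, the
    learning rate halved every 20 epochs, and training stopped once the
    best test loss has not improved by >1% for ``plateau_patience``
    consecutive epochs.
    """

    batch_size: int = 50
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 20
    max_epochs: int = 100
    plateau_patience: int = 10
    plateau_rtol: float = 0.01
    augment_flips: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LossTrace:
    """Per-epoch train/test losses (normalised-label MSE)."""

    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "lr": self.learning_rate,
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
            }
        ).to_csv(Path(path), index=False)


class Adam:
    """Adam optimiser over a network's parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= update.astype(p.value.dtype)


def _epoch_pass(net: LDSENet, x: np.ndarray, y_norm: np.ndarray, batch_size: int,
                opt: Adam, rng: np.random.Generator, augment_flips: bool) -> float:
    order = rng.permutation(len(x))
    total, count = 0.0, 0
    for start in range(0, len(x), batch_size):
        idx = order[start : start + batch_size]
        xb, yb = x[idx], y_norm[idx]
        if augment_flips:
            # horizontal/vertical flips preserve both the defocus level and
            # the astigmatic orientation cue (axes are not exchanged)
            fh = rng.random(len(idx)) < 0.5
            fv = rng.random(len(idx)) < 0.5
            xb = xb.copy()
            xb[fh] = xb[fh, :, :, ::-1]
            xb[fv] = xb[fv, :, ::-1, :]
        net.zero_grad()
        pred = net.forward(xb, train=True)
        err = pred - yb
        loss = float(np.mean(err.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss {loss} at optimiser step {opt.t}"
            )
        net.backward((2.0 / len(idx)) * err.astype(pred.dtype))
        opt.step()
        total += loss * len(idx)
        count += len(idx)
    return total / count


def _eval_loss(net: LDSENet, x: np.ndarray, y_norm: np.ndarray, batch_size: int) -> float:
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(net.forward(x[start : start + batch_size], train=False))
    return mse_loss(y_norm, np.concatenate(preds))


def train(
    net: LDSENet,
    train_data: tuple[np.ndarray, np.ndarray],
    test_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    log: Callable[[str], None] | None = None,
) -> tuple[LDSENet, LossTrace]:
    """Fit the network; returns the best-test-loss weights and the trace.

    ``train_data``/``test_data`` are ``(images, z_um)`` pairs with images
    shaped ``(N, C, S, S)`` in [0, 1] and labels in micrometres; the two
    sets must be disjoint (this is the caller's contract — use a
    field-level split).  Everything (shuffling, initial weights via the
    network's own seed) is deterministic given the seeds.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    x_tr, y_tr = train_data
    x_te, y_te = test_data
    x_tr = np.asarray(x_tr, dtype=net.dtype)
    x_te = np.asarray(x_te, dtype=net.dtype)
    yn_tr = net.normalize_labels(y_tr)
    yn_te = net.normalize_labels(y_te)

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    trace = LossTrace()
    best_loss = np.inf
    best_weights = net.get_weights()
    best_buffers = net.get_buffers()
    stall = 0

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)
        tr_loss = _epoch_pass(net, x_tr, yn_tr, cfg.batch_size, opt, rng, cfg.augment_flips)
        te_loss = _eval_loss(net, x_te, yn_te, cfg.batch_size)
        trace.train_loss.append(tr_loss)
        trace.test_loss.append(te_loss)
        trace.learning_rate.append(opt.lr)
        if log is not None:
            log(f"epoch {epoch:3d} lr {opt.lr:.2e} train_loss {tr_loss:.6f} test_loss {te_loss:.6f}")
        if te_loss < best_loss * (1.0 - cfg.plateau_rtol):
            stall = 0
        else:
            stall += 1
        if te_loss < best_loss:
            best_loss = te_loss
            best_weights = net.get_weights()
            best_buffers = net.get_buffers()
            trace.best_epoch = epoch
        if stall >= cfg.plateau_patience:
            break

    net.set_weights(best_weights)
    net.set_buffers(best_buffers)
    return net, trace
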