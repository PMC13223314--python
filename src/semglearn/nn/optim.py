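"""Optimization machinery: AdamW, plateau LR scheduling, early stopping.

The shared :func:`fit` loop drives every training stage in the package
(autoencoder, classifier head, user calibration, class-expansion phases):
AdamW updates on trainable parameters only, a learning-rate scheduler that
halves the rate when validation loss plateaus, early stopping with
best-validation weight restoration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Module
from .tensor import Parameter


@dataclass
class TrainConfig:
    """Hyperparameters shared by all training stages.

    Defaults: learning rate 1e-3, batch 64, early-stop patience 10 epochs,
    plateau patience 5 epochs with factor 0.5 down to min_lr 1e-5.
    """

    batch_size: int = 64
    max_epochs: int = 100
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_lr: float = 1e-5
    weight_decay: float = 1e-4

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.early_stop_patience,
               self.plateau_patience, self.min_lr) <= 0 or self.max_epochs < 0:
            raise ValueError("TrainConfig values must be positive")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")


class AdamW:
    """AdamW: Adam with decoupled weight decay (decay skipped for biases
    and other 1-D parameters, the usual convention)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if p.data.ndim > 1 and self.weight_decay > 0:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the optimizer's LR by ``factor`` after ``patience`` epochs
    without validation improvement; never below ``min_lr``."""

    def __init__(self, opt: AdamW, factor: float, patience: int, min_lr: float):
        self.opt = opt
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0


def fit(model: Module, batch_loss_fn, val_loss_fn, n_train: int,
        tc: TrainConfig, rng: np.random.Generator) -> dict:
    """Generic mini-batch training loop.

    ``batch_loss_fn(indices)`` returns the scalar loss Tensor for a batch of
    training indices; ``val_loss_fn()`` returns the float validation loss.
    Restores the best-validation parameters before returning the history.
    Raises ``FloatingPointError`` if the loss becomes non-finite.
    """
    opt = AdamW(model.parameters(), lr=tc.learning_rate,
                weight_decay=tc.weight_decay)
    sched = ReduceLROnPlateau(opt, tc.plateau_factor, tc.plateau_patience, tc.min_lr)
    history = {"train_loss": [], "val_loss": [], "lr": [], "stopped_epoch": 0}
    # the starting parameters take part in best-val selection, so a stage
    # that never improves validation ends exactly where it began
    best_val = float(val_loss_fn()) if tc.max_epochs > 0 else np.inf
    history["initial_val_loss"] = best_val if np.isfinite(best_val) else None
    best_state = model.state_dict()
    bad = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            opt.zero_grad()
            loss = batch_loss_fn(idx)
            loss_value = float(loss.data.item())
            if not np.isfinite(loss_value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss_value}")
            loss.backward()
            opt.step()
            losses.append(loss_value)
        vl = float(val_loss_fn())
        if not np.isfinite(vl):
            raise FloatingPointError(f"validation loss non-finite at epoch {epoch}")
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["val_loss"].append(vl)
        history["lr"].append(opt.lr)
        history["stopped_epoch"] = epoch + 1
        if vl < best_val - 1e-12:
            best_val = vl
            best_state = model.state_dict()
            bad = 0
        else:
            bad += 1
            if bad >= tc.early_stop_patience:
                break
        sched.step(vl)
    model.load_state_dict(best_state)
    return history
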