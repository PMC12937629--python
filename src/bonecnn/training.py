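"""Training procedure: Adam, cosine annealing with warm restarts,
categorical cross-entropy on logits, early stopping on validation loss.

The loop mirrors common supervised-classification practice: per epoch,
minibatches of the (shuffled, seeded) training tensors are stepped with
Adam at the epoch's scheduled learning rate; the validation set is then
scored in evaluation mode.  The lowest validation loss defines the best
checkpoint, and training stops once the validation loss has failed to
improve for ``early_stop_patience`` consecutive epochs (any decrease
resets the counter).  All randomness — weight init (on the model side),
data order, dropout — flows from the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError, InputError
from .model import BoneCNN, save_checkpoint


@dataclass
class TrainConfig:
    """Optimiser, schedule and stopping hyperparameters.

    Defaults: Adam(beta1=0.9, beta2=0.999) at 1e-4, batch 8, at most 60
    epochs with patience 8.  The cosine warm-restart schedule restarts
    every ``restart_period`` epochs, each cycle ``period_multiplier``
    times longer than the last, decaying to ``min_lr``.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    max_epochs: int = 60
    early_stop_patience: int = 8
    restart_period: int = 10
    period_multiplier: int = 2
    min_lr: float = 0.0
    mixed_precision: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.early_stop_patience < 1:
            raise ConfigurationError(f"patience must be >= 1, got {self.early_stop_patience}")
        if self.restart_period < 1 or self.period_multiplier < 1:
            raise ConfigurationError("restart_period and period_multiplier must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch trace: losses, accuracies, learning rate."""

    rows: list[dict] = field(default_factory=list)
    best_epoch: int = 0  # 1-based epoch with minimum validation loss
    stopped_early: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy", "learning_rate"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def best_val_loss(self) -> float:
        return self.rows[self.best_epoch - 1]["val_loss"]

    def validate(self) -> None:
        losses = [r["val_loss"] for r in self.rows]
        if losses and losses[self.best_epoch - 1] != min(losses):
            raise ConfigurationError("best_epoch does not attain the minimum validation loss")


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


def lr_at(config: TrainConfig, fraction: float) -> float:
    """Cosine-annealed rate at a position within the current cycle.

    eta = eta_min + 0.5 * (eta_base - eta_min) * (1 + cos(pi * fraction)).
    """
    if not 0.0 <= fraction <= 1.0:
        raise InputError(f"cycle fraction must lie in [0, 1], got {fraction}")
    return config.min_lr + 0.5 * (config.learning_rate - config.min_lr) * (
        1.0 + math.cos(math.pi * fraction)
    )


def cycle_position(config: TrainConfig, epoch: int) -> tuple[int, float]:
    """Map a 0-based epoch to (cycle index, fraction within cycle).

    Cycle lengths are T0, T0*m, T0*m^2, ... (warm restarts)."""
    t = config.restart_period
    e = epoch
    cycle = 0
    while e >= t:
        e -= t
        t *= config.period_multiplier
        cycle += 1
    return cycle, e / t


def lr_for_epoch(config: TrainConfig, epoch: int) -> float:
    """Scheduled learning rate for a 0-based epoch index."""
    _, frac = cycle_position(config, epoch)
    return lr_at(config, frac)


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------


class EarlyStopper:
    """Patience rule on validation loss; any decrease resets the counter."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ConfigurationError("patience must be >= 1")
        self.patience = patience
        self.best = math.inf
        self.best_epoch = 0
        self.since_best = 0

    def update(self, epoch: int, val_loss: float) -> tuple[bool, bool]:
        """Feed one epoch's validation loss (1-based epoch).

        Returns ``(is_best, should_stop)``."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_best = 0
            return True, False
        self.since_best += 1
        return False, self.since_best >= self.patience


def simulate_early_stopping(val_losses: list[float], patience: int) -> tuple[int, int]:
    """Run the patience rule over a loss trace.

    Returns ``(stop_epoch, best_epoch)`` where ``stop_epoch`` is the
    1-based epoch after which training halts (``len(val_losses)`` if the
    rule never triggers)."""
    stopper = EarlyStopper(patience)
    for epoch, loss in enumerate(val_losses, start=1):
        _, stop = stopper.update(epoch, loss)
        if stop:
            return epoch, stopper.best_epoch
    return len(val_losses), stopper.best_epoch


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def evaluate_loss(
    model: BoneCNN, x: np.ndarray, y: np.ndarray, batch_size: int = 32
) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in evaluation mode."""
    total, correct, loss_sum = 0, 0, 0.0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = nn.cross_entropy(logits, yb)
        loss_sum += loss * len(xb)
        correct += int((logits.argmax(axis=1) == yb).sum())
        total += len(xb)
    return loss_sum / total, correct / total


def train_model(
    model: BoneCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> tuple[BoneCNN, TrainingHistory]:
    """Fit the network; returns it with the best-epoch weights restored.

    Training metrics are running averages over the epoch's minibatches
    (i.e. computed with the weights as they moved); validation metrics
    come from a clean evaluation-mode pass after the epoch.
    """
    if len(x_train) == 0:
        raise InputError("empty training set")
    if len(x_val) == 0:
        raise InputError("empty validation set")
    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(np.random.default_rng(config.seed + 1))
    opt = nn.Adam(model.params(), lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    stopper = EarlyStopper(config.early_stop_patience)
    history = TrainingHistory()
    best_state = model.get_state()

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_for_epoch(config, epoch - 1)
        opt.lr = lr
        order = rng.permutation(len(x_train))
        loss_sum, correct, seen = 0.0, 0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss} (lr={lr:.2e})"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            loss_sum += loss * len(xb)
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += len(xb)
        val_loss, val_acc = evaluate_loss(model, x_val, y_val, batch_size=max(config.batch_size, 32))
        history.rows.append(
            {
                "epoch": epoch,
                "train_loss": loss_sum / seen,
                "train_accuracy": correct / seen,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "learning_rate": lr,
            }
        )
        is_best, should_stop = stopper.update(epoch, val_loss)
        if is_best:
            best_state = model.get_state()
        if should_stop:
            history.stopped_early = True
            break

    history.best_epoch = stopper.best_epoch
    model.set_state(best_state)
    history.validate()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, history


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def training_diagnostics(history: TrainingHistory, eps: float = 1e-3) -> dict:
    """Convergence summary of a history.

    ``overfit_gap`` is final validation loss minus final training loss.
    ``epoch_to_plateau`` is the first (1-based) epoch after which the
    running-minimum validation loss never again improves by ``eps`` or
    more.
    """
    if not history.rows:
        raise InputError("empty training history")
    final = history.rows[-1]
    gap = final["val_loss"] - final["train_loss"]
    losses = [r["val_loss"] for r in history.rows]
    n = len(losses)
    plateau = n
    for e in range(1, n + 1):
        running_min = min(losses[:e])
        future = losses[e:]
        if not future or min(future) > running_min - eps:
            plateau = e
            break
    return {"overfit_gap": gap, "epoch_to_plateau": plateau}
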