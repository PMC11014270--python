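"""Training protocol: Adam, MSE loss, validation split, early stopping, repeats.

The validation rows are the trailing ``n - floor((1 - val_fraction) * n)``
rows after a single seed-keyed shuffle of the training set (so 315 training
spectra at a 10% validation fraction give exactly 32 validation spectra).
Early stopping watches the validation loss with the configured patience and
restores the best weights. When ``n_repeats > 1`` the whole run is repeated
with fresh initializations and the repeat with the lowest best validation
loss is kept; ``epochs_run`` accumulates over repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import ConfigurationError, DomainError, TrainingDivergedError
from .architectures import ARCHITECTURES, Network, build_model
from .optim import Adam

#: per-architecture defaults: batch size, max epochs, learning rate, patience
ARCH_DEFAULTS = {
    "simple_cnn": dict(batch_size=128, max_epochs=1000, learning_rate=5e-3, patience=200),
    "s_alexnet": dict(batch_size=16, max_epochs=300, learning_rate=1e-5, patience=300),
    "resnet": dict(batch_size=160, max_epochs=1000, learning_rate=1e-5, patience=200),
    "googlenet": dict(batch_size=160, max_epochs=1000, learning_rate=1e-5, patience=200),
}


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run (loss is fixed to MSE)."""

    arch: str = "simple_cnn"
    batch_size: int = 128
    max_epochs: int = 1000
    learning_rate: float = 5e-3
    val_fraction: float = 0.10
    patience: int = 200
    n_repeats: int = 11
    seed: int = 42

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.arch!r}")
        if not 0.0 < self.val_fraction < 1.0:
            raise DomainError("val_fraction must be in (0, 1)")
        if min(self.batch_size, self.max_epochs, self.patience, self.n_repeats) < 1:
            raise DomainError("batch_size, max_epochs, patience, n_repeats must be >= 1")

    @classmethod
    def for_arch(cls, arch: str, **overrides) -> "TrainingConfig":
        """Architecture defaults with optional overrides."""
        if arch not in ARCH_DEFAULTS:
            raise ConfigurationError(f"unknown architecture {arch!r}")
        kw = dict(ARCH_DEFAULTS[arch])
        kw.update(overrides)
        return cls(arch=arch, **kw)

    def to_dict(self) -> dict:
        return {"arch": self.arch, "batch_size": self.batch_size,
                "max_epochs": self.max_epochs, "learning_rate": self.learning_rate,
                "val_fraction": self.val_fraction, "patience": self.patience,
                "n_repeats": self.n_repeats, "seed": self.seed}


def validation_split(n_train: int, val_fraction: float = 0.10, seed: int = 42):
    """(fit_idx, val_idx): trailing complement after one seeded shuffle.

    |val| = n_train - floor((1 - val_fraction) * n_train).
    """
    if n_train < 2:
        raise DomainError("need at least two training rows")
    n_fit = int(math.floor((1.0 - val_fraction) * n_train))
    if n_fit < 1 or n_fit >= n_train:
        raise DomainError(
            f"val_fraction {val_fraction} leaves no fit or no validation rows at n={n_train}")
    perm = np.random.default_rng(seed).permutation(n_train)
    return perm[:n_fit], perm[n_fit:]


def mse_loss(pred: np.ndarray, y: np.ndarray):
    """Mean squared error and its gradient w.r.t. the (N, 1) predictions."""
    diff = pred.ravel() - y
    loss = float(np.mean(diff ** 2))
    dpred = (2.0 / y.size) * diff[:, None]
    return loss, dpred


@dataclass
class TrainedRegressor:
    """An opaque fitted predictor with its training history."""

    network: Network
    config: TrainingConfig
    history: dict
    epochs_run: int
    best_validation_loss: float
    repeat_epochs: list = field(default_factory=list)

    @property
    def arch(self) -> str:
        return self.network.arch

    @property
    def input_length(self) -> int:
        return self.network.input_length

    def predict(self, X) -> np.ndarray:
        """Percent predictions for (k, m) input; deterministic; no clipping."""
        return self.network.predict(X)


def _run_single(net: Network, X_fit, y_fit, X_val, y_val,
                config: TrainingConfig, rng: np.random.Generator):
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    wait = 0
    n_fit = len(X_fit)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        batch_losses = []
        for start in range(0, n_fit, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = net.forward(X_fit[idx], training=True)
            loss, dpred = mse_loss(pred, y_fit[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            net.backward(dpred)
            opt.step()
            batch_losses.append(loss)
        val_loss, _ = mse_loss(net.forward(X_val, training=False), y_val)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    net.set_weights(best_weights)
    return len(history["val_loss"]), best_val, best_epoch, history


def train(model: Network | None, X_train, y_train,
          config: TrainingConfig) -> TrainedRegressor:
    """Fit per the protocol; returns the best repeat as a TrainedRegressor.

    ``model`` seeds the first repeat (built from ``config`` when None);
    further repeats use fresh initializations keyed to ``config.seed``.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DomainError(f"X {X.shape} incompatible with {y.size} targets")
    fit_idx, val_idx = validation_split(len(y), config.val_fraction, config.seed)
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    best = None
    total_epochs = 0
    repeat_epochs = []
    for r in range(config.n_repeats):
        rep_seed = (config.seed + 10007 * r) % (2 ** 31)
        if r == 0 and model is not None:
            net = model
        else:
            net = build_model(config.arch, X.shape[1], seed=rep_seed)
        rng = np.random.default_rng(rep_seed + 1)
        epochs, best_val, _, history = _run_single(
            net, X_fit, y_fit, X_val, y_val, config, rng)
        total_epochs += epochs
        repeat_epochs.append(epochs)
        if best is None or best_val < best[0]:
            best = (best_val, net, history)
    best_val, net, history = best
    return TrainedRegressor(network=net, config=config, history=history,
                            epochs_run=total_epochs, best_validation_loss=best_val,
                            repeat_epochs=repeat_epochs)
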