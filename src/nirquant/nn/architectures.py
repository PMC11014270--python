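"""The four one-dimensional deep regressor architectures.

Each maps an SNV-scaled spectrum of length m to one linear output unit
(percent adulteration). The four designs keep their namesakes' defining
mechanisms at a size trainable on a few hundred spectra:

* ``simple_cnn``  — two conv/pool stages and a small dense head.
* ``s_alexnet``   — five convolution layers (first with stride 4), three
  max-pools, two dense layers: a slimmed AlexNet.
* ``resnet``      — strided stem plus four pre-activation residual blocks
  with identity shortcuts, global average pooling.
* ``googlenet``   — strided stem plus two inception modules with parallel
  1/3/5-wide and pooled branches, global average pooling.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, DimensionError
from .layers import (BatchNorm1D, Conv1D, Dense, Flatten, GlobalAvgPool1D,
                     InceptionModule, MaxPool1D, ReLU, ResidualBlock, Sequential)

ARCHITECTURES = ("simple_cnn", "s_alexnet", "resnet", "googlenet")

MIN_INPUT_LENGTH = 16


class Network:
    """A trainable regressor: Sequential body + bookkeeping."""

    def __init__(self, arch: str, body: Sequential, input_length: int):
        self.arch = arch
        self.body = body
        self.input_length = input_length

    def parameters(self):
        return self.body.parameters()

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @property
    def output_dim(self) -> int:
        return self.body.out_shape((1, self.input_length))[0]

    def forward(self, X, training=False):
        """X is (N, m); returns (N, 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise DimensionError(
                f"expected (N, {self.input_length}) input, got {X.shape}")
        if X.shape[0] == 0:
            return np.zeros((0, 1))
        return self.body.forward(X[:, None, :], training=training)

    def backward(self, dout):
        return self.body.backward(dout)

    def predict(self, X) -> np.ndarray:
        return self.forward(X, training=False).ravel()

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p.data[...] = w


def _build_body(arch: str, rng: np.random.Generator, input_length: int) -> Sequential:
    if arch == "simple_cnn":
        head = Sequential(
            Conv1D(1, 32, 7, rng=rng), ReLU(), MaxPool1D(2),
            Conv1D(32, 64, 5, rng=rng), ReLU(), MaxPool1D(2),
            Flatten(),
        )
        (flat,) = head.out_shape((1, input_length))
        return Sequential(*head.layers,
                          Dense(flat, 64, rng=rng), ReLU(), Dense(64, 1, rng=rng))
    if arch == "s_alexnet":
        head = Sequential(
            Conv1D(1, 48, 11, stride=4, rng=rng), ReLU(), MaxPool1D(2),
            Conv1D(48, 128, 5, padding="same", rng=rng), ReLU(), MaxPool1D(2),
            Conv1D(128, 192, 3, padding="same", rng=rng), ReLU(),
            Conv1D(192, 192, 3, padding="same", rng=rng), ReLU(),
            Conv1D(192, 128, 3, padding="same", rng=rng), ReLU(), MaxPool1D(2),
            Flatten(),
        )
        (flat,) = head.out_shape((1, input_length))
        return Sequential(*head.layers,
                          Dense(flat, 256, rng=rng), ReLU(),
                          Dense(256, 128, rng=rng), ReLU(), Dense(128, 1, rng=rng))
    if arch == "resnet":
        return Sequential(
            Conv1D(1, 32, 7, stride=2, rng=rng), ReLU(),
            ResidualBlock(32, 32, rng=rng),
            ResidualBlock(32, 32, rng=rng),
            ResidualBlock(32, 64, rng=rng),
            ResidualBlock(64, 64, rng=rng),
            BatchNorm1D(64), ReLU(),
            GlobalAvgPool1D(), Dense(64, 1, rng=rng),
        )
    if arch == "googlenet":
        return Sequential(
            Conv1D(1, 32, 7, stride=2, rng=rng), ReLU(), MaxPool1D(2),
            InceptionModule(32, 16, 32, 8, 8, rng=rng),
            InceptionModule(64, 32, 48, 12, 12, rng=rng),
            GlobalAvgPool1D(), Dense(104, 1, rng=rng),
        )
    raise ConfigurationError(
        f"unknown architecture {arch!r}; expected one of {ARCHITECTURES}")


def _min_admissible_length(arch: str, upper: int = 4096) -> int | None:
    for L in range(2, upper):
        try:
            rng = np.random.default_rng(0)
            _build_body(arch, rng, L).out_shape((1, L))
            return L
        except ConfigurationError:
            continue
    return None


def build_model(arch: str, input_length: int, seed: int = 0) -> Network:
    """Untrained regressor of the given architecture for length-m spectra.

    Raises ConfigurationError for an unknown tag or an input too short for
    the architecture's pooling stack (the message reports the minimal
    admissible length).
    """
    if arch not in ARCHITECTURES:
        raise ConfigurationError(
            f"unknown architecture {arch!r}; expected one of {ARCHITECTURES}")
    if input_length < MIN_INPUT_LENGTH:
        raise ConfigurationError(
            f"input_length must be >= {MIN_INPUT_LENGTH}, got {input_length}")
    rng = np.random.default_rng(seed)
    try:
        body = _build_body(arch, rng, input_length)
        body.out_shape((1, input_length))
    except ConfigurationError as exc:
        min_len = _min_admissible_length(arch)
        raise ConfigurationError(
            f"input length {input_length} too short for {arch}; minimal "
            f"admissible length is {min_len} ({exc})") from exc
    return Network(arch, body, input_length)
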