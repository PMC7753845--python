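"""Fully connected tanh autoencoder with a penalized cross-entropy objective.

Architecture (widths configurable; defaults follow the study design):

    input d -> 550 (tanh) -> 275 bottleneck (tanh) -> 1100 (tanh) -> d (logistic)

The reconstruction objective for an input row ``x`` in [0, 1]^d and its
reconstruction ``x'`` in (0, 1)^d is the negated cross-entropy

    logloss(x, x') = -sum_k [ x_k log x'_k + (1 - x_k) log(1 - x'_k) ]

penalized by an L1 term on every weight matrix (coefficient ``alpha_w``) and
an L2 term on the bottleneck activation (coefficient ``alpha_a``):

    L = logloss(x, x') + sum_i alpha_w * ||W_i||_1 + alpha_a * ||h_bottleneck||_2^2

Training is plain minibatch SGD with inverted dropout on the hidden-layer
activations; inference (``transform``) runs without dropout.  All gradients
are derived analytically and are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import StackedMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-7  # reconstruction clip: x' in [eps, 1 - eps]


@dataclass
class AutoencoderConfig:
    """Widths, penalties and optimizer settings.

    ``hidden_widths`` are the three hidden layers in order: encoder hidden,
    bottleneck, decoder hidden.  ``epochs=10`` and ``dropout=0.5`` are the
    study defaults; ``alpha_w`` (L1 on weights) and ``alpha_a`` (L2 on the
    bottleneck activity) default to 1e-4 / 1e-5.
    """

    hidden_widths: tuple[int, int, int] = (550, 275, 1100)
    epochs: int = 10
    dropout: float = 0.5
    alpha_w: float = 1e-4
    alpha_a: float = 1e-5
    learning_rate: float = 5.0
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_widths) != 3 or any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden_widths must be three positive layer widths")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.alpha_w < 0 or self.alpha_a < 0:
            raise ValueError("penalty coefficients must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    @property
    def bottleneck_width(self) -> int:
        return self.hidden_widths[1]


@dataclass
class TrainedAutoencoder:
    """Fitted weights/biases plus the config and per-epoch loss trace.

    ``weights[i]`` has shape (fan_in, fan_out); the forward pass for layer i
    is ``activation(h @ weights[i] + biases[i])`` with tanh on the three
    hidden layers and the logistic function on the output layer.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: AutoencoderConfig
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = self.layer_widths
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (widths[i], widths[i + 1]) or b.shape != (widths[i + 1],):
                raise ValueError(f"layer {i} parameter shapes inconsistent with config")

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    @property
    def layer_widths(self) -> list[int]:
        d = self.weights[0].shape[0]
        return [d, *self.config.hidden_widths, d]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAutoencoder":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a TrainedAutoencoder")
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def layer_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "tanh"
) -> np.ndarray:
    """One layer: activation(x @ W + b); ``activation`` is tanh, logistic or linear."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != W.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} does not match weight fan-in {W.shape[0]}")
    z = x @ W + b
    if activation == "tanh":
        return np.tanh(z)
    if activation == "logistic":
        return _sigmoid(z)
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _forward(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Forward pass; returns (raw tanh activations a1..a3, [h1..h3, x']).

    ``raw`` holds the pre-dropout tanh outputs (needed for the backward
    pass); ``post`` holds the activations actually fed forward, i.e. with
    the inverted-dropout masks applied when given, plus the logistic
    reconstruction as the last element.
    """
    raw, post = [], []
    h = X
    for i in range(3):
        a = layer_forward(h, weights[i], biases[i], "tanh")
        raw.append(a)
        h = a * dropout_masks[i] if dropout_masks is not None else a
        post.append(h)
    post.append(layer_forward(h, weights[3], biases[3], "logistic"))
    return raw, post


def reconstruction_objective(
    x: np.ndarray,
    x_prime: np.ndarray,
    weights: list[np.ndarray] | None = None,
    alpha_w: float = 0.0,
    alpha_a: float = 0.0,
    bottleneck: np.ndarray | None = None,
) -> float:
    """Penalized cross-entropy between an input and its reconstruction.

    ``x`` must lie in [0, 1]; ``x_prime`` is clipped into (0, 1).  With both
    penalties zero this is the plain (negated) cross-entropy, minimized at
    perfect reconstruction.  For 2-D inputs the cross-entropy and activity
    terms are averaged over rows.
    """
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("input x outside [0, 1]: rescale the stacked matrix to [0, 1] first")
    xp = np.clip(xp, _EPS, 1.0 - _EPS)
    ce = -(x * np.log(xp) + (1.0 - x) * np.log(1.0 - xp))
    if x.ndim == 2:
        loss = float(ce.sum(axis=1).mean())
    else:
        loss = float(ce.sum())
    if alpha_w and weights is not None:
        loss += alpha_w * float(sum(np.abs(W).sum() for W in weights))
    if alpha_a and bottleneck is not None:
        bn = np.asarray(bottleneck, dtype=float)
        sq = (bn**2).sum(axis=-1)
        loss += alpha_a * float(np.mean(sq) if bn.ndim == 2 else sq)
    return loss


def _loss_and_grads(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    alpha_w: float,
    alpha_a: float,
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Batch loss and analytic gradients w.r.t. every weight and bias.

    Loss = mean over rows of [cross-entropy + alpha_a * ||h2||^2]
         + alpha_w * sum_i ||W_i||_1.
    """
    n = X.shape[0]
    raw, post = _forward(X, weights, biases, dropout_masks)
    a1, a2, a3 = raw
    h1, h2, h3, xp = post
    xp_c = np.clip(xp, _EPS, 1.0 - _EPS)
    ce = -(X * np.log(xp_c) + (1.0 - X) * np.log(1.0 - xp_c))
    loss = float(ce.sum(axis=1).mean())
    loss += alpha_a * float((h2**2).sum(axis=1).mean())
    loss += alpha_w * float(sum(np.abs(W).sum() for W in weights))

    gW = [np.zeros_like(W) for W in weights]
    gb = [np.zeros_like(b) for b in biases]
    masks = dropout_masks if dropout_masks is not None else [1.0, 1.0, 1.0]

    # output layer: d(ce)/dz4 = x' - x for the logistic / cross-entropy pair
    delta = (xp_c - X) / n
    gW[3] = h3.T @ delta
    gb[3] = delta.sum(axis=0)

    # decoder hidden (tanh): dL/dz3 = (dL/dh3 * mask) * (1 - a3^2)
    delta = (delta @ weights[3].T) * masks[2] * (1.0 - a3**2)
    gW[2] = h2.T @ delta
    gb[2] = delta.sum(axis=0)

    # bottleneck (tanh); activity penalty contributes 2*alpha_a/n * h2 at h2
    dh2 = delta @ weights[2].T + (2.0 * alpha_a / n) * h2
    delta = dh2 * masks[1] * (1.0 - a2**2)
    gW[1] = h1.T @ delta
    gb[1] = delta.sum(axis=0)

    # encoder hidden (tanh)
    delta = (delta @ weights[1].T) * masks[0] * (1.0 - a1**2)
    gW[0] = X.T @ delta
    gb[0] = delta.sum(axis=0)

    # L1 subgradient on the weights
    if alpha_w:
        for i in range(4):
            gW[i] = gW[i] + alpha_w * np.sign(weights[i])
    return loss, gW, gb


def _init_params(
    widths: list[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Fan-based scaled-uniform (Glorot) initialization."""
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train(stacked: StackedMatrix, config: AutoencoderConfig | None = None) -> TrainedAutoencoder:
    """Fit the autoencoder by minibatch SGD on the penalized cross-entropy.

    Dropout applies to hidden activations during training only; the run is
    reproducible under a fixed ``config.seed``.  The returned loss trace
    holds the mean per-sample batch loss of each epoch.
    """
    cfg = config or AutoencoderConfig()
    X = stacked.values.to_numpy(dtype=float)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("stacked values must lie in [0, 1]; run stack_unit_norm first")
    n, d = X.shape
    widths = [d, *cfg.hidden_widths, d]
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(widths, rng)
    # start the output layer at the per-feature mean so the short training
    # budget is spent on structure rather than on learning the marginals
    mu = np.clip(X.mean(axis=0), 1e-4, 1.0 - 1e-4)
    biases[3][:] = np.log(mu / (1.0 - mu))

    keep = 1.0 - cfg.dropout
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            if cfg.dropout > 0:
                masks = [
                    (rng.random((batch.shape[0], w)) < keep).astype(float) / keep
                    for w in cfg.hidden_widths
                ]
            else:
                masks = None
            loss, gW, gb = _loss_and_grads(
                batch, weights, biases, cfg.alpha_w, cfg.alpha_a, masks
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    f"reduce learning_rate (currently {cfg.learning_rate})"
                )
            # step on the per-feature mean loss so the effective rate does
            # not grow with the input width d
            step = cfg.learning_rate / d
            for i in range(4):
                weights[i] -= step * gW[i]
                biases[i] -= step * gb[i]
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
        logger.debug("epoch %d/%d: loss %.4f", epoch + 1, cfg.epochs, trace[-1])

    return TrainedAutoencoder(weights=weights, biases=biases, config=cfg, loss_trace=trace)


def transform(model: TrainedAutoencoder, stacked: StackedMatrix) -> pd.DataFrame:
    """Bottleneck activations (no dropout): samples x bottleneck-width DataFrame."""
    X = stacked.values.to_numpy(dtype=float)
    if X.shape[1] != model.input_width:
        raise ValueError(
            f"stacked matrix has {X.shape[1]} features but the model expects "
            f"{model.input_width}"
        )
    h = layer_forward(X, model.weights[0], model.biases[0], "tanh")
    h = layer_forward(h, model.weights[1], model.biases[1], "tanh")
    cols = [f"AE{j:03d}" for j in range(h.shape[1])]
    return pd.DataFrame(h, index=stacked.sample_ids, columns=cols)


def reconstruct(model: TrainedAutoencoder, stacked: StackedMatrix) -> np.ndarray:
    """Full forward pass without dropout; returns the reconstruction x'."""
    X = stacked.values.to_numpy(dtype=float)
    return _forward(X, model.weights, model.biases)[1][-1]
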