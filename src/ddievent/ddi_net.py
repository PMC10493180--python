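"""The event classifier: a small fully connected network over pair encodings.

Architecture (defaults): input -> 512 (ReLU) -> dropout -> 256 (sigmoid) ->
dropout -> 128 (sigmoid) -> dropout -> softmax over the n event types.
Trained with minibatch Adam on cross-entropy against one-hot targets for a
fixed number of epochs; no early stopping. Everything (weight init, shuffling,
dropout masks) is driven by one seeded generator, so runs are reproducible
bit-for-bit.

Implemented directly on NumPy: the model is three dense layers, which keeps
the dependency surface small and makes determinism trivial to guarantee.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelConfig",
    "MLPClassifier",
    "build_model",
    "train",
    "predict_proba",
    "predict_event",
    "save_model",
    "load_model",
    "load_config",
]

_GRID_HIDDEN_SIZES = {128, 256, 512}
_GRID_DROPOUT = {0.1, 0.2, 0.3, 0.4, 0.5}


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    ``loss`` selects between categorical cross-entropy on the softmax output
    (default; the computation a softmax head with one-hot targets performs)
    and per-class binary cross-entropy on the same softmax output.
    """

    hidden_sizes: list[int] = field(default_factory=lambda: [512, 256, 128])
    dropout_rate: float = 0.3
    first_hidden_activation: str = "relu"
    other_hidden_activation: str = "sigmoid"
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    loss: str = "categorical_ce"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("categorical_ce", "per_class_bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        for name in (self.first_hidden_activation, self.other_hidden_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    def in_reference_grid(self) -> bool:
        """Whether this config lies on the published tuning grid."""
        return (
            1 <= len(self.hidden_sizes) <= 3
            and all(h in _GRID_HIDDEN_SIZES for h in self.hidden_sizes)
            and round(self.dropout_rate, 10) in _GRID_DROPOUT
        )

    @staticmethod
    def reference_grid(seed: int = 0) -> list["ModelConfig"]:
        """The tuning grid: 1-3 hidden layers, non-increasing widths from
        {512, 256, 128}, dropout in {0.1..0.5}."""
        from itertools import combinations_with_replacement

        grid = []
        for depth in (1, 2, 3):
            for sizes in combinations_with_replacement(sorted(_GRID_HIDDEN_SIZES, reverse=True), depth):
                for rate in sorted(_GRID_DROPOUT):
                    grid.append(
                        ModelConfig(hidden_sizes=list(sizes), dropout_rate=rate, seed=seed)
                    )
        return grid


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return (z > 0).astype(z.dtype)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return a * (1.0 - a)


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _tanh_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return 1.0 - a * a


_ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "tanh": (_tanh, _tanh_grad),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class MLPClassifier:
    """Dense softmax classifier with per-layer activations and dropout."""

    def __init__(self, config: ModelConfig, input_width: int, n_events: int):
        if input_width < 1 or n_events < 1:
            raise ValueError("input_width and n_events must be >= 1")
        self.config = config
        self.input_width = input_width
        self.n_events = n_events
        self.fitted = False
        self._rng = np.random.default_rng(config.seed)
        sizes = [input_width, *config.hidden_sizes, n_events]
        self.activations: list[str] = []
        for layer in range(len(config.hidden_sizes)):
            self.activations.append(
                config.first_hidden_activation if layer == 0 else config.other_hidden_activation
            )
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            act = self.activations[layer] if layer < len(self.activations) else "softmax"
            if act == "relu":  # He init; Glorot elsewhere
                scale = np.sqrt(2.0 / fan_in)
            else:
                scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(self._rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.loss_history: list[float] = []

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def _forward(
        self, x: np.ndarray, train_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; dropout is applied only when a training rng is given."""
        rate = self.config.dropout_rate
        cache = []
        a = x
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if layer < len(self.activations):
                fwd, _ = _ACTIVATIONS[self.activations[layer]]
                h = fwd(z)
                mask = None
                if train_rng is not None and rate > 0.0:
                    mask = (train_rng.random(h.shape) >= rate) / (1.0 - rate)
                    h = h * mask
                cache.append((a, z, h, mask))
                a = h
            else:
                probs = _softmax(z)
                cache.append((a, z, probs, None))
                a = probs
        return a, cache

    def _loss_and_output_grad(
        self, probs: np.ndarray, y_onehot: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Mean loss over the batch and gradient w.r.t. the output logits."""
        b = probs.shape[0]
        eps = 1e-12
        p = np.clip(probs, eps, 1.0 - eps)
        if self.config.loss == "categorical_ce":
            loss = float(-np.sum(y_onehot * np.log(p)) / b)
            dlogits = (probs - y_onehot) / b
        else:  # per-class BCE on the softmax outputs, averaged over classes
            k = probs.shape[1]
            loss = float(
                -np.sum(y_onehot * np.log(p) + (1.0 - y_onehot) * np.log(1.0 - p)) / (b * k)
            )
            dp = (p - y_onehot) / (p * (1.0 - p)) / (b * k)
            dlogits = probs * (dp - np.sum(dp * probs, axis=1, keepdims=True))
        return loss, dlogits

    def _backward(self, cache: list, dlogits: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        delta = dlogits
        for layer in range(len(self.weights) - 1, -1, -1):
            a_in, z, h, mask = cache[layer]
            grads[layer] = (a_in.T @ delta, delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.weights[layer].T
                a_prev, z_prev, h_prev, mask_prev = cache[layer - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                _, grad_fn = _ACTIVATIONS[self.activations[layer - 1]]
                # activation grad is taken at the pre-dropout activation
                act_val = h_prev if mask_prev is None else _ACTIVATIONS[
                    self.activations[layer - 1]
                ][0](z_prev)
                delta = delta * grad_fn(z_prev, act_val)
        return grads

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if x.shape[1] != self.input_width:
            raise ValueError(f"input width {x.shape[1]} != expected {self.input_width}")
        if y.min() < 0 or y.max() >= self.n_events:
            raise ValueError("event index out of range")
        present = np.bincount(y, minlength=self.n_events) > 0
        if not present.all():
            missing = np.flatnonzero(~present)
            warnings.warn(
                f"events absent from training labels (unlearnable here): {missing.tolist()}",
                stacklevel=2,
            )
        onehot = np.zeros((len(y), self.n_events))
        onehot[np.arange(len(y)), y] = 1.0

        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)  # shuffling + dropout stream
        # Adam state
        mom = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        vel = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(y)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = self._forward(x[idx], train_rng=rng)
                loss, dlogits = self._loss_and_output_grad(probs, onehot[idx])
                epoch_loss += loss * len(idx)
                grads = self._backward(cache, dlogits)
                step += 1
                params = self.weights + self.biases
                gs = [g for g, _ in grads] + [g for _, g in grads]
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for p, g, m, v in zip(params, gs, mom, vel):
                    m *= beta1
                    m += (1.0 - beta1) * g
                    v *= beta2
                    v += (1.0 - beta2) * g * g
                    p -= cfg.learning_rate * (m / corr1) / (np.sqrt(v / corr2) + eps)
            self.loss_history.append(epoch_loss / n)
        self.fitted = True
        return self

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained")
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.input_width:
            raise ValueError(f"input width {x.shape[1:]} != expected {self.input_width}")
        out = np.empty((x.shape[0], self.n_events))
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self._forward(x[start : start + batch_size], train_rng=None)
            out[start : start + batch_size] = probs
        return out


def build_model(config: ModelConfig, input_width: int, n_events: int) -> MLPClassifier:
    """Construct an untrained classifier for the given input/output widths."""
    return MLPClassifier(config, input_width, n_events)


def train(
    model: MLPClassifier, x: np.ndarray, y: np.ndarray, config: ModelConfig | None = None
) -> MLPClassifier:
    """Fit the model in place and return it (the "trained model")."""
    if config is not None and config is not model.config:
        model.config = config
    return model.fit(x, y)


def predict_proba(model: MLPClassifier, x: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix of event probabilities, dropout disabled."""
    return model.predict_proba(x)


def predict_event(probas: np.ndarray) -> np.ndarray:
    """Argmax event per row; ties resolve to the lowest event index."""
    return np.argmax(np.asarray(probas), axis=1)


def save_model(model: MLPClassifier, path: str | Path) -> None:
    """Serialize config + parameters to one ``.npz`` file."""
    arrays = {f"w{k}": w for k, w in enumerate(model.weights)}
    arrays |= {f"b{k}": b for k, b in enumerate(model.biases)}
    meta = {
        "config": asdict(model.config),
        "input_width": model.input_width,
        "n_events": model.n_events,
        "fitted": model.fitted,
        "loss_history": model.loss_history,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> MLPClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = MLPClassifier(
            ModelConfig(**meta["config"]), meta["input_width"], meta["n_events"]
        )
        model.weights = [data[f"w{k}"] for k in range(len(model.weights))]
        model.biases = [data[f"b{k}"] for k in range(len(model.biases))]
    model.fitted = meta["fitted"]
    model.loss_history = meta["loss_history"]
    return model


def load_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from a YAML key/value file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig(**raw)


def write_training_log(model: MLPClassifier, path: str | Path) -> None:
    lines = [f"seed\t{model.config.seed}"]
    lines += [f"epoch\t{k + 1}\tloss\t{loss:.10f}" for k, loss in enumerate(model.loss_history)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
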