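"""Three-layer back-propagation network for the weed/rice decision.

A deliberately classical implementation: sigmoid hidden and output
layers, one-hot targets, mean-squared-error loss, full-batch gradient
descent with momentum, and an adaptive learning rate that grows while
the error falls and shrinks (rejecting the step) when the error jumps.
The hidden-layer width must satisfy the Kolmogorov sizing rule
``D_h >= 2M + 1`` for ``M`` inputs; the default of 12 admits up to five
input features.

Inputs are z-scored with statistics learned on the training set; the
features span ~10 orders of magnitude in raw units (variance ~1e-6 V²
against a ~4.5 V mean), so training on raw columns would stall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["MLPConfig", "MLPModel", "train", "predict"]


@dataclass(frozen=True)
class MLPConfig:
    """Training hyper-parameters for the back-propagation network."""

    hidden_size: int = 12
    output_size: int = 2
    learning_rate: float = 0.5
    lr_increase: float = 1.05   # applied after an epoch that improves the error
    lr_decrease: float = 0.7    # applied when the error worsens beyond the ratio
    max_error_ratio: float = 1.04
    momentum: float = 0.9
    goal: float = 1e-3          # stop when the mean squared error falls below
    max_epochs: int = 5000

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.output_size < 1:
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")

    def validate_input_size(self, n_inputs: int) -> None:
        minimum = 2 * n_inputs + 1
        if self.hidden_size < minimum:
            raise ValueError(
                f"hidden layer of {self.hidden_size} violates the sizing rule: "
                f"{n_inputs} inputs need at least {minimum} hidden neurons"
            )


@dataclass
class MLPModel:
    """A trained network: weights, standardisation statistics, history."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    offset: np.ndarray            # per-feature z-score mean
    scale: np.ndarray             # per-feature z-score std (1 where degenerate)
    classes: List[str]
    history: List[Tuple[int, float]] = field(default_factory=list)
    feature_names: Optional[List[str]] = None

    @property
    def input_size(self) -> int:
        return self.w1.shape[0]

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "offset": self.offset.tolist(),
            "scale": self.scale.tolist(),
            "history": [[int(e), float(m)] for e, m in self.history],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPModel":
        return cls(
            w1=np.asarray(payload["w1"], float),
            b1=np.asarray(payload["b1"], float),
            w2=np.asarray(payload["w2"], float),
            b2=np.asarray(payload["b2"], float),
            offset=np.asarray(payload["offset"], float),
            scale=np.asarray(payload["scale"], float),
            classes=list(payload["classes"]),
            history=[(int(e), float(m)) for e, m in payload.get("history", [])],
            feature_names=payload.get("feature_names"),
        )

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model_w, X: np.ndarray):
    w1, b1, w2, b2 = model_w
    hidden = _sigmoid(X @ w1 + b1)
    output = _sigmoid(hidden @ w2 + b2)
    return hidden, output


def _mse(output: np.ndarray, targets: np.ndarray) -> float:
    return float(np.mean((output - targets) ** 2))


def _gradients(X, targets, weights):
    """Analytic MSE gradients for the two sigmoid layers."""
    w1, b1, w2, b2 = weights
    hidden, output = _forward(weights, X)
    delta_out = 2.0 * (output - targets) / targets.size * output * (1.0 - output)
    g_w2 = hidden.T @ delta_out
    g_b2 = delta_out.sum(axis=0)
    delta_hidden = (delta_out @ w2.T) * hidden * (1.0 - hidden)
    g_w1 = X.T @ delta_hidden
    g_b1 = delta_hidden.sum(axis=0)
    return (g_w1, g_b1, g_w2, g_b2), _mse(output, targets)


def train(
    features,
    labels: Sequence[str],
    config: MLPConfig = MLPConfig(),
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> MLPModel:
    """Train the network on a labelled feature table.

    Full-batch gradient descent; each epoch's step uses momentum over
    the previous accepted step.  After an epoch the learning rate is
    multiplied by ``lr_increase`` if the error fell, and if the error
    rose by more than ``max_error_ratio`` the step is rejected, the
    momentum memory cleared and the rate multiplied by ``lr_decrease``.
    Stops at ``goal`` or ``max_epochs``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table")
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    config.validate_input_size(X.shape[1])

    offset = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - offset) / scale
    targets = np.zeros((X.shape[0], max(config.output_size, len(classes))))
    for i, c in enumerate(classes):
        targets[y == c, i] = 1.0

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB9]))
    n_in, n_hidden, n_out = X.shape[1], config.hidden_size, targets.shape[1]
    weights = [
        rng.uniform(-0.5, 0.5, size=(n_in, n_hidden)) / np.sqrt(n_in),
        np.zeros(n_hidden),
        rng.uniform(-0.5, 0.5, size=(n_hidden, n_out)) / np.sqrt(n_hidden),
        np.zeros(n_out),
    ]
    velocity = [np.zeros_like(w) for w in weights]
    lr = config.learning_rate
    _, error = _gradients(Xs, targets, weights)
    history = [(0, error)]

    for epoch in range(1, config.max_epochs + 1):
        grads, _ = _gradients(Xs, targets, weights)
        step = [config.momentum * v - lr * g for v, g in zip(velocity, grads)]
        proposal = [w + s for w, s in zip(weights, step)]
        _, new_error = _gradients(Xs, targets, proposal)
        if new_error > error * config.max_error_ratio and lr > 1e-12:
            lr *= config.lr_decrease
            velocity = [np.zeros_like(w) for w in weights]
        else:
            weights = proposal
            velocity = step
            if new_error < error:
                lr *= config.lr_increase
            error = new_error
        history.append((epoch, error))
        if error <= config.goal:
            break

    return MLPModel(
        w1=weights[0],
        b1=weights[1],
        w2=weights[2],
        b2=weights[3],
        offset=offset,
        scale=scale,
        classes=classes,
        history=history,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def predict(model: MLPModel, features) -> Tuple[np.ndarray, np.ndarray]:
    """Classify a feature table; returns (labels, output scores)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_size:
        raise ValueError(
            f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not match "
            f"the model's {model.input_size} inputs"
        )
    Xs = (X - model.offset) / model.scale
    _, output = _forward((model.w1, model.b1, model.w2, model.b2), Xs)
    indices = np.argmax(output[:, : len(model.classes)], axis=1)
    labels = np.array([model.classes[i] for i in indices])
    return labels, output
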