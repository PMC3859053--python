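"""Small feed-forward neural network classifier.

The classifier mirrors the deployment architecture: d input units (the
KDA-projected feature dimension), one hidden layer of 3 logistic-sigmoid
units, and one softmax output unit per activity class, trained by
mini-batch gradient descent on the cross-entropy loss. Training is
deterministic given the seed (weights initialized uniform(-0.5, 0.5),
shuffling driven by the same generator), so a trained model can be
serialized, shipped to the device and reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, FormatError, ParameterError

_FORMAT_VERSION = 1


@dataclass
class ANNModel:
    """Weights of a [d, hidden, C] network plus the class-name table."""

    w1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h, C)
    b2: np.ndarray  # (C,)
    class_names: list[str]
    training_config: dict = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[0], self.w1.shape[1], self.w2.shape[1])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: ANNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hidden = _sigmoid(x @ model.w1 + model.b1)
    return hidden, _softmax(hidden @ model.w2 + model.b2)


def train_ann(
    features,
    labels,
    hidden_size: int = 3,
    learning_rate: float = 0.1,
    epochs: int = 500,
    batch_size: int = 32,
    momentum: float = 0.9,
    seed: int = 0,
    class_names: list[str] | None = None,
) -> ANNModel:
    """Train the [d, hidden, C] softmax classifier by mini-batch descent.

    Classic momentum (default 0.9) accelerates convergence of the tiny
    network. ``class_names`` fixes the output ordering; by default classes
    are the sorted unique labels. Bit-identical results for identical
    inputs and seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"features must be 2-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("features contain non-finite values")
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ParameterError("features and labels length mismatch")
    if class_names is None:
        class_names = sorted(str(c) for c in np.unique(labels))
    n_classes = len(class_names)
    if n_classes < 2:
        raise ParameterError(f"need at least 2 classes, got {n_classes}")
    index = {name: i for i, name in enumerate(class_names)}
    try:
        y = np.array([index[str(c)] for c in labels])
    except KeyError as exc:
        raise ParameterError(f"label {exc} not in class_names") from exc

    n, d = x.shape
    rng = np.random.default_rng(seed)
    model = ANNModel(
        w1=rng.uniform(-0.5, 0.5, size=(d, hidden_size)),
        b1=rng.uniform(-0.5, 0.5, size=hidden_size),
        w2=rng.uniform(-0.5, 0.5, size=(hidden_size, n_classes)),
        b2=rng.uniform(-0.5, 0.5, size=n_classes),
        class_names=list(class_names),
        training_config={
            "hidden_size": hidden_size,
            "learning_rate": learning_rate,
            "epochs": epochs,
            "batch_size": batch_size,
            "momentum": momentum,
            "seed": seed,
        },
    )
    onehot = np.eye(n_classes)[y]
    batch = min(batch_size, n)
    vel = {
        "w1": np.zeros_like(model.w1),
        "b1": np.zeros_like(model.b1),
        "w2": np.zeros_like(model.w2),
        "b2": np.zeros_like(model.b2),
    }
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch):
            sel = perm[start : start + batch]
            xb, tb = x[sel], onehot[sel]
            hidden, probs = _forward(model, xb)
            delta_out = (probs - tb) / sel.size
            grad_w2 = hidden.T @ delta_out
            grad_b2 = delta_out.sum(axis=0)
            delta_hid = (delta_out @ model.w2.T) * hidden * (1.0 - hidden)
            grad_w1 = xb.T @ delta_hid
            grad_b1 = delta_hid.sum(axis=0)
            for key, grad in (
                ("w1", grad_w1), ("b1", grad_b1), ("w2", grad_w2), ("b2", grad_b2)
            ):
                vel[key] = momentum * vel[key] - learning_rate * grad
                setattr(model, key, getattr(model, key) + vel[key])
        _, probs = _forward(model, x)
        eps = 1e-12
        model.loss_history.append(float(-np.mean(np.log(probs[np.arange(n), y] + eps))))
    return model


def predict(model: ANNModel, x) -> tuple[str, np.ndarray]:
    """Class label and softmax score vector for one input.

    Scores are non-negative and sum to 1; ties break toward the
    lower class index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.w1.shape[0],):
        raise ParameterError(
            f"input dimension {x.shape} != model input ({model.w1.shape[0]},)"
        )
    _, probs = _forward(model, x[None, :])
    scores = probs[0]
    return model.class_names[int(np.argmax(scores))], scores


def predict_batch(model: ANNModel, x) -> tuple[list[str], np.ndarray]:
    """Vectorized :func:`predict` over the rows of a 2-D array."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.w1.shape[0]:
        raise ParameterError(
            f"inputs must be (n, {model.w1.shape[0]}), got {x.shape}"
        )
    _, probs = _forward(model, x)
    labels = [model.class_names[i] for i in np.argmax(probs, axis=1)]
    return labels, probs


def model_to_dict(model: ANNModel) -> dict:
    return {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "class_names": model.class_names,
        "training_config": model.training_config,
    }


def model_from_dict(payload: dict) -> ANNModel:
    try:
        model = ANNModel(
            w1=np.asarray(payload["w1"], dtype=float),
            b1=np.asarray(payload["b1"], dtype=float),
            w2=np.asarray(payload["w2"], dtype=float),
            b2=np.asarray(payload["b2"], dtype=float),
            class_names=list(payload["class_names"]),
            training_config=dict(payload.get("training_config", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid ANN model payload: {exc}") from exc
    sizes = tuple(payload.get("layer_sizes", model.layer_sizes))
    if sizes != model.layer_sizes:
        raise FormatError(
            f"declared layer sizes {sizes} do not match weights {model.layer_sizes}"
        )
    return model


def save_model(model: ANNModel, path) -> None:
    """Serialize a model to JSON (floats use round-trip repr)."""
    with open(path, "w") as handle:
        json.dump(model_to_dict(model), handle)


def load_model(path) -> ANNModel:
    """Load a JSON model; predictions round-trip bit-exactly."""
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"model file {path} does not hold an object")
    return model_from_dict(payload)
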