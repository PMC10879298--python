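"""Three-class softmax network over trajectory features.

A deliberately small multilayer perceptron: eight fully connected
hidden layers of 10, 20, 32, 64, 64, 32, 20 and 10 rectified-linear
units, then a 3-unit softmax output, trained with categorical
cross-entropy under RMSprop at its conventional default learning rate
(0.001) for a fixed number of epochs with no early stopping.

The network is implemented directly on NumPy with the standard
conventions of deep-learning frameworks: Glorot-uniform weight
initialisation, zero biases, RMSprop with rho = 0.9 and epsilon = 1e-7,
uniform minibatch shuffling per epoch. All randomness (initial weights,
batch order) derives from the config seed, so a train/evaluate run is
bit-reproducible on one machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_builder import FeatureRecord, ShapeError
from .track_io import ClassLabel, LabelError

__all__ = [
    "ModelConfig",
    "DenseSoftmaxNet",
    "TrainResult",
    "ConfusionMatrix",
    "build_model",
    "train",
    "predict",
    "evaluate",
    "confusion_matrix",
    "parameter_count",
]

logger = logging.getLogger(__name__)

_CLASSES = (ClassLabel.M0, ClassLabel.M1, ClassLabel.M2)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters."""

    hidden_sizes: tuple[int, ...] = (10, 20, 32, 64, 64, 32, 20, 10)
    output_size: int = 3
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_size != 3:
            raise ValueError("output_size must be 3 (M0, M1, M2)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("all hidden sizes must be >= 1")


@dataclass
class TrainResult:
    """Per-epoch histories plus the trained model."""

    loss: list[float]
    accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    model: "DenseSoftmaxNet"


@dataclass
class ConfusionMatrix:
    """3x3 confusion counts, true classes in rows, predictions in columns.

    Rows are labeled by the morphology clusters used as ground truth
    (Cluster C, P, E), columns by the predicted subtype (M0, M1, M2).
    """

    counts: np.ndarray  # (3, 3) ints

    row_labels: tuple[str, ...] = ("Cluster C", "Cluster P", "Cluster E")
    col_labels: tuple[str, ...] = ("M0", "M1", "M2")

    @property
    def percent(self) -> np.ndarray:
        """Row-normalized percentages; empty rows stay all-zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return 100.0 * self.counts / safe

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Diagonal of the percent matrix, as fractions in [0, 1]."""
        return np.diag(self.percent) / 100.0

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseSoftmaxNet:
    """Fully connected relu stack with a softmax head, trained by RMSprop."""

    def __init__(self, input_dim: int, config: ModelConfig):
        if input_dim < 1:
            raise ValueError("input feature length must be known and >= 1")
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        sizes = (input_dim, *config.hidden_sizes, config.output_size)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        # RMSprop gradient-square accumulators
        self._sw = [np.zeros_like(w) for w in self.weights]
        self._sb = [np.zeros_like(b) for b in self.biases]
        self._shuffle_rng = np.random.default_rng(config.seed + 1)

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; last entry is the softmax output."""
        acts = [X]
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            acts.append(_softmax(z) if i == len(self.weights) - 1 else _relu(z))
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ShapeError(
                f"feature length {X.shape[1]} does not match model input "
                f"{self.input_dim}"
            )
        return self._forward(X)[-1]

    # -- training ----------------------------------------------------------

    def train_batch(self, X: np.ndarray, Y: np.ndarray) -> None:
        """One RMSprop step on a minibatch (Y one-hot)."""
        acts = self._forward(X)
        n = len(X)
        delta = (acts[-1] - Y) / n  # softmax + cross-entropy gradient
        cfg = self.config
        for i in range(len(self.weights) - 1, -1, -1):
            gw = acts[i].T @ delta
            gb = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
            self._sw[i] = cfg.rho * self._sw[i] + (1 - cfg.rho) * gw**2
            self._sb[i] = cfg.rho * self._sb[i] + (1 - cfg.rho) * gb**2
            self.weights[i] -= cfg.learning_rate * gw / (
                np.sqrt(self._sw[i]) + cfg.epsilon
            )
            self.biases[i] -= cfg.learning_rate * gb / (
                np.sqrt(self._sb[i]) + cfg.epsilon
            )

    def evaluate_arrays(self, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
        """(cross-entropy loss, accuracy) on arrays with one-hot targets."""
        P = self.predict_proba(X)
        eps = 1e-12
        loss = float(-(Y * np.log(P + eps)).sum(axis=1).mean())
        acc = float((P.argmax(axis=1) == Y.argmax(axis=1)).mean())
        return loss, acc

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(
            path,
            hidden_sizes=np.array(self.config.hidden_sizes),
            input_dim=np.array(self.input_dim),
            seed=np.array(self.config.seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DenseSoftmaxNet":
        data = np.load(path)
        config = ModelConfig(
            hidden_sizes=tuple(int(h) for h in data["hidden_sizes"]),
            seed=int(data["seed"]),
        )
        net = cls(int(data["input_dim"]), config)
        n_layers = len(net.weights)
        net.weights = [data[f"w{i}"] for i in range(n_layers)]
        net.biases = [data[f"b{i}"] for i in range(n_layers)]
        return net


def parameter_count(input_dim: int, config: ModelConfig) -> int:
    """Number of trainable weights and biases of the configured network."""
    sizes = (input_dim, *config.hidden_sizes, config.output_size)
    return sum(a * b + b for a, b in zip(sizes, sizes[1:]))


def build_model(config: ModelConfig, input_dim: int) -> DenseSoftmaxNet:
    """Construct the seeded, untrained network for a given feature length."""
    return DenseSoftmaxNet(input_dim, config)


def _to_arrays(records: list[FeatureRecord]) -> tuple[np.ndarray, np.ndarray]:
    lengths = {len(r.features) for r in records}
    if len(lengths) > 1:
        raise ShapeError(f"inconsistent feature lengths: {sorted(lengths)}")
    X = np.stack([r.features for r in records])
    Y = np.stack([r.onehot for r in records])
    return X, Y


def train(
    model: DenseSoftmaxNet,
    train_records: list[FeatureRecord],
    validation_records: list[FeatureRecord],
    config: ModelConfig | None = None,
) -> TrainResult:
    """Train for exactly ``config.epochs`` epochs; no early stopping.

    Histories (train/validation loss and accuracy) are recorded once
    per epoch on the full sets. A class missing from the training set
    is logged as a warning but training proceeds.
    """
    config = config or model.config
    if not train_records or not validation_records:
        raise ValueError("train and validation sets must be non-empty")
    Xtr, Ytr = _to_arrays(train_records)
    Xva, Yva = _to_arrays(validation_records)
    if Xtr.shape[1] != model.input_dim:
        raise ShapeError(
            f"feature length {Xtr.shape[1]} does not match model input "
            f"{model.input_dim}"
        )
    present = set(np.flatnonzero(Ytr.sum(axis=0)))
    for cls in _CLASSES:
        if cls.index not in present:
            logger.warning("class %s absent from the training set", cls.value)

    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    n = len(Xtr)
    for _ in range(config.epochs):
        order = model._shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.train_batch(Xtr[idx], Ytr[idx])
        tr_loss, tr_acc = model.evaluate_arrays(Xtr, Ytr)
        va_loss, va_acc = model.evaluate_arrays(Xva, Yva)
        history["loss"].append(tr_loss)
        history["accuracy"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
    return TrainResult(
        history["loss"], history["accuracy"],
        history["val_loss"], history["val_accuracy"], model,
    )


def predict(
    model: DenseSoftmaxNet, records: list[FeatureRecord]
) -> tuple[np.ndarray, list[ClassLabel]]:
    """Class probabilities and argmax labels per record.

    Ties break toward the lower class index (M0 < M1 < M2), which is
    what argmax-first gives.
    """
    X = np.stack([r.features for r in records])
    probs = model.predict_proba(X)
    labels = [_CLASSES[i] for i in probs.argmax(axis=1)]
    return probs, labels


def confusion_matrix(
    true_labels: list[ClassLabel], predicted_labels: list[ClassLabel]
) -> ConfusionMatrix:
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, predicted_labels, strict=True):
        counts[t.index, p.index] += 1
    return ConfusionMatrix(counts)


def evaluate(
    model: DenseSoftmaxNet, validation_records: list[FeatureRecord]
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and overall accuracy on labeled records."""
    if not validation_records:
        raise ValueError("validation set is empty")
    missing = [r.cell_id for r in validation_records if r.label is None]
    if missing:
        raise LabelError(f"unlabeled validation records: {missing[:5]}")
    _, predicted = predict(model, validation_records)
    cm = confusion_matrix([r.label for r in validation_records], predicted)
    return cm, cm.overall_accuracy
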