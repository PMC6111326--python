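"""Pose-sequence exercise recognition: augmentation, training, evaluation.

Real recordings of one exercise repetition differ mainly in how long each
pose is held, so training data is produced by *dwell-time augmentation*:
each pose of the canonical sequence is repeated a uniform-random 1-10
times (drawn independently per pose and per sample), then the sequence is
tail-truncated to a fixed frame budget and right-padded with 0.  Collapsing
the runs of any un-truncated sample recovers the canonical sequence
exactly, so augmentation preserves completeness.

The classifier is a 32-unit gated-recurrent-unit network with a dense
softmax head, trained with log loss and Adam (see :mod:`rehabcoach._gru`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._gru import GRUClassifier
from .exercises import ExerciseDefinition, pose_alphabet_size

#: Frame budget all sequences are truncated/padded to.
DEFAULT_MAX_LENGTH = 47


@dataclass(frozen=True)
class AugmentationConfig:
    """Dwell-time augmentation parameters."""

    repeat_min: int = 1
    repeat_max: int = 10
    max_length: int = DEFAULT_MAX_LENGTH
    pad_value: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.repeat_min <= self.repeat_max:
            raise ValueError("need 1 <= repeat_min <= repeat_max")
        if self.max_length < 1:
            raise ValueError("max_length must be positive")


@dataclass
class SequenceDataset:
    """Fixed-length label sequences with aligned exercise names."""

    X: np.ndarray  # (N, max_length) int labels, 0-padded
    y: np.ndarray  # (N,) int class indices into `classes`
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def labels(self) -> list[str]:
        return [self.classes[i] for i in self.y]

    def per_class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.y, minlength=len(self.classes))
        return dict(zip(self.classes, counts.tolist()))


@dataclass
class ClassifierModel:
    """Trained recognizer: the network plus its class names and meta."""

    net: GRUClassifier
    classes: tuple[str, ...]
    max_length: int
    meta: dict = field(default_factory=dict)


def generate_augmented(
    definition: ExerciseDefinition,
    count: int,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """``count`` augmented sequences for one exercise, shape (count, max_length).

    Pose ``i`` of the canonical sequence is repeated ``n_i`` times with
    ``n_i`` drawn uniformly from {repeat_min..repeat_max}, order preserved;
    the raw sequence is then truncated to ``max_length`` (keeping the head)
    and right-padded with ``pad_value``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    canonical = np.asarray(definition.canonical, dtype=np.int64)
    k = canonical.size
    reps = rng.integers(cfg.repeat_min, cfg.repeat_max + 1, size=(count, k))
    out = np.full((count, cfg.max_length), cfg.pad_value, dtype=np.int64)
    for i in range(count):
        seq = np.repeat(canonical, reps[i])[: cfg.max_length]
        out[i, : seq.size] = seq
    return out


def build_dataset(
    catalogue: Sequence[ExerciseDefinition],
    per_class_train: int,
    per_class_test: int,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[SequenceDataset, SequenceDataset]:
    """Balanced, independently drawn train/test splits over ``catalogue``."""
    classes = tuple(d.name for d in catalogue)
    splits = []
    for per_class in (per_class_train, per_class_test):
        if per_class < 1:
            raise ValueError("per-class counts must be >= 1")
        X = np.concatenate(
            [generate_augmented(d, per_class, cfg, rng) for d in catalogue]
        )
        y = np.repeat(np.arange(len(classes)), per_class)
        splits.append(SequenceDataset(X=X, y=y, classes=classes))
    return splits[0], splits[1]


def train_classifier(
    train: SequenceDataset,
    epochs: int = 10,
    units: int = 32,
    seed: int = 0,
    embed_dim: int = 8,
    batch_size: int = 128,
    vocab_size: int | None = None,
) -> ClassifierModel:
    """Train the GRU classifier; returns the model with its loss curve."""
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if vocab_size is None:
        vocab_size = int(train.X.max())
    net = GRUClassifier(
        n_classes=len(train.classes),
        vocab_size=vocab_size,
        units=units,
        embed_dim=embed_dim,
        seed=seed,
    )
    net.fit(train.X, train.y, epochs=epochs, batch_size=batch_size)
    return ClassifierModel(
        net=net,
        classes=train.classes,
        max_length=train.X.shape[1],
        meta={
            "epochs": epochs,
            "seed": seed,
            "loss": list(net.history["loss"]),
            "train_accuracy": list(net.history["accuracy"]),
        },
    )


def classify(
    model: ClassifierModel, seq: Sequence[int] | np.ndarray
) -> tuple[str, np.ndarray]:
    """Predicted exercise name and the full class posterior for one sequence."""
    arr = np.asarray(seq, dtype=np.int64).ravel()
    if arr.size > model.max_length:
        raise ValueError(
            f"sequence length {arr.size} exceeds model input length {model.max_length}"
        )
    padded = np.zeros(model.max_length, dtype=np.int64)
    padded[: arr.size] = arr
    probs = model.net.predict_proba(padded[None, :])[0]
    return model.classes[int(probs.argmax())], probs


def evaluate(
    model: ClassifierModel, test: SequenceDataset
) -> tuple[float, np.ndarray]:
    """Accuracy (fraction correct) and confusion matrix (rows = true class)."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = model.net.predict(test.X)
    k = len(model.classes)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (test.y, pred), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())
    return accuracy, confusion


def train_accuracy(model: ClassifierModel, train: SequenceDataset) -> float:
    """Fraction correct on the training split with the final weights."""
    return float(np.mean(model.net.predict(train.X) == train.y))


def canonical_dataset(
    catalogue: Sequence[ExerciseDefinition], max_length: int = DEFAULT_MAX_LENGTH
) -> SequenceDataset:
    """The un-repeated canonical sequence of each exercise, padded."""
    classes = tuple(d.name for d in catalogue)
    X = np.zeros((len(catalogue), max_length), dtype=np.int64)
    for i, d in enumerate(catalogue):
        X[i, : len(d.canonical)] = d.canonical
    return SequenceDataset(X=X, y=np.arange(len(catalogue)), classes=classes)
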