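"""Dataset splitting, model training, self-attention feature extraction and fusion.

Training follows the reference recipe: stochastic gradient descent with
momentum 0.702, initial learning rate 2e-4, mini-batch 64, constant schedule,
and a stratified 60:10:30 train/validation/test split (a 70:30 split is
available via ``TrainConfig.split``).  Deep features are tapped at each
model's self-attention layer — N x 1024 for BRwSA and N x 512 for IBRwSA —
and fused by column concatenation into an N x 1536 matrix.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from .architectures import ArchitectureGraph, GraphNet, extract_feature_width
from . import nn

__all__ = [
    "TrainConfig",
    "FeatureMatrix",
    "TrainingError",
    "split_dataset",
    "train_model",
    "extract_features",
    "fuse",
]


class TrainingError(RuntimeError):
    """Raised when optimization diverges; carries the offending epoch index."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    momentum: float = 0.702
    minibatch: int = 64
    epochs: int = 100
    seed: int = 0
    split: tuple[float, float, float] = (0.60, 0.10, 0.30)

    def __post_init__(self) -> None:
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class FeatureMatrix:
    """N x d feature values with integer labels and per-column provenance tags."""

    values: np.ndarray
    labels: np.ndarray
    column_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.column_tags:
            self.column_tags = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.column_tags) != self.values.shape[1]:
            raise ValueError("one tag per column required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def select(self, columns: np.ndarray) -> "FeatureMatrix":
        columns = np.asarray(columns)
        if columns.dtype == bool:
            columns = np.flatnonzero(columns)
        return FeatureMatrix(
            self.values[:, columns],
            self.labels,
            [self.column_tags[int(j)] for j in columns],
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.values, columns=self.column_tags)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), labels, list(df.columns))


def split_dataset(
    items: list, labels: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[tuple, tuple, tuple]:
    """Stratified train/validation/test split.

    Returns three ``(items, labels)`` pairs.  Per class, ``floor`` of the
    train and validation fractions go to those partitions and the remainder
    to test, so 10 samples split 6/1/3 and 100 split 60/10/30.  Deterministic
    given ``cfg.seed``; partitions are disjoint and exhaustive.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx, te_idx = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 4:
            raise ValueError(f"class {cls} has fewer than 4 samples")
        idx = rng.permutation(idx)
        n_tr = int(np.floor(cfg.split[0] * len(idx)))
        n_va = int(np.floor(cfg.split[1] * len(idx)))
        tr_idx.extend(idx[:n_tr])
        va_idx.extend(idx[n_tr : n_tr + n_va])
        te_idx.extend(idx[n_tr + n_va :])

    def take(indices):
        indices = np.array(sorted(indices), dtype=int)
        picked = [items[i] for i in indices]
        return picked, labels[indices]

    return take(tr_idx), take(va_idx), take(te_idx)


def _resize_batch(images: list[np.ndarray] | np.ndarray, side: int) -> np.ndarray:
    out = []
    warned = False
    for img in images:
        img = np.asarray(img, dtype=float)
        if img.shape[:2] != (side, side):
            if not warned:
                warnings.warn(f"resizing images to {side}x{side} model input")
                warned = True
            img = resize(img, (side, side, 3), order=1, anti_aliasing=False)
        out.append(img)
    return np.stack(out)


def train_model(
    graph: ArchitectureGraph,
    train: tuple,
    val: tuple | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[GraphNet, dict]:
    """Train a graph with SGD + momentum; returns the model and per-epoch history.

    ``train`` / ``val`` are ``(images, labels)`` pairs.  History holds
    ``train_loss``, ``train_acc`` and, when a validation set is given,
    ``val_loss`` / ``val_acc`` per epoch.  Non-finite loss aborts with
    :class:`TrainingError` carrying the epoch index.
    """
    cfg = cfg or TrainConfig()
    images, labels = train
    labels = np.asarray(labels, dtype=int)
    n_classes = graph.num_classes
    if labels.max() >= n_classes:
        raise ValueError("label outside the model's class range")
    side = graph.input_shape[0]
    x = _resize_batch(images, side)
    rng = np.random.default_rng(cfg.seed)
    model = GraphNet(graph, rng=rng)
    opt = nn.SGDMomentum(model.trainable_layers(), cfg.learning_rate, cfg.momentum)

    if val is not None and len(val[0]) == 0:
        val = None
    history: dict[str, list[float]] = {"train_loss": [], "train_acc": []}
    if val is not None:
        history["val_loss"] = []
        history["val_acc"] = []
        xv = _resize_batch(val[0], side)
        yv = np.asarray(val[1], dtype=int)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.minibatch):
            batch = order[start : start + cfg.minibatch]
            loss = model.loss_and_grads(x[batch], labels[batch])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch)
            opt.step()
            losses.append(loss)
        probs = model.predict_proba(x)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float((probs.argmax(1) == labels).mean()))
        if val is not None:
            pv = model.predict_proba(xv)
            ce = -np.log(np.maximum(pv[np.arange(len(yv)), yv], 1e-300)).mean()
            history["val_loss"].append(float(ce))
            history["val_acc"].append(float((pv.argmax(1) == yv).mean()))
    return model, history


def extract_features(
    model: GraphNet,
    images: list[np.ndarray] | np.ndarray,
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Self-attention layer activations as an N x width feature matrix.

    Images whose size differs from the model input are resized with a
    warning.  Column tags record the producing model.
    """
    side = model.graph.input_shape[0]
    x = _resize_batch(images, side)
    feats = model.features(x)
    width = extract_feature_width(model.graph)
    assert feats.shape[1] == width
    if labels is None:
        labels = np.zeros(len(x), dtype=int)
    tags = [f"{model.graph.name}:attn{i}" for i in range(width)]
    return FeatureMatrix(feats, labels, tags)


def fuse(fa: FeatureMatrix, fb: FeatureMatrix) -> FeatureMatrix:
    """Concatenation fusion: columns of ``fa`` first, then ``fb``."""
    if fa.n != fb.n:
        raise ValueError("row counts differ")
    if not np.array_equal(fa.labels, fb.labels):
        raise ValueError("label vectors differ")
    if fb.width == 0:
        return FeatureMatrix(fa.values.copy(), fa.labels, list(fa.column_tags))
    return FeatureMatrix(
        np.hstack([fa.values, fb.values]),
        fa.labels,
        list(fa.column_tags) + list(fb.column_tags),
    )
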