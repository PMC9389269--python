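"""Seeded training loop (Adam + cross-entropy) and posterior prediction.

The loop mirrors common practice for small classifiers: stratified
80/20 train/validation split of the supplied indices, per-epoch shuffled
mini-batches, augmentation applied only in train mode, and the weights
with the best validation accuracy returned.  Everything is driven by
``numpy`` generators seeded from the config, so a rerun with the same
seed reproduces the loss curve bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split

from ..errors import DegenerateDataset, InvalidConfiguration
from .core import Adam, softmax, softmax_cross_entropy
from .models import Model

__all__ = ["TrainConfig", "ArrayDataset", "train_modality", "predict_posteriors"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one modality's training run.

    Defaults follow the image-modality recipe (Adam, lr 1e-4, batch 32,
    80 epochs); the video recipe uses lr 1e-2, batch 1, 30 epochs.
    Desk-scale runs shrink ``epochs`` and ``batch_size`` via the
    experiment config, not here.
    """

    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 80
    seed: int = 0
    val_fraction: float = 0.2
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise InvalidConfiguration("learning rate must be nonnegative")
        if self.optimizer != "adam":
            raise InvalidConfiguration(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class ArrayDataset:
    """Samples plus the transforms that turn them into network input.

    ``train_transform(x, rng)`` performs seeded augmentation;
    ``eval_transform(x)`` is its deterministic counterpart.  With no
    transforms the raw arrays are fed as-is.
    """

    X: np.ndarray | list
    y: np.ndarray
    train_transform: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None
    eval_transform: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != self.y.size:
            raise InvalidConfiguration("X and y length mismatch")

    def __len__(self) -> int:
        return self.y.size

    def train_batch(self, idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.train_transform is None:
            return np.stack([np.asarray(self.X[i], dtype=float) for i in idx])
        return np.stack([self.train_transform(self.X[i], rng) for i in idx])

    def eval_batch(self, idx: np.ndarray) -> np.ndarray:
        if self.eval_transform is None:
            return np.stack([np.asarray(self.X[i], dtype=float) for i in idx])
        return np.stack([self.eval_transform(self.X[i]) for i in idx])


def _accuracy(model: Model, dataset: ArrayDataset, idx: np.ndarray, batch: int) -> float:
    correct = 0
    for start in range(0, idx.size, batch):
        chunk = idx[start : start + batch]
        logits = model.forward(dataset.eval_batch(chunk), train=False)
        correct += int(np.sum(np.argmax(logits, axis=1) == dataset.y[chunk]))
    return correct / idx.size


def train_modality(
    model: Model,
    dataset: ArrayDataset,
    cfg: TrainConfig,
    train_idx: np.ndarray | None = None,
) -> tuple[Model, list[dict]]:
    """Train ``model`` on ``dataset`` and return it with its history.

    ``train_idx`` restricts training to a subset (the non-test portion of
    a fold); the 80/20 train/validation split happens inside it.  The
    returned model carries the weights of the epoch with the best
    validation accuracy.
    """
    idx = np.arange(len(dataset)) if train_idx is None else np.asarray(train_idx)
    labels = dataset.y[idx]
    if np.unique(labels).size < 2:
        raise DegenerateDataset("training set must contain at least two classes")
    n_classes = np.unique(labels).size
    n_val = max(int(round(cfg.val_fraction * idx.size)), n_classes)
    # stratify only when the validation set can hold every class
    stratify = labels if np.min(np.bincount(labels)) >= 2 and n_val >= n_classes else None
    tr, val = train_test_split(
        idx,
        test_size=n_val,
        random_state=cfg.seed % (2**32),
        stratify=stratify,
    )
    rng = np.random.default_rng([cfg.seed, 0x7261696E])
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: list[dict] = []
    best_acc = -1.0
    best_state = model.state_dict()
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, cfg.batch_size):
            chunk = order[start : start + cfg.batch_size]
            xb = dataset.train_batch(chunk, rng)
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, dataset.y[chunk])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_acc = _accuracy(model, dataset, val, cfg.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def predict_posteriors(model: Model, x: np.ndarray) -> np.ndarray:
    """Softmax posteriors for a single input or a batch.

    A single sample may be passed without the batch axis; the result is
    then a length-``n_classes`` simplex vector.
    """
    arr = np.asarray(x, dtype=float)
    batch_ndim = 5 if model.kind == "video" else 4
    single = arr.ndim == batch_ndim - 1
    if single:
        arr = arr[None]
    logits = model.forward(arr, train=False)
    post = softmax(logits)
    return post[0] if single else post
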