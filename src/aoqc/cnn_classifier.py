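"""Compact CIFAR-style CNN grading 65 x 65 patches into three categories.

The network follows the small-image classification template: stacked
convolution → ReLU → 2x2 max-pool blocks, a dense hidden layer, and a
three-way softmax head, trained with SGD + momentum on cross-entropy.
Inputs are conditioned to exactly 65 x 65 px (center crop if larger,
mirror padding if smaller) and standardized per patch (z-score), so
brightness differences between acquisitions do not dominate the filters.
Class imbalance can be countered with inverse-frequency class weights.

The implementation is pure numpy (see :mod:`aoqc._nn`); convolutions run
through im2col + BLAS matmuls, which keeps training on a few thousand
patches to CPU-minutes. Training is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .patch import Patch, GradeCategory

__all__ = ["CnnConfig", "CnnModel", "TrainingHistory", "condition_input", "train", "predict", "predict_batch"]

INPUT_SIDE = 65
N_CLASSES = 3


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and optimization settings.

    ``conv_blocks`` is a sequence of (filters, kernel_size) pairs; every
    block is convolution → ReLU → 2x2 max-pool. ``fc_widths`` lists hidden
    dense widths before the softmax head.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((32, 5), (32, 5), (64, 5))
    fc_widths: tuple[int, ...] = (64,)
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 30
    class_weighting: bool = True
    monitor_fraction: float = 0.1
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_blocks:
            raise ValueError("at least one conv block required")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not (0 < self.monitor_fraction < 1):
            raise ValueError("monitor_fraction must be in (0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch train/monitor loss and accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    monitor_loss: list[float] = field(default_factory=list)
    monitor_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class CnnModel:
    """A trained (or initializable) network; see :func:`train`."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in, side = 1, INPUT_SIDE
        for filters, k in config.conv_blocks:
            layers += [_nn.Conv2D(c_in, filters, k, rng), _nn.ReLU(), _nn.MaxPool2()]
            c_in, side = filters, side // 2
        layers.append(_nn.Flatten())
        width = c_in * side * side
        for w in config.fc_widths:
            layers += [_nn.Dense(width, w, rng), _nn.ReLU()]
            width = w
        layers.append(_nn.Dense(width, N_CLASSES, rng))
        self.layers = layers
        self.trained = False

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Softmax probabilities for standardized inputs (N, 1, 65, 65)."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        out = [
            _nn.softmax(self._forward(x[i : i + batch]))
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(out, axis=0)


def condition_input(patch: Patch, side: int = INPUT_SIDE) -> Patch:
    """Bring a patch to exactly ``side`` x ``side`` px.

    Larger inputs are center-cropped (odd surpluses trimmed from the
    bottom/right); smaller ones are mirror-padded symmetrically (odd
    deficits padded on the bottom/right). Idempotent at the target side.
    """
    arr = patch.intensities
    for axis in (0, 1):
        n = arr.shape[axis]
        if n > side:
            start = (n - side) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + side)
            arr = arr[tuple(sl)]
        elif n < side:
            while arr.shape[axis] < side:
                deficit = side - arr.shape[axis]
                cur = arr.shape[axis]
                before = min(deficit // 2, cur)
                after = min(deficit - before, cur)
                pad = [(0, 0), (0, 0)]
                pad[axis] = (before, after)
                arr = np.pad(arr, pad, mode="symmetric")
    return Patch(
        intensities=arr, pixel_scale=patch.pixel_scale, provenance=patch.provenance
    )


def _standardize(arr: np.ndarray) -> np.ndarray:
    """Per-patch z-score; flat patches map to zeros."""
    mu = arr.mean()
    sd = arr.std()
    return (arr - mu) / sd if sd > 0 else arr - mu


def _to_tensor(patches: Sequence[Patch]) -> np.ndarray:
    out = np.empty((len(patches), 1, INPUT_SIDE, INPUT_SIDE), dtype=np.float32)
    for i, p in enumerate(patches):
        out[i, 0] = _standardize(condition_input(p).intensities)
    return out


def train(
    patches: Sequence[Patch],
    labels: Sequence[int],
    config: CnnConfig = CnnConfig(),
    subject_ids: Optional[Sequence[str]] = None,
) -> tuple[CnnModel, TrainingHistory]:
    """Train the compact CNN on labeled patches.

    A held-back *monitoring* subset (``config.monitor_fraction``, split by
    subject when ``subject_ids`` is given, otherwise by patch) tracks
    generalization each epoch; training stops early when monitoring loss
    has not improved for ``early_stop_patience`` epochs. Raises if any of
    the three categories is absent.
    """
    y = np.asarray(labels, dtype=int) - 1
    if set(np.unique(y)) != {0, 1, 2}:
        raise ValueError("training data must contain all three categories")
    x = _to_tensor(patches)

    rng = np.random.default_rng(config.seed)
    n = len(x)
    if subject_ids is not None:
        subjects = np.asarray(subject_ids)
        uniq = np.array(sorted(set(subjects)))
        order = rng.permutation(len(uniq))
        n_mon = max(1, int(round(config.monitor_fraction * len(uniq))))
        mon_subjects = set(uniq[order[:n_mon]])
        monitor_mask = np.isin(subjects, list(mon_subjects))
        if monitor_mask.all() or not monitor_mask.any():
            raise ValueError("monitoring split left one side empty")
    else:
        order = rng.permutation(n)
        n_mon = max(1, int(round(config.monitor_fraction * n)))
        monitor_mask = np.zeros(n, dtype=bool)
        monitor_mask[order[:n_mon]] = True

    x_tr, y_tr = x[~monitor_mask], y[~monitor_mask]
    x_mon, y_mon = x[monitor_mask], y[monitor_mask]

    if config.class_weighting:
        freq = np.bincount(y_tr, minlength=N_CLASSES) / len(y_tr)
        class_w = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-9), 0.0)
        class_w = (class_w / class_w[freq > 0].mean()).astype(np.float32)
    else:
        class_w = np.ones(N_CLASSES, dtype=np.float32)

    model = CnnModel(config)
    model.trained = True  # forward passes allowed during monitoring
    opt = _nn.SGDMomentum(model.layers, lr=config.learning_rate, momentum=config.momentum)
    history = TrainingHistory()
    best_loss, best_state, stale = np.inf, None, 0

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(x_tr))
        losses, correct, seen = [], 0, 0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model._forward(xb, train=True)
            probs = _nn.softmax(logits)
            loss, grad = _nn.cross_entropy(probs, yb, sample_weight=class_w[yb])
            model._backward(grad)
            opt.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == yb).sum())
            seen += len(yb)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(100.0 * correct / seen)

        probs_mon = model.predict_proba(x_mon)
        mon_loss, _ = _nn.cross_entropy(probs_mon, y_mon, sample_weight=class_w[y_mon])
        history.monitor_loss.append(mon_loss)
        history.monitor_accuracy.append(
            100.0 * float(np.mean(probs_mon.argmax(axis=1) == y_mon))
        )

        if mon_loss < best_loss - 1e-6:
            best_loss, stale = mon_loss, 0
            best_state = [
                [(name, param.copy()) for name, param, _ in layer.params]
                for layer in model.layers
                if layer.params
            ]
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    if best_state is not None:  # restore the best-monitored weights
        for layer, saved in zip(
            (l for l in model.layers if l.params), best_state
        ):
            for name, value in saved:
                getattr(layer, name)[...] = value
    return model, history


def predict(model: CnnModel, patch: Patch) -> tuple[GradeCategory, np.ndarray]:
    """Category and class-probability vector for one patch."""
    probs = model.predict_proba(_to_tensor([patch]))[0]
    return GradeCategory(int(probs.argmax()) + 1), probs


def predict_batch(
    model: CnnModel, patches: Sequence[Patch]
) -> tuple[np.ndarray, np.ndarray]:
    """Categories (1-3) and probability matrix for patches, in input order."""
    probs = model.predict_proba(_to_tensor(patches))
    return probs.argmax(axis=1) + 1, probs
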