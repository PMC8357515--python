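"""Plain SGD training on the half-MSE loss, reproducible from a seed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import CTSlice, BinaryMask
from .models import DilatedFCN, PatchCNN, normalize_hu
from .ops import mse_loss

__all__ = ["TrainingConfig", "LossRecord", "train"]


@dataclass
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 2.0
    seed: int = 0
    m: int | None = None  # loss divisor; defaults to outputs per batch
    binarize_threshold: float = 0.5
    patches_per_image: int = 16  # patch-classifier training only

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class LossRecord:
    epoch: int
    R: float


def _sgd_step(model, grad_prob: np.ndarray, lr: float) -> None:
    model.backward(grad_prob)
    for p, g in zip(model.parameters(), model.gradients()):
        p -= lr * g


def _check_finite(r: float, epoch: int) -> None:
    if not np.isfinite(r):
        raise RuntimeError(
            f"training diverged: non-finite loss at epoch {epoch}; "
            "reduce the learning rate"
        )


def train(
    model: DilatedFCN | PatchCNN,
    data: list[tuple[CTSlice, BinaryMask]],
    config: TrainingConfig,
) -> tuple[list[np.ndarray], list[LossRecord]]:
    """Minimize the half-MSE between probability maps and gold masks.

    Initializes the model weights from ``config.seed``, runs mini-batch
    SGD for ``config.epochs`` epochs and returns the (in-place updated)
    parameter list together with one loss record per epoch. Identical
    data, config and seed reproduce the run bit-for-bit.
    """
    if not data:
        raise ValueError("training data is empty")
    for ct, mask in data:
        if ct.pixels.shape != mask.shape:
            raise ValueError("slice/mask shape mismatch in training data")
    rng = np.random.default_rng(config.seed)
    model.init_weights(rng)
    if isinstance(model, PatchCNN):
        records = _train_patches(model, data, config, rng)
    else:
        records = _train_dense(model, data, config, rng)
    return model.parameters(), records


def _train_dense(model, data, config, rng) -> list[LossRecord]:
    x = np.stack([normalize_hu(ct.pixels) for ct, _ in data])[:, None]
    y = np.stack([m for _, m in data]).astype(np.float64)[:, None]
    n = x.shape[0]
    records = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            out = model.forward(xb)
            m = config.m or out.size
            r = mse_loss(yb, out, m)
            losses.append(r)
            _sgd_step(model, (out - yb) / m, config.learning_rate)
        r_epoch = float(np.mean(losses))
        _check_finite(r_epoch, epoch)
        records.append(LossRecord(epoch=epoch, R=r_epoch))
    return records


def _train_patches(model, data, config, rng) -> list[LossRecord]:
    p = model.patch_size
    half = p // 2
    padded = [
        np.pad(normalize_hu(ct.pixels), ((half, p - 1 - half),) * 2, mode="reflect")
        for ct, _ in data
    ]
    masks = [np.asarray(m, dtype=bool) for _, m in data]
    pos_idx = [np.flatnonzero(m) for m in masks]
    neg_idx = [np.flatnonzero(~m) for m in masks]
    records = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        losses = []
        batch_x, batch_y = [], []
        for i in order:
            h, w = masks[i].shape
            k = config.patches_per_image
            npos = min(k // 2, pos_idx[i].size)
            chosen = []
            if npos:
                chosen.append(rng.choice(pos_idx[i], size=npos))
            chosen.append(rng.choice(neg_idx[i], size=k - npos))
            for flat in np.concatenate(chosen):
                r, c = divmod(int(flat), w)
                batch_x.append(padded[i][r : r + p, c : c + p])
                batch_y.append(float(masks[i][r, c]))
                if len(batch_x) >= config.batch_size * 8:
                    losses.append(_patch_step(model, batch_x, batch_y, config))
                    batch_x, batch_y = [], []
        if batch_x:
            losses.append(_patch_step(model, batch_x, batch_y, config))
            batch_x, batch_y = [], []
        r_epoch = float(np.mean(losses))
        _check_finite(r_epoch, epoch)
        records.append(LossRecord(epoch=epoch, R=r_epoch))
    return records


def _patch_step(model, batch_x, batch_y, config) -> float:
    x = np.stack(batch_x)[:, None]
    y = np.asarray(batch_y, dtype=np.float64)[:, None]
    out = model.forward(x)
    m = config.m or out.size
    r = mse_loss(y, out, m)
    _sgd_step(model, (out - y) / m, config.learning_rate)
    return r
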