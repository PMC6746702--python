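"""Training protocols: Adam, cross-entropy (+ Dice-overlap) losses, loops.

Both methods follow the same regime: Adam with its default parameters
(alpha 1e-3, beta1 0.9, beta2 0.999, eps 1e-8), no early stopping, no
learning-rate schedule, no transfer learning; training runs for a fixed
number of epochs and the checkpoint with the best validation selection
metric (patch accuracy / validation Dice) is returned.  Patch classifiers
minimise cross-entropy; semantic networks minimise cross-entropy plus the
Dice-overlap loss, with horizontal-flip augmentation drawn per image per
epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Module

__all__ = ["TrainConfig", "Adam", "dice_overlap_loss", "semantic_loss",
           "train_patch_classifier", "train_semantic_model",
           "dice_percent_from_masks", "write_training_log"]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    flip_probability: float = 0.5  # semantic augmentation only
    seed: int = 0


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _one_hot_mask(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) integer mask -> (N, K, H, W) one-hot float array."""
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[mask].transpose(0, 3, 1, 2)


def dice_overlap_loss(probs, target_mask: np.ndarray, n_classes: int = 4,
                      smooth: float = 1.0, squared: bool = True):
    """Dice-overlap loss: 1 - mean over classes of the soft Dice score.

    ``probs`` holds per-pixel class probabilities, shape (N, K, H, W)
    (a Tensor during training or a plain array for inspection);
    ``target_mask`` is the integer area mask (N, H, W) or (H, W).  The
    soft Dice per class is (2 * sum(p*g) + s) / (sum(p^2) + sum(g^2) + s)
    with smoothing ``s``; ``squared=False`` switches the denominator to
    plain sums.  Classes are equally weighted.
    """
    p = ad.Tensor.as_tensor(probs)
    target_mask = np.asarray(target_mask)
    if target_mask.ndim == 2:
        target_mask = target_mask[None]
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    g = _one_hot_mask(target_mask, n_classes).astype(p.data.dtype)
    axes = (0, 2, 3)
    inter = (p * g).sum(axis=axes)
    if squared:
        denom = (p * p).sum(axis=axes) + Tensor((g * g).sum(axis=axes))
    else:
        denom = p.sum(axis=axes) + Tensor(g.sum(axis=axes))
    score = (2.0 * inter + smooth) / (denom + smooth)
    return 1.0 - score.mean()


def semantic_loss(logits: Tensor, target_mask: np.ndarray,
                  n_classes: int = 4):
    """Sum of per-pixel cross-entropy and Dice-overlap loss."""
    n, k, h, w = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(n * h * w, k)
    ce = ad.cross_entropy(flat, np.asarray(target_mask).reshape(-1))
    probs = ad.log_softmax(logits, axis=1).exp()
    return ce + dice_overlap_loss(probs, target_mask, n_classes)


def dice_percent_from_masks(pred_mask: np.ndarray, true_mask: np.ndarray,
                            n_classes: int = 4) -> float:
    """Mean hard Dice overlap percentage across classes of two label masks."""
    scores = []
    for c in range(n_classes):
        x, y = pred_mask == c, true_mask == c
        total = x.sum() + y.sum()
        scores.append(100.0 if total == 0 else 200.0 * (x & y).sum() / total)
    return float(np.mean(scores))


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_metric: float


def write_training_log(log: list[EpochRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss", "val_metric"])
        for rec in log:
            writer.writerow([rec.epoch, f"{rec.train_loss:.6f}",
                             f"{rec.val_loss:.6f}", f"{rec.val_metric:.6f}"])


def select_best(log: list[EpochRecord]) -> int:
    """Index of the epoch with the highest validation metric (first argmax)."""
    metrics = [rec.val_metric for rec in log]
    return int(np.argmax(metrics))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_patch_classifier(model: Module, x_train: np.ndarray,
                           y_train: np.ndarray, x_val: np.ndarray,
                           y_val: np.ndarray, config: TrainConfig,
                           on_epoch=None,
                           ) -> tuple[Module, list[EpochRecord]]:
    """Train a patch classifier with cross-entropy; select by val accuracy.

    ``x_*`` are (n, H, W) intensity patches in [0, 255]; ``y_*`` integer
    class indices in the fixed order (ILM, RPE, CSI, BG).  Returns the
    model restored to its argmax-validation-accuracy checkpoint plus the
    per-epoch log.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    x_train = (np.asarray(x_train, dtype=np.float32) / 255.0)[:, None]
    x_val = (np.asarray(x_val, dtype=np.float32) / 255.0)[:, None]
    opt = Adam(model.parameters(), config.learning_rate, config.beta1,
               config.beta2, config.eps)
    log: list[EpochRecord] = []
    best_weights = model.get_weights()
    best_metric = -np.inf
    for epoch in range(1, config.max_epochs + 1):
        losses = []
        for idx in _batches(len(x_train), config.batch_size, rng):
            opt.zero_grad()
            logits = model(Tensor(x_train[idx]), rng, training=True)
            loss = ad.cross_entropy(logits, y_train[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss, correct = [], 0
        for start in range(0, len(x_val), 256):
            sl = slice(start, start + 256)
            logits = model(Tensor(x_val[sl]), training=False)
            val_loss.append(float(ad.cross_entropy(logits, y_val[sl]).data)
                            * (logits.shape[0]))
            correct += int((logits.data.argmax(axis=1) == y_val[sl]).sum())
        acc = correct / len(x_val)
        log.append(EpochRecord(epoch, float(np.mean(losses)),
                               float(np.sum(val_loss) / len(x_val)), acc))
        if on_epoch is not None:
            on_epoch(log[-1])
        if acc > best_metric:
            best_metric = acc
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, log


def train_semantic_model(model: Module, train_pairs, val_pairs,
                         config: TrainConfig, on_epoch=None,
                         ) -> tuple[Module, list[EpochRecord]]:
    """Train a semantic network on (image, area-mask) pairs.

    ``train_pairs``/``val_pairs`` are sequences of ``(image, mask)`` with
    images in [0, 255] and integer masks; images are scaled to [0, 1] and
    randomly horizontally flipped (image and mask together) once per image
    per epoch.  Loss: cross-entropy + Dice overlap; selection: highest
    mean validation Dice of the argmax segmentation.
    """
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    imgs = np.stack([np.asarray(p[0], dtype=np.float32) / 255.0
                     for p in train_pairs])
    masks = np.stack([np.asarray(p[1], dtype=np.int64) for p in train_pairs])
    val_imgs = np.stack([np.asarray(p[0], dtype=np.float32) / 255.0
                         for p in val_pairs])
    val_masks = np.stack([np.asarray(p[1], dtype=np.int64) for p in val_pairs])

    opt = Adam(model.parameters(), config.learning_rate, config.beta1,
               config.beta2, config.eps)
    log: list[EpochRecord] = []
    best_weights = model.get_weights()
    best_metric = -np.inf
    for epoch in range(1, config.max_epochs + 1):
        # per-epoch augmentation: flip each image (and mask) with p = 0.5
        flips = rng.random(len(imgs)) < config.flip_probability
        ep_imgs = np.where(flips[:, None, None], imgs[:, :, ::-1], imgs)
        ep_masks = np.where(flips[:, None, None], masks[:, :, ::-1], masks)
        losses = []
        for idx in _batches(len(ep_imgs), config.batch_size, rng):
            opt.zero_grad()
            logits = model(Tensor(ep_imgs[idx][:, None]), rng, training=True)
            loss = semantic_loss(logits, ep_masks[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_losses, val_dice = [], []
        for i in range(0, len(val_imgs), config.batch_size):
            sl = slice(i, i + config.batch_size)
            logits = model(Tensor(val_imgs[sl][:, None]), training=False)
            val_losses.append(float(semantic_loss(logits, val_masks[sl]).data)
                              * logits.shape[0])
            pred = logits.data.argmax(axis=1)
            val_dice.extend(dice_percent_from_masks(p, t)
                            for p, t in zip(pred, val_masks[sl]))
        metric = float(np.mean(val_dice))
        log.append(EpochRecord(epoch, float(np.mean(losses)),
                               float(np.sum(val_losses) / len(val_imgs)),
                               metric))
        if on_epoch is not None:
            on_epoch(log[-1])
        if metric > best_metric:
            best_metric = metric
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, log
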