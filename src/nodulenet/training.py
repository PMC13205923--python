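"""Training protocol: weighted BCE, freeze policy, AdamW + cosine schedule.

The protocol mirrors a two-phase transfer setup: backbone weights are
frozen and only the inserted transformer blocks and the classification
head are trainable. The loss is a class-weighted binary cross-entropy
on the positive-class probability,

    L = -(1/N) sum_i [ w1 y_i log p_i + w0 (1 - y_i) log(1 - p_i) ],

with weights w_c = N / (2 n_c) computed from the (possibly upsampled)
training counts. Checkpoints are written whenever the validation loss
improves; the validation F1 at that checkpoint is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .nn import core
from .models import MSTResNet, ResNet50, save_checkpoint

PROB_EPS = 1e-7  # clamp applied inside the log terms


@dataclass(frozen=True)
class ClassWeights:
    w0: float  # non-nodule weight
    w1: float  # nodule weight


@dataclass
class TrainingConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    seeds: tuple[int, ...] = (42, 444, 916)
    freeze_backbone: bool = True
    threshold: float = 0.5
    checkpoint_dir: str | None = None

    def __post_init__(self):
        validate_threshold(self.threshold)
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class RunRecord:
    seed: int
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf
    val_f1_at_best: float | None = None
    checkpoint_path: str | None = None


def validate_threshold(threshold: float):
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"decision threshold must lie strictly in (0, 1), got {threshold}")


# ---------------------------------------------------------------------
# loss and class weights


def compute_class_weights(n0: int, n1: int) -> ClassWeights:
    """Inverse-frequency weights w_c = N / (2 n_c) for two classes."""
    if n0 < 1 or n1 < 1:
        raise ValueError("both classes need at least one training image")
    n = n0 + n1
    return ClassWeights(w0=n / (2.0 * n0), w1=n / (2.0 * n1))


def wbce_loss(probabilities: Sequence[float], labels: Sequence[int], weights: ClassWeights) -> float:
    """Weighted binary cross-entropy on plain arrays (nodule = class 1)."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.size == 0:
        raise ValueError("empty batch")
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    terms = weights.w1 * y * np.log(p) + weights.w0 * (1 - y) * np.log(1.0 - p)
    return float(-terms.mean())


def wbce_loss_from_logits(logits: core.Tensor, labels: np.ndarray, weights: ClassWeights) -> core.Tensor:
    """Graph-connected WBCE from 2-class logits (softmax positive prob)."""
    y = np.asarray(labels, np.float32)
    probs = core.softmax(logits, axis=1)
    p1 = probs[:, 1].clip(PROB_EPS, 1.0 - PROB_EPS)
    pos = p1.log() * (weights.w1 * y)
    neg = (1.0 - p1).clip(PROB_EPS, 1.0).log() * (weights.w0 * (1.0 - y))
    return (pos + neg).mean() * -1.0


# ---------------------------------------------------------------------
# freeze policy / prediction


def apply_freeze_policy(model: nn.Module) -> nn.Module:
    """Freeze backbone stages and stem; keep MST blocks and head trainable.

    Only *parameters* are frozen; batch-norm running statistics are
    buffers and keep adapting in training mode, standing in for the
    stats a previously fine-tuned backbone would carry.
    """
    for name, p in model.named_parameters():
        trainable = name.startswith("mst.") or name.startswith(("fc.", "backbone.fc."))
        p.requires_grad = trainable
    return model


def _forward_logits(model: nn.Module, x) -> tuple[core.Tensor, np.ndarray]:
    out = model(x)
    if isinstance(out, core.Tensor):  # plain baseline
        with core.no_grad():
            probs = core.softmax(core.Tensor(out.data), axis=1).data
        return out, probs[:, 1]
    return out.logits, out.nodule_probability


def predict(
    model: nn.Module,
    images: np.ndarray,
    threshold: float = 0.5,
    batch_size: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded prediction; ties at the threshold classify positive
    (screening favours sensitivity). Returns (labels, probabilities)."""
    validate_threshold(threshold)
    was_training = model.training
    model.eval()
    probs = []
    with core.no_grad():
        for i in range(0, len(images), batch_size):
            _, p1 = _forward_logits(model, np.asarray(images[i : i + batch_size], np.float32))
            probs.append(p1)
    if was_training:
        model.train()
    p = np.concatenate(probs)
    return (p >= threshold).astype(int), p


# ---------------------------------------------------------------------
# training loop


def _epoch_eval_loss(model, dataset, weights, batch_size):
    xs_idx = np.arange(len(dataset))
    losses, ns = [], []
    with core.no_grad():
        for i in range(0, len(xs_idx), batch_size):
            batch = [dataset[j] for j in xs_idx[i : i + batch_size]]
            x = np.stack([b[0] for b in batch])
            y = np.array([b[1] for b in batch])
            _, p1 = _forward_logits(model, x)
            losses.append(wbce_loss(p1, y, weights) * len(batch))
            ns.append(len(batch))
    return float(np.sum(losses) / np.sum(ns))


def _val_f1(model, dataset, threshold, batch_size):
    x = np.stack([dataset[i][0] for i in range(len(dataset))])
    y = np.array([dataset[i][1] for i in range(len(dataset))])
    pred, _ = predict(model, x, threshold, batch_size)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def train(
    model: nn.Module,
    train_dataset,
    val_dataset,
    cfg: TrainingConfig,
    seed: int,
    log: Callable[[str], None] | None = None,
) -> RunRecord:
    """Run the full optimization loop, deterministically for a given seed.

    Datasets are index-able ``(image, label)`` pairs; class weights are
    recomputed from the (upsampled) training labels. Checkpoints are
    saved to ``cfg.checkpoint_dir`` on validation-loss improvement.
    """
    labels = np.array([train_dataset.label(i) if hasattr(train_dataset, "label") else train_dataset[i][1] for i in range(len(train_dataset))])
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    if len(labels) == 0 or len(val_dataset) == 0:
        raise ValueError("empty training or validation split")
    if n0 == 0 or n1 == 0:
        raise ValueError("training split must contain both classes")
    weights = compute_class_weights(n0, n1)

    if cfg.freeze_backbone and isinstance(model, MSTResNet):
        apply_freeze_policy(model)
    nn.reseed_dropout(model, seed)
    if hasattr(train_dataset, "reseed"):
        train_dataset.reseed(seed)
    shuffle_rng = np.random.default_rng([seed, 7919])

    opt = nn.AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    record = RunRecord(seed=seed)
    emit = log or (lambda s: None)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.epochs):
        lr = nn.cosine_annealing_lr(cfg.learning_rate, epoch, cfg.epochs)
        opt.lr = lr
        model.train()
        order = shuffle_rng.permutation(len(train_dataset))
        running, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            batch = [train_dataset[j] for j in idx]
            x = np.stack([b[0] for b in batch])
            y = np.array([b[1] for b in batch])
            logits, _ = _forward_logits(model, x)
            loss = wbce_loss_from_logits(logits, y, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            running += loss.item() * len(idx)
            seen += len(idx)
        train_loss = running / seen
        model.eval()
        val_loss = _epoch_eval_loss(model, val_dataset, weights, cfg.batch_size)
        record.train_losses.append(train_loss)
        record.val_losses.append(val_loss)
        record.learning_rates.append(float(lr))
        improved = val_loss < record.best_val_loss
        if improved:
            record.best_val_loss = val_loss
            record.best_epoch = epoch
            record.val_f1_at_best = _val_f1(model, val_dataset, cfg.threshold, cfg.batch_size)
            if ckpt_dir:
                path = ckpt_dir / f"best_seed{seed}.npz"
                save_checkpoint(model, path)
                record.checkpoint_path = str(path)
        emit(
            f"epoch {epoch + 1:3d}/{cfg.epochs}  lr {lr:.3e}  "
            f"train_loss {train_loss:.4f}  val_loss {val_loss:.4f}"
            + ("  *checkpoint*" if improved else "")
        )
    return record
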