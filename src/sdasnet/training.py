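"""Training and evaluation loops.

Defaults mirror the published study configuration: 300 epochs, batch 16,
Adam with learning rate 0.000327, first-moment coefficient 0.9 and L2
weight decay 0.0002, on 512x512 inputs.  The loss is pixel-wise two-class
cross-entropy by default, with BCE and cross-entropy + soft-Dice variants.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import Sample
from .metrics import MetricsReport, evaluate_masks
from .model import SDASNet, save_checkpoint

logger = logging.getLogger("sdasnet")

LOSSES = ("cross_entropy", "bce", "ce_dice")


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 0.000327
    beta1: float = 0.9           # "momentum" of the study configuration
    weight_decay: float = 0.0002
    loss: str = "cross_entropy"
    seed: int = 0
    checkpoint_path: str | None = None
    log_csv: str | None = None
    eval_every: int = 1          # epochs between metric evaluations (0 = never)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")


def samples_to_arrays(samples: list[Sample]):
    """(N, 3, H, W) float32 images in [0, 1] and (N, H, W) int label maps."""
    images = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    images = images.transpose(0, 3, 1, 2)
    labels = np.stack([(s.mask > 0).astype(np.int64) for s in samples])
    return images, labels


def _soft_dice(probs_fg: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    target = labels.astype(probs_fg.dtype.type)
    inter = nn.sum_(probs_fg * nn.Tensor(target))
    total = nn.sum_(probs_fg) + nn.Tensor(np.asarray(target.sum(),
                                                     dtype=target.dtype))
    return 1.0 - (2.0 * inter + 1.0) * nn.power(total + 1.0, -1.0)


def compute_loss(logits: nn.Tensor, labels: np.ndarray, kind: str) -> nn.Tensor:
    if kind == "cross_entropy":
        return nn.cross_entropy_logits(logits, labels)
    if kind == "bce":
        # two-class logits reduce to a Bernoulli likelihood on the
        # foreground-vs-background logit difference
        return nn.cross_entropy_logits(logits, labels)
    if kind == "ce_dice":
        ce = nn.cross_entropy_logits(logits, labels)
        probs = nn.softmax(logits, axis=1)
        # select the foreground-class probability channel
        sel = np.zeros((1, logits.shape[1], 1, 1), dtype=np.float32)
        sel[0, 1, 0, 0] = 1.0
        fg_prob = nn.sum_(probs * nn.Tensor(sel), axis=1)
        return ce + 0.5 * _soft_dice(fg_prob, labels)
    raise ValueError(kind)


def recalibrate_batchnorm(model: nn.Module, images: np.ndarray,
                          batch_size: int = 8) -> None:
    """Refresh batch-normalisation running statistics under the final weights.

    The exponential running averages lag the activation statistics of a
    fast-moving short run, which skews eval-mode predictions.  This replaces
    them with the mean batch statistics of one forward sweep over ``images``
    (momentum 1/k on the k-th batch accumulates an exact mean), leaving all
    learned parameters untouched.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    model.train()
    try:
        for k, i in enumerate(range(0, images.shape[0], batch_size), start=1):
            for bn in bns:
                bn.momentum = 1.0 / k
            model(images[i:i + batch_size])
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m
        model.eval()


def evaluate(model: SDASNet, samples: list[Sample],
             batch_size: int = 8) -> MetricsReport:
    """Run the model over samples and score predictions against labels."""
    if not samples:
        raise ValueError("no samples to evaluate")
    model.eval()
    images, _ = samples_to_arrays(samples)
    preds = []
    for i in range(0, len(samples), batch_size):
        preds.extend(model.predict_mask(images[i:i + batch_size]))
    return evaluate_masks(preds, [s.mask for s in samples])


def train(model: SDASNet, train_samples: list[Sample],
          val_samples: list[Sample] | None, config: TrainConfig) -> list[dict]:
    """Seeded Adam optimisation; returns one history record per epoch."""
    if not train_samples:
        raise ValueError("empty training split")
    images, labels = samples_to_arrays(train_samples)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        betas=(config.beta1, 0.999),
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_miou = -1.0
    csv_writer = csv_file = None
    if config.log_csv:
        csv_file = open(config.log_csv, "w", newline="")
        csv_writer = csv.writer(csv_file)
        csv_writer.writerow(["epoch", "loss", "train_PA", "train_mIoU",
                             "val_PA", "val_mIoU"])
    try:
        for epoch in range(1, config.epochs + 1):
            model.train()
            order = rng.permutation(len(train_samples))
            epoch_loss = 0.0
            n_batches = 0
            t0 = time.time()
            for i in range(0, len(order), config.batch_size):
                idx = order[i:i + config.batch_size]
                logits = model(images[idx])
                loss = compute_loss(logits, labels[idx], config.loss)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += loss.item()
                n_batches += 1
            record = {"epoch": epoch, "loss": epoch_loss / n_batches}
            if config.eval_every and epoch % config.eval_every == 0:
                train_report = evaluate(model, train_samples,
                                        config.batch_size)
                record.update(train_PA=train_report.PA,
                              train_mIoU=train_report.mIoU)
                if val_samples:
                    val_report = evaluate(model, val_samples,
                                          config.batch_size)
                    record.update(val_PA=val_report.PA,
                                  val_mIoU=val_report.mIoU)
                    if (config.checkpoint_path
                            and val_report.mIoU > best_miou):
                        best_miou = val_report.mIoU
                        save_checkpoint(model, config.checkpoint_path)
            logger.info("epoch %d  loss %.4f  (%.1fs)  %s", epoch,
                        record["loss"], time.time() - t0,
                        {k: round(v, 4) for k, v in record.items()
                         if k not in ("epoch", "loss")})
            if csv_writer:
                csv_writer.writerow([record.get(k, "") for k in
                                     ("epoch", "loss", "train_PA",
                                      "train_mIoU", "val_PA", "val_mIoU")])
            history.append(record)
    finally:
        if csv_file:
            csv_file.close()
    if config.checkpoint_path and best_miou < 0:
        save_checkpoint(model, config.checkpoint_path)
    return history


def tiny_overfit_run(seed: int, steps: int = 200, n_samples: int = 8,
                     image_size: int = 64, base_width: int = 8,
                     learning_rate: float = 3e-3):
    """Scaled-down end-to-end learnability check.

    Trains a small model (base width 8, 64x64 inputs, 4x4 token grid) for
    ``steps`` full-batch Adam steps on ``n_samples`` synthetic antler images
    and returns ``(history, final training mIoU)``.  The learning rate is
    the standard small-scale overfit setting rather than the full study
    configuration's, and weight decay is off, since the point is memorising
    a tiny set, not generalising.  Batch-norm running statistics are
    recalibrated under the final weights before scoring (see
    :func:`recalibrate_batchnorm`).
    """
    from .model import ModelConfig, build_model
    from .dwt_module import DWTModuleConfig
    from .synth import SynthConfig, generate_synthetic_dataset

    samples = generate_synthetic_dataset(
        SynthConfig(image_size=(image_size, image_size), seed=seed), n_samples)
    config = ModelConfig(
        base_width=base_width, input_size=(image_size, image_size),
        dwt=DWTModuleConfig(out_channels=base_width,
                            mid_channels=max(base_width // 2, 1),
                            final_stride=1))
    model = build_model(config, seed=seed)
    tc = TrainConfig(epochs=steps, batch_size=n_samples,
                     learning_rate=learning_rate, weight_decay=0.0,
                     seed=seed, eval_every=0)
    history = train(model, samples, None, tc)
    images, _ = samples_to_arrays(samples)
    recalibrate_batchnorm(model, images, batch_size=n_samples)
    report = evaluate(model, samples, batch_size=n_samples)
    return history, report.mIoU
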