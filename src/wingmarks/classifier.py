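"""Tier 1: binary complete/incomplete wing classification.

A wing is "incomplete" (label 1) when it is missing landmark 4 or 6 or
absent altogether; complete wings (label 0) may still carry benign tears
or stains. The classifier ends in a single fully connected unit with a
sigmoid, trained with binary cross-entropy and Adam, keeping the weights
from the epoch with the lowest validation loss. Test-set metrics carry
95% bootstrap confidence intervals (percentile method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, apply_augmentation, sample_augmentation
from .io import WingImage
from .models_common import image_to_tensor
from .nn import (Adam, Conv2d, GlobalMaxPool, Linear, MaxPool2d, ReLU,
                 Sequential, bce_with_logits, sigmoid)

__all__ = ["ClassifierConfig", "ClassificationMetrics", "BackboneUnavailableError",
           "build_classifier", "train_classifier", "predict_scores",
           "bootstrap_metrics", "binary_metrics"]

_HEAVY_BACKBONES = ("vgg16_bn", "resnet18", "inception_v3")


class BackboneUnavailableError(RuntimeError):
    """Named ImageNet backbone requested without a deep-learning runtime."""


@dataclass
class ClassifierConfig:
    """Training protocol: Adam, lr 1e-4, 30 epochs, batch 50, BCE loss.

    ``tiny_test_net`` is the CPU-runnable backbone; the named ImageNet
    backbones are interface placeholders (input 224, or 299 for
    inception_v3) that raise :class:`BackboneUnavailableError`.
    """

    backbone: str = "tiny_test_net"
    input_size: int = 64
    lr: float = 1e-4
    epochs: int = 30
    batch_size: int = 50
    pretrained: bool = False
    threshold: float = 0.5
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        if self.backbone == "inception_v3" and self.input_size not in (299,):
            self.input_size = 299
        if self.backbone in ("vgg16_bn", "resnet18") and self.input_size != 224:
            self.input_size = 224
        if self.input_size % 8 != 0 and self.backbone == "tiny_test_net":
            raise ValueError("tiny_test_net input_size must be divisible by 8")


def build_classifier(config: ClassifierConfig, rng: np.random.Generator
                     ) -> Sequential:
    """Model mapping a 3-channel square input to one sigmoid-activated score.

    The head is a single fully connected unit ((feature_dim + 1)
    parameters) on top of the convolutional feature extractor.
    """
    if config.backbone in _HEAVY_BACKBONES:
        raise BackboneUnavailableError(
            f"backbone {config.backbone!r} needs a pretrained deep-learning "
            "runtime; use 'tiny_test_net' for CPU training")
    if config.backbone != "tiny_test_net":
        raise ValueError(f"unknown backbone {config.backbone!r}")
    # global max pooling makes the damage cue position-invariant
    return Sequential(
        Conv2d(3, 8, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(8, 16, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(16, 32, rng=rng), ReLU(), MaxPool2d(),
        GlobalMaxPool(), Linear(32, 1, rng=rng),
    )


def _tensors(items: list[tuple[WingImage, int]], size: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([image_to_tensor(img, size) for img, _ in items])
    y = np.array([lab for _, lab in items], dtype=float)[:, None]
    return x, y


def train_classifier(model: Sequential,
                     train: list[tuple[WingImage, int]],
                     val: list[tuple[WingImage, int]],
                     config: ClassifierConfig,
                     rng: np.random.Generator) -> dict:
    """Fit with BCE + Adam; return history and restore the best checkpoint.

    Image augmentation (the shared affine scheme) is applied on-the-fly to
    every training image each epoch. The returned model carries the
    weights of the epoch with the minimum validation loss.
    """
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    labels = {lab for _, lab in train}
    if labels - {0, 1}:
        raise ValueError("labels must be 0 (complete) or 1 (incomplete)")
    if len(labels) < 2:
        raise ValueError("training set contains a single class")

    xval, yval = _tensors(val, config.input_size)
    plain_x, ytr = _tensors(train, config.input_size)

    opt = Adam(model, lr=config.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss, best_state = math.inf, model.clone_state()

    for _ in range(config.epochs):
        if config.augment.enabled:
            xtr = np.stack([
                image_to_tensor(apply_augmentation(img, None,
                                sample_augmentation(rng, config.augment))[0],
                                config.input_size)
                for img, _ in train])
        else:
            xtr = plain_x
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            logits = model.forward(xtr[idx])
            loss, grad = bce_with_logits(logits, ytr[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / len(order))

        vloss, _ = bce_with_logits(model.forward(xval), yval)
        history["val_loss"].append(vloss)
        if vloss < best_loss:
            best_loss, best_state = vloss, model.clone_state()

    model.load_state_dict(best_state)
    return {"history": history, "best_val_loss": best_loss}


def predict_scores(model: Sequential, images: list[WingImage],
                   input_size: int) -> np.ndarray:
    x = np.stack([image_to_tensor(img, input_size) for img in images])
    return sigmoid(model.forward(x))[:, 0]


def binary_metrics(pred_labels: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Sensitivity, specificity, precision, F1 and accuracy; NaN when undefined."""
    p = np.asarray(pred_labels).astype(int)
    y = np.asarray(labels).astype(int)
    tp = int(np.sum((p == 1) & (y == 1)))
    tn = int(np.sum((p == 0) & (y == 0)))
    fp = int(np.sum((p == 1) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2 * prec * sens / (prec + sens)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "accuracy": acc}


@dataclass
class ClassificationMetrics:
    """Point estimates with 95% percentile-bootstrap CI bounds, all in [0, 1]."""

    point: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    n_boot: int
    resample_size: int


def bootstrap_metrics(predictions: np.ndarray, labels: np.ndarray,
                      n_boot: int = 5000, resample_size: int = 205,
                      rng: np.random.Generator | None = None,
                      threshold: float = 0.5) -> ClassificationMetrics:
    """Percentile 95% CIs by resampling the test predictions with replacement.

    ``predictions`` may be sigmoid scores (thresholded at 0.5) or hard
    labels. Resamples where a metric is undefined (e.g. precision with no
    predicted positives) are excluded from that metric's percentiles.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    scores = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(scores) != len(y) or len(y) < 1:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    p = (scores >= threshold).astype(int)

    point = binary_metrics(p, y)
    names = list(point)
    draws = {m: np.empty(n_boot) for m in names}
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=resample_size)
        mb = binary_metrics(p[idx], y[idx])
        for m in names:
            draws[m][b] = mb[m]

    lower, upper = {}, {}
    for m in names:
        vals = draws[m][~np.isnan(draws[m])]
        if len(vals) == 0:
            lower[m] = upper[m] = math.nan
        else:
            lower[m] = float(np.percentile(vals, 2.5))
            upper[m] = float(np.percentile(vals, 97.5))
    return ClassificationMetrics(point, lower, upper, n_boot, resample_size)
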