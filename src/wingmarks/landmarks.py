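"""Tier 2: landmark localisation by coordinate regression and by segmentation.

Two heads solve the same task. The regression head maps an image to 22
numbers — normalised (x, y) for each of the 11 landmarks — trained with
MSE over two Adam sessions (lr 1e-3 then 1e-4), keeping minimum-
validation-loss weights per session. The segmentation head emits one
activation map per landmark, trained against binary disk targets (radius
R, default 5 px in model space) with the average of binary cross-entropy
and dice loss; a map is turned back into a coordinate by averaging the
locations of all pixels at or above the 7th-highest pixel value, a rule
that always yields a point — even for an absent landmark.

A constant mean-location baseline anchors every comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, apply_augmentation, sample_augmentation
from .io import N_LANDMARKS, LandmarkSet, WingImage
from .models_common import image_to_tensor, model_to_native, native_to_model
from .nn import (Adam, Conv2d, Flatten, Linear, MaxPool2d, ReLU, Sequential,
                 Upsample2x, sigmoid)

__all__ = [
    "RegressionConfig", "SegmentationConfig", "SegmentationTarget",
    "build_regression_net", "build_segmentation_net", "make_disk_targets",
    "infer_landmark_from_map", "combined_loss", "train_regression",
    "train_segmentation", "predict_regression", "predict_segmentation",
    "baseline_mean_location", "MeanLocationBaseline",
]


@dataclass
class RegressionConfig:
    """Coordinate-regression head and schedule.

    The published schedule is two sessions of 100 epochs; desk-scale runs
    shrink ``session_epochs`` while keeping the two-session lr drop.
    """

    backbone: str = "tiny_test_net"
    input_size: int = 64
    session_epochs: tuple[int, int] = (100, 100)
    session_lrs: tuple[float, float] = (1e-3, 1e-4)
    batch_size: int = 16
    pretrained: bool = False
    augment: AugmentationConfig | None = None


@dataclass
class SegmentationConfig:
    """Encoder–decoder head: 11 output channels, (BCE + dice)/2 loss."""

    input_size: int = 64
    disk_radius: int = 5
    epochs: int = 50
    lr: float = 1e-3
    batch_size: int = 16
    dice_eps: float = 1.0
    augment: AugmentationConfig | None = None


@dataclass
class SegmentationTarget:
    """11 binary disk maps at model resolution."""

    maps: np.ndarray  # (11, S, S) float 0/1
    disk_radius: int


def build_regression_net(config: RegressionConfig, rng: np.random.Generator
                         ) -> Sequential:
    """Feature extractor + one fresh conv layer + a 22-unit output layer."""
    s = config.input_size
    if s % 8 != 0:
        raise ValueError("input_size must be divisible by 8")
    feat = 16 * (s // 8) * (s // 8)
    return Sequential(
        Conv2d(3, 8, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(8, 16, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(16, 16, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(16, 16, rng=rng), ReLU(),    # the randomly initialised conv head
        Flatten(), Linear(feat, 2 * N_LANDMARKS, rng=rng),
    )


def build_segmentation_net(config: SegmentationConfig, rng: np.random.Generator
                           ) -> Sequential:
    """Symmetric downsample/upsample stack emitting 11 logit maps."""
    if config.input_size % 4 != 0:
        raise ValueError("input_size must be divisible by 4")
    return Sequential(
        Conv2d(3, 8, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(8, 16, rng=rng), ReLU(), MaxPool2d(),
        Conv2d(16, 16, rng=rng), ReLU(),
        Upsample2x(), Conv2d(16, 8, rng=rng), ReLU(),
        Upsample2x(), Conv2d(8, N_LANDMARKS, rng=rng),
    )


# ---------------------------------------------------------------------------
# targets and the map -> coordinate inference rule


def make_disk_targets(landmarks: LandmarkSet, native_size: tuple[int, int],
                      model_size: int, radius: int = 5) -> SegmentationTarget:
    """Binary maps with a filled disk of radius R at each rescaled landmark.

    A pixel of channel k is 1 exactly when its distance to landmark k (in
    model space) is at most R; disks at image borders are clipped and
    disks of different channels may overlap.
    """
    if radius < 1:
        raise ValueError("disk radius must be >= 1")
    pts = native_to_model(landmarks.points, native_size, model_size)
    yy, xx = np.mgrid[0:model_size, 0:model_size]
    maps = np.zeros((N_LANDMARKS, model_size, model_size))
    for k in range(N_LANDMARKS):
        x, y = pts[k]
        maps[k] = ((xx - x) ** 2 + (yy - y) ** 2 <= radius ** 2).astype(float)
    return SegmentationTarget(maps, radius)


def infer_landmark_from_map(activation: np.ndarray) -> tuple[float, float]:
    """Centroid of all pixels at or above the 7th-highest pixel value.

    The threshold is the 7th value of the pixel multiset sorted descending
    (duplicates counted), so a binary disk of >= 7 pixels selects the whole
    disk and a constant map degenerates to the full-grid centroid
    ((W-1)/2, (H-1)/2).
    """
    a = np.asarray(activation, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("activation map must be finite")
    flat = a.ravel()
    k = min(7, flat.size)
    v7 = np.partition(flat, flat.size - k)[flat.size - k]
    ys, xs = np.nonzero(a >= v7)
    return float(xs.mean()), float(ys.mean())


def combined_loss(pred_maps: np.ndarray, target_maps: np.ndarray,
                  eps: float = 1.0) -> float:
    """(BCE + dice)/2 on probability maps, dice averaged over channels."""
    p = np.asarray(pred_maps, dtype=float)
    t = np.asarray(target_maps, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    bce = float(np.mean(-(t * np.log(pc) + (1 - t) * np.log(1 - pc))))
    chans = p.reshape(-1, p.shape[-2], p.shape[-1])
    tch = t.reshape(-1, t.shape[-2], t.shape[-1])
    inter = (chans * tch).sum(axis=(1, 2))
    sums = chans.sum(axis=(1, 2)) + tch.sum(axis=(1, 2))
    dice = float(np.mean(1.0 - (2.0 * inter + eps) / (sums + eps)))
    return (bce + dice) / 2.0


def _combined_loss_grad(logits: np.ndarray, targets: np.ndarray,
                        eps: float) -> tuple[float, np.ndarray]:
    """Training form of the combined loss on logits, with gradient."""
    p = sigmoid(logits)
    n_el = logits.size
    bce = float(np.mean(np.log1p(np.exp(-np.abs(logits)))
                        + np.maximum(logits, 0.0) - logits * targets))
    g_bce = (p - targets) / n_el

    nb, nc = logits.shape[0], logits.shape[1]
    inter = (p * targets).sum(axis=(2, 3))
    sums = p.sum(axis=(2, 3)) + targets.sum(axis=(2, 3))
    dice = float(np.mean(1.0 - (2.0 * inter + eps) / (sums + eps)))
    denom = (sums + eps)[:, :, None, None]
    g_dice_p = -(2.0 * targets * denom - (2.0 * inter + eps)[:, :, None, None]) \
        / (denom ** 2)
    g_dice = g_dice_p * p * (1.0 - p) / (nb * nc)
    return (bce + dice) / 2.0, (g_bce + g_dice) / 2.0


# ---------------------------------------------------------------------------
# training


def _augmented_pair(image: WingImage, landmarks: LandmarkSet,
                    config: AugmentationConfig, rng: np.random.Generator
                    ) -> tuple[WingImage, LandmarkSet] | None:
    """Sample one augmentation; resample once if landmarks leave the frame."""
    for _ in range(2):
        aug = sample_augmentation(rng, config)
        img, lms, in_frame = apply_augmentation(image, landmarks, aug)
        if np.all(in_frame[lms.valid]):
            return img, lms
    return None


def _regression_batch(pairs: list[tuple[WingImage, LandmarkSet]],
                      size: int,
                      augment: AugmentationConfig | None,
                      rng: np.random.Generator | None
                      ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for image, landmarks in pairs:
        if augment is not None and augment.enabled and rng is not None:
            got = _augmented_pair(image, landmarks, augment, rng)
            if got is None:
                continue
            image, landmarks = got
        xs.append(image_to_tensor(image, size))
        pts = native_to_model(landmarks.points, image.shape, size) / size
        ys.append(pts.ravel())
    return np.stack(xs), np.stack(ys)


def _fit(model: Sequential, loss_fn, xtr, ytr, xval, yval, epochs: int,
         lr: float, batch_size: int, rng: np.random.Generator,
         refresh=None) -> dict:
    """Generic minibatch loop keeping minimum-validation-loss weights."""
    opt = Adam(model, lr=lr)
    history = {"train_loss": [], "val_loss": []}
    best, best_state = math.inf, model.clone_state()
    for _ in range(epochs):
        if refresh is not None:
            xtr, ytr = refresh()
        order = rng.permutation(len(xtr))
        total = 0.0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            model.zero_grad()
            out = model.forward(xtr[idx])
            loss, grad = loss_fn(out, ytr[idx])
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
        history["train_loss"].append(total / len(order))
        vloss, _ = loss_fn(model.forward(xval), yval)
        history["val_loss"].append(vloss)
        if vloss < best:
            best, best_state = vloss, model.clone_state()
    model.load_state_dict(best_state)
    return {"history": history, "best_val_loss": best}


def train_regression(model: Sequential,
                     train: list[tuple[WingImage, LandmarkSet]],
                     val: list[tuple[WingImage, LandmarkSet]],
                     config: RegressionConfig,
                     rng: np.random.Generator) -> dict:
    """Two Adam sessions of MSE training on normalised coordinates."""
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    size = config.input_size
    xval, yval = _regression_batch(val, size, None, None)

    def mse(pred, target):
        diff = pred - target
        return float(np.mean(diff * diff)), 2.0 * diff / diff.size

    plain = _regression_batch(train, size, None, None)
    aug_on = config.augment is not None and config.augment.enabled
    refresh = (lambda: _regression_batch(train, size, config.augment, rng)) \
        if aug_on else None

    sessions = []
    for epochs, lr in zip(config.session_epochs, config.session_lrs, strict=True):
        sessions.append(_fit(model, mse, *plain, xval, yval, epochs, lr,
                             config.batch_size, rng, refresh=refresh))
    return {"sessions": sessions,
            "best_val_loss": min(s["best_val_loss"] for s in sessions)}


def train_segmentation(model: Sequential,
                       train: list[tuple[WingImage, LandmarkSet]],
                       val: list[tuple[WingImage, LandmarkSet]],
                       config: SegmentationConfig,
                       rng: np.random.Generator) -> dict:
    """Single Adam session against disk targets with the combined loss."""
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    size = config.input_size

    def batch(pairs, augment, brng):
        xs, ys = [], []
        for image, landmarks in pairs:
            if augment is not None and augment.enabled and brng is not None:
                got = _augmented_pair(image, landmarks, augment, brng)
                if got is None:
                    continue
                image, landmarks = got
            xs.append(image_to_tensor(image, size))
            ys.append(make_disk_targets(landmarks, image.shape, size,
                                        config.disk_radius).maps)
        return np.stack(xs), np.stack(ys)

    xval, yval = batch(val, None, None)
    plain = batch(train, None, None)
    aug_on = config.augment is not None and config.augment.enabled
    refresh = (lambda: batch(train, config.augment, rng)) if aug_on else None

    def loss_fn(logits, targets):
        return _combined_loss_grad(logits, targets, config.dice_eps)

    return _fit(model, loss_fn, *plain, xval, yval, config.epochs, config.lr,
                config.batch_size, rng, refresh=refresh)


# ---------------------------------------------------------------------------
# prediction


def predict_regression(model: Sequential, image: WingImage,
                       input_size: int) -> LandmarkSet:
    """Forward pass; 22 outputs rescaled back to native pixel coordinates."""
    x = image_to_tensor(image, input_size)[None]
    out = model.forward(x)[0].reshape(N_LANDMARKS, 2) * input_size
    return LandmarkSet(model_to_native(out, image.shape, input_size))


def predict_segmentation(model: Sequential, image: WingImage,
                         input_size: int) -> LandmarkSet:
    """Per-channel 7th-highest-value inference, rescaled to native space."""
    x = image_to_tensor(image, input_size)[None]
    maps = sigmoid(model.forward(x))[0]
    pts = np.array([infer_landmark_from_map(maps[k]) for k in range(N_LANDMARKS)])
    return LandmarkSet(model_to_native(pts, image.shape, input_size))


@dataclass
class MeanLocationBaseline:
    """Constant predictor: the per-landmark mean of the training coordinates."""

    mean_points: np.ndarray

    def predict(self, image: WingImage | None = None) -> LandmarkSet:
        return LandmarkSet(self.mean_points.copy())


def baseline_mean_location(train_landmarks: list[LandmarkSet]
                           ) -> MeanLocationBaseline:
    if not train_landmarks:
        raise ValueError("need at least one training example")
    stack = np.stack([lms.points for lms in train_landmarks])
    return MeanLocationBaseline(stack.mean(axis=0))
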