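"""Shared ingestion and coordinate plumbing for the tiny network heads.

Every model consumes a 3-channel square tensor (grayscale inputs are
replicated across channels) and all coordinate contracts are defined in
native image space; model-space coordinates are derived views related by
the per-axis factors (W_native / W_model, H_native / H_model).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .io import WingImage
from .nn import Sequential

__all__ = ["image_to_tensor", "native_to_model", "model_to_native",
           "save_checkpoint", "load_checkpoint_arrays"]


def image_to_tensor(image: WingImage | np.ndarray, size: int) -> np.ndarray:
    """Resize to (size, size) and replicate channels; returns (3, size, size)."""
    px = image.pixels if isinstance(image, WingImage) else np.asarray(image, float)
    if px.ndim == 3:
        px = px.mean(axis=2)
    small = resize(px, (size, size), order=1, anti_aliasing=False,
                   preserve_range=True)
    # centre intensities for conditioning; [0, 1] inputs become [-0.5, 0.5]
    return np.repeat(small[None, :, :] - 0.5, 3, axis=0)


def native_to_model(points: np.ndarray, native_shape: tuple[int, int],
                    model_size: int) -> np.ndarray:
    """Map (x, y) native pixels to model space by per-axis ratios."""
    h, w = native_shape
    return np.asarray(points, float) * np.array([model_size / w, model_size / h])


def model_to_native(points: np.ndarray, native_shape: tuple[int, int],
                    model_size: int) -> np.ndarray:
    h, w = native_shape
    return np.asarray(points, float) * np.array([w / model_size, h / model_size])


def save_checkpoint(model: Sequential, config: dict, metrics: dict,
                    path: str | Path) -> None:
    """Single weights file plus a JSON sidecar of config and metrics."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": config, "metrics": metrics}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))


def load_checkpoint_arrays(path: str | Path) -> list[np.ndarray]:
    with np.load(Path(path).with_suffix(".npz")) as data:
        return [data[f"p{i}"] for i in range(len(data.files))]
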