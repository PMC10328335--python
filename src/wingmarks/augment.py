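"""Joint random affine augmentation of images and landmark coordinates.

Training draws scaling and per-axis shifts uniformly from [-5%, +5%] and
rotations from [-22 deg, +22 deg], applying the same similarity map to the
pixel grid and to every landmark. The composition order is a declared
convention: rotation about the image centre, then scaling about the
centre, then translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .io import LandmarkSet, WingImage

__all__ = ["AugmentationConfig", "AffineAugmentation", "sample_augmentation",
           "apply_augmentation"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Sampling intervals; the defaults are the trained-model settings."""

    scale_pct: float = 5.0
    shift_pct: float = 5.0
    rotation_deg: float = 22.0
    enabled: bool = True


@dataclass(frozen=True)
class AffineAugmentation:
    """One sampled transform: scale factor, shift (fraction of W and H), rotation."""

    scale: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous matrix in (x, y) coordinates for an (H, W) image."""
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        theta = np.deg2rad(self.rotation)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        uncentre = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
        scale = np.diag([self.scale, self.scale, 1.0])
        shift = np.array([[1, 0, self.shift[0] * w],
                          [0, 1, self.shift[1] * h],
                          [0, 0, 1]], dtype=float)
        return shift @ uncentre @ scale @ rot @ centre


def sample_augmentation(rng: np.random.Generator,
                        config: AugmentationConfig = AugmentationConfig()
                        ) -> AffineAugmentation:
    """Draw scale, shift and rotation independently and uniformly."""
    if not config.enabled:
        return AffineAugmentation()
    s = config.scale_pct / 100.0
    t = config.shift_pct / 100.0
    return AffineAugmentation(
        scale=1.0 + float(rng.uniform(-s, s)),
        shift=(float(rng.uniform(-t, t)), float(rng.uniform(-t, t))),
        rotation=float(rng.uniform(-config.rotation_deg, config.rotation_deg)),
    )


def apply_augmentation(image: WingImage, landmarks: LandmarkSet | None,
                       aug: AffineAugmentation
                       ) -> tuple[WingImage, LandmarkSet | None, np.ndarray]:
    """Apply one augmentation jointly to pixels and coordinates.

    Pixels are resampled bilinearly with the background (border median)
    as fill; coordinates get the exact affine map. Returns the augmented
    image, the mapped landmarks, and an in-frame mask — landmarks pushed
    outside the frame are flagged, not an error.
    """
    px = image.pixels
    shape2 = px.shape[:2]
    m = aug.matrix(shape2)
    minv = np.linalg.inv(m)
    # affine_transform works in (row, col) = (y, x); swap axes of the matrix
    a_xy, b_xy = minv[:2, :2], minv[:2, 2]
    a_rc = a_xy[::-1, ::-1].copy()
    b_rc = b_xy[::-1].copy()
    fill = float(np.median(np.concatenate([px[0].ravel(), px[-1].ravel()])))

    if px.ndim == 2:
        warped = affine_transform(px, a_rc, offset=b_rc, order=1, cval=fill,
                                  mode="constant")
    else:
        warped = np.stack([affine_transform(px[..., c], a_rc, offset=b_rc,
                                            order=1, cval=fill, mode="constant")
                           for c in range(px.shape[2])], axis=-1)
    out_img = WingImage(warped, image.id)

    if landmarks is None:
        return out_img, None, np.ones(0, dtype=bool)
    pts = landmarks.points
    mapped = (np.hstack([pts, np.ones((len(pts), 1))]) @ m.T)[:, :2]
    out_lms = LandmarkSet(mapped, landmarks.valid.copy())
    in_frame = out_lms.in_frame(shape2)
    return out_img, out_lms, in_frame
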