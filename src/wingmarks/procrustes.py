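"""Procrustes shape-bias analysis.

A landmark model is only usable for morphometrics if its error is
independent of wing shape: were predictions worse for unusual shapes,
downstream shape comparisons would be biased at the tails of the shape
distribution. We quantify shape by the Procrustes disparity — a
specimen's distance from the sample mean shape after generalized
Procrustes alignment (translation, scale and rotation removed; no
reflection, since wings are chirality-fixed after flipping) — and regress
each image's mean pixel-distance error on it after trimming 2-SD
outliers on both variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import LandmarkSet

__all__ = ["ProcrustesResult", "BiasRegression", "generalized_procrustes",
           "bias_regression"]


@dataclass
class ProcrustesResult:
    """Mean shape (centred, unit centroid size), aligned shapes and disparities."""

    mean_shape: np.ndarray          # (k, 2)
    aligned_shapes: np.ndarray      # (n, k, 2)
    disparities: np.ndarray         # (n,) Procrustes distance from the mean
    n_iterations: int


def _normalise(shape: np.ndarray) -> np.ndarray:
    centred = shape - shape.mean(axis=0)
    size = np.sqrt((centred ** 2).sum())
    if size < 1e-12:
        raise ValueError("degenerate shape: all landmarks coincide")
    return centred / size


def _rotate_onto(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (det +1, no reflection) of shape onto target."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    return shape @ r


def generalized_procrustes(shapes: list[LandmarkSet] | np.ndarray,
                           tol: float = 1e-8, max_iter: int = 100
                           ) -> ProcrustesResult:
    """Iterative alignment of >= 2 shapes to their evolving mean.

    Each shape is centred and scaled to unit centroid size, then
    repeatedly rotated onto the current mean shape; the mean is
    re-estimated (and renormalised to unit size) until it moves by less
    than ``tol``. Disparity_i is the root-sum-of-squares distance of the
    aligned shape i from the mean.
    """
    arr = np.stack([s.points if isinstance(s, LandmarkSet) else np.asarray(s)
                    for s in shapes]).astype(float)
    if len(arr) < 2:
        raise ValueError("need at least two shapes")
    norm = np.stack([_normalise(s) for s in arr])

    mean = norm[0]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = np.stack([_rotate_onto(s, mean) for s in norm])
        new_mean = _normalise(aligned.mean(axis=0))
        change = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if change < tol:
            break
    aligned = np.stack([_rotate_onto(s, mean) for s in norm])
    disparities = np.sqrt(((aligned - mean) ** 2).sum(axis=(1, 2)))
    return ProcrustesResult(mean, aligned, disparities, iterations)


@dataclass
class BiasRegression:
    """OLS of mean pixel error on Procrustes disparity after 2-SD trimming."""

    slope: float
    intercept: float
    r_squared: float
    r_squared_before: float
    outlier_mask: np.ndarray  # True where the point was trimmed
    n_used: int


def bias_regression(disparities: np.ndarray, mean_errors: np.ndarray
                    ) -> BiasRegression:
    """Trim points beyond 2 SD of the mean on either variable, then fit OLS.

    The trimming is marginal on each variable and the union of flagged
    points is removed; R-squared before removal is reported alongside.
    """
    x = np.asarray(disparities, dtype=float)
    y = np.asarray(mean_errors, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D inputs with >= 3 points")

    r_before = stats.linregress(x, y).rvalue ** 2
    out = (np.abs(x - x.mean()) > 2 * x.std(ddof=0)) \
        | (np.abs(y - y.mean()) > 2 * y.std(ddof=0))
    if (~out).sum() < 3:
        raise ValueError("fewer than 3 points remain after outlier trimming")
    fit = stats.linregress(x[~out], y[~out])
    return BiasRegression(float(fit.slope), float(fit.intercept),
                          float(fit.rvalue ** 2), float(r_before),
                          out, int((~out).sum()))
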