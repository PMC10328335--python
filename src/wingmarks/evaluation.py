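"""Pixel-distance error statistics for landmark predictions.

Errors are Euclidean distances in native image pixels, one per (image,
landmark) pair. Because the error distributions are skewed, interval
summaries are empirical 2.5/97.5 percentiles of the per-instance
distances (with the median), not normal-theory intervals of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import N_LANDMARKS, LandmarkSet

__all__ = ["ErrorSummary", "distance_errors", "per_image_mean_error",
           "quartile_table"]


@dataclass
class ErrorSummary:
    """Distance-error summary: MAE, RMSE and LB/median/UB percentile bounds."""

    per_pair_distances: np.ndarray  # (n_images, 11)
    mae: float
    rmse: float
    lb: float
    median: float
    ub: float
    per_landmark: pd.DataFrame

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "lb": self.lb,
                "median": self.median, "ub": self.ub,
                "per_landmark": self.per_landmark.to_dict(orient="records")}


def _distances(pred: list[LandmarkSet], truth: list[LandmarkSet]) -> np.ndarray:
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    if not pred:
        raise ValueError("empty input")
    diffs = np.stack([p.points - t.points for p, t in zip(pred, truth)])
    return np.sqrt((diffs ** 2).sum(axis=2))


def distance_errors(pred: list[LandmarkSet], truth: list[LandmarkSet]
                    ) -> ErrorSummary:
    """Overall and per-landmark MAE/RMSE with percentile interval bounds.

    lb/ub are the 2.5th/97.5th percentiles (linear interpolation between
    order statistics) of the pooled per-pair distances.
    """
    d = _distances(pred, truth)
    flat = d.ravel()
    rows = []
    for k in range(N_LANDMARKS):
        dk = d[:, k]
        rows.append({"landmark": k + 1, "mae": float(dk.mean()),
                     "rmse": float(np.sqrt(np.mean(dk ** 2))),
                     "median": float(np.median(dk)),
                     "lb": float(np.percentile(dk, 2.5)),
                     "ub": float(np.percentile(dk, 97.5))})
    return ErrorSummary(
        per_pair_distances=d,
        mae=float(flat.mean()),
        rmse=float(np.sqrt(np.mean(flat ** 2))),
        lb=float(np.percentile(flat, 2.5)),
        median=float(np.median(flat)),
        ub=float(np.percentile(flat, 97.5)),
        per_landmark=pd.DataFrame(rows),
    )


def per_image_mean_error(pred: list[LandmarkSet], truth: list[LandmarkSet]
                         ) -> np.ndarray:
    """Mean of the 11 per-landmark distances for each image."""
    return _distances(pred, truth).mean(axis=1)


def quartile_table(pred: list[LandmarkSet], truth: list[LandmarkSet]
                   ) -> pd.DataFrame:
    """Box-plot-ready per-landmark quartiles (q1, median, q3, whiskers)."""
    d = _distances(pred, truth)
    rows = []
    for k in range(N_LANDMARKS):
        q1, med, q3 = np.percentile(d[:, k], [25, 50, 75])
        iqr = q3 - q1
        rows.append({"landmark": k + 1, "q1": q1, "median": med, "q3": q3,
                     "lo_whisker": max(d[:, k].min(), q1 - 1.5 * iqr),
                     "hi_whisker": min(d[:, k].max(), q3 + 1.5 * iqr)})
    return pd.DataFrame(rows)
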