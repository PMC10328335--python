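"""End-to-end wiring: splits, the two-tier gate, and desk-scale runs.

The deployment pattern is a gate-then-locate pipeline: tier 1 scores each
(left-oriented) image and wings classified incomplete are rejected from
landmark prediction; tier 2 produces coordinates for the remainder. One
seed fixes data generation, the 60:20:20 split, initialisation,
augmentation and bootstrap draws, so a run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierConfig, predict_scores
from .io import LandmarkSet, WingImage, flip_to_left
from .landmarks import predict_regression, predict_segmentation
from .nn import Sequential

__all__ = ["RunConfig", "split_indices", "two_tier_predict"]


@dataclass
class RunConfig:
    """Top-level run parameters; split defaults to 60:20:20."""

    seed: int = 0
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_indices(n: int, split: tuple[float, float, float],
                  rng: np.random.Generator,
                  stratify: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/val/test index sets, optionally stratified by label."""
    if stratify is None:
        groups = [np.arange(n)]
    else:
        stratify = np.asarray(stratify)
        groups = [np.nonzero(stratify == v)[0] for v in np.unique(stratify)]
    train, val, test = [], [], []
    for g in groups:
        perm = rng.permutation(g)
        n_tr = int(round(split[0] * len(g)))
        n_va = int(round(split[1] * len(g)))
        train.append(perm[:n_tr])
        val.append(perm[n_tr:n_tr + n_va])
        test.append(perm[n_tr + n_va:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def two_tier_predict(images: list[WingImage],
                     classifier: Sequential,
                     landmark_model: Sequential,
                     *, classifier_input: int, landmark_input: int,
                     head: str = "regression",
                     threshold: float = 0.5
                     ) -> tuple[dict[str, LandmarkSet], list[tuple[str, float]]]:
    """Gate with tier 1, localise with tier 2.

    Right-wing images are flipped before both tiers. Returns landmark
    sets for accepted (complete) wings keyed by image name, and the
    rejected images with their incompleteness scores.
    """
    if classifier is None or landmark_model is None:
        raise ValueError("both a trained classifier and landmark model are required")
    oriented = []
    for img in images:
        flipped, _ = flip_to_left(img, None)
        oriented.append(flipped)
    scores = predict_scores(classifier, oriented, classifier_input)

    predict = predict_regression if head == "regression" else predict_segmentation
    accepted: dict[str, LandmarkSet] = {}
    rejected: list[tuple[str, float]] = []
    for img, score in zip(oriented, scores):
        name = str(img.id) if img.id is not None else f"image{len(accepted) + len(rejected)}"
        if score >= threshold:
            rejected.append((name, float(score)))
        else:
            accepted[name] = predict(landmark_model, img, landmark_input)
    return accepted, rejected
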