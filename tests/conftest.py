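"""Shared fixtures: small synthetic wing sets and (expensive) trained models.

Training fixtures are session-scoped so the module tests and the
acceptance suite share one run each of the tier-1 classifier, the two
tier-2 heads, and the augmentation-direction experiment. Everything is
seeded; wings are generated at a reduced 128 x 160 native canvas with
64 px model inputs to keep the whole suite inside a CPU test budget.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from wingmarks import evaluation, synthetic
from wingmarks.augment import AugmentationConfig
from wingmarks.classifier import (ClassifierConfig, build_classifier,
                                  predict_scores, train_classifier)
from wingmarks.landmarks import (RegressionConfig, SegmentationConfig,
                                 baseline_mean_location, build_regression_net,
                                 build_segmentation_net, predict_regression,
                                 predict_segmentation, train_regression,
                                 train_segmentation)
from wingmarks.pipeline import split_indices

CANVAS = (128, 160)
INPUT = 64


@pytest.fixture(scope="session")
def wing_batch():
    """300 complete wings with ground truth at the reduced canvas."""
    rng = np.random.default_rng(11)
    wings = [synthetic.generate_wing(synthetic.sample_spec(rng, canvas=CANVAS))
             for _ in range(300)]
    return [(img, lms) for img, lms, _ in wings]


@pytest.fixture(scope="session")
def labelled_batch():
    """200 wings, balanced complete/incomplete, for tier 1."""
    wings = synthetic.generate_training_set(200, incomplete_fraction=0.5,
                                            rng_seed=0, canvas=CANVAS)
    return [(img, lab) for img, _, lab in wings]


@pytest.fixture(scope="session")
def trained_classifier(labelled_batch):
    """Tier-1 tiny net trained for 10 epochs; returns model + split + accuracy."""
    labels = np.array([lab for _, lab in labelled_batch])
    rng = np.random.default_rng(0)
    tr, va, te = split_indices(len(labelled_batch), (0.6, 0.2, 0.2), rng,
                               stratify=labels)
    config = ClassifierConfig(input_size=INPUT, epochs=10, batch_size=10, lr=5e-3)
    model = build_classifier(config, rng)
    result = train_classifier(model, [labelled_batch[i] for i in tr],
                              [labelled_batch[i] for i in va], config, rng)
    val_scores = predict_scores(model, [labelled_batch[i][0] for i in va], INPUT)
    val_acc = float(((val_scores >= 0.5).astype(int) == labels[va]).mean())
    return {"model": model, "config": config, "result": result,
            "splits": (tr, va, te), "labels": labels, "val_accuracy": val_acc}


@pytest.fixture(scope="session")
def trained_tier2(wing_batch):
    """Both tier-2 heads trained on the shared wing batch, plus the baseline."""
    rng = np.random.default_rng(0)
    tr, va, te = split_indices(len(wing_batch), (0.6, 0.2, 0.2), rng)
    train = [wing_batch[i] for i in tr]
    val = [wing_batch[i] for i in va]
    truths = [wing_batch[i][1] for i in te]

    reg_cfg = RegressionConfig(input_size=INPUT, session_epochs=(30, 15),
                               session_lrs=(1e-3, 1e-4), batch_size=16)
    reg = build_regression_net(reg_cfg, rng)
    train_regression(reg, train, val, reg_cfg, rng)
    reg_preds = [predict_regression(reg, wing_batch[i][0], INPUT) for i in te]

    seg_cfg = SegmentationConfig(input_size=INPUT, disk_radius=3, epochs=20,
                                 batch_size=16)
    seg = build_segmentation_net(seg_cfg, rng)
    train_segmentation(seg, train, val, seg_cfg, rng)
    seg_preds = [predict_segmentation(seg, wing_batch[i][0], INPUT) for i in te]

    baseline = baseline_mean_location([lms for _, lms in train])
    base_preds = [baseline.predict() for _ in te]

    return {
        "regression_model": reg, "segmentation_model": seg,
        "input_size": INPUT, "test_truths": truths,
        "regression": evaluation.distance_errors(reg_preds, truths),
        "segmentation": evaluation.distance_errors(seg_preds, truths),
        "baseline": evaluation.distance_errors(base_preds, truths),
        "regression_preds": reg_preds, "segmentation_preds": seg_preds,
    }


@pytest.fixture(scope="session")
def augmentation_experiment():
    """Regression head trained on position-biased wings, tested on shifted ones.

    The training wings sit at the canvas centre; the test wings are
    shifted, so affine augmentation is the only route to generalising
    over position.
    """
    srng = np.random.default_rng(5)

    def wingset(n, centred):
        out = []
        for _ in range(n):
            spec = synthetic.sample_spec(srng, canvas=CANVAS)
            if centred:
                spec = replace(spec, shift=(0.0, 0.0))
            img, lms, _ = synthetic.generate_wing(spec)
            out.append((img, lms))
        return out

    train, val, test = wingset(180, True), wingset(40, True), wingset(60, False)
    truths = [lms for _, lms in test]
    maes = {}
    for key, aug in (("without", None), ("with", AugmentationConfig(enabled=True))):
        cfg = RegressionConfig(input_size=INPUT, session_epochs=(15, 8),
                               session_lrs=(1e-3, 1e-4), augment=aug)
        rng = np.random.default_rng(0)
        model = build_regression_net(cfg, rng)
        train_regression(model, train, val, cfg, rng)
        preds = [predict_regression(model, img, INPUT) for img, _ in test]
        maes[key] = evaluation.distance_errors(preds, truths).mae
    return maes
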