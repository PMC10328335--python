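"""Tier-2 heads: disk targets, map inference, losses, prediction plumbing."""

import numpy as np
import pytest

from wingmarks.io import LandmarkSet, WingImage
from wingmarks.landmarks import (RegressionConfig, SegmentationConfig,
                                 baseline_mean_location, build_regression_net,
                                 build_segmentation_net, combined_loss,
                                 infer_landmark_from_map, make_disk_targets,
                                 predict_regression, predict_segmentation)
from wingmarks.models_common import native_to_model
from wingmarks.nn import sigmoid


def _lms(pts):
    return LandmarkSet(np.asarray(pts, float))


def _interior_lms(x=100.0, y=50.0):
    pts = np.tile([x, y], (11, 1))
    return _lms(pts)


def lattice_disk_count(radius):
    """Brute-force count of lattice points with dx^2 + dy^2 <= R^2."""
    return sum(1 for dx in range(-radius, radius + 1)
               for dy in range(-radius, radius + 1)
               if dx * dx + dy * dy <= radius * radius)


@pytest.mark.parametrize("radius,expected", [(1, 5), (5, 81)])
def test_disk_target_interior_sums(radius, expected):
    # native == model space so landmark coordinates stay integral
    target = make_disk_targets(_interior_lms(), (224, 224), 224, radius)
    assert lattice_disk_count(radius) == expected
    assert np.all(target.maps.sum(axis=(1, 2)) == expected)


def test_disk_clipped_at_corner_and_radius_validation():
    corner = _lms(np.tile([0.0, 0.0], (11, 1)))
    target = make_disk_targets(corner, (224, 224), 224, 5)
    assert target.maps[0].sum() < lattice_disk_count(5)
    with pytest.raises(ValueError):
        make_disk_targets(corner, (224, 224), 224, 0)
    assert target.maps.shape == (11, 224, 224)


def test_infer_from_binary_disk_and_constant_map():
    m = np.zeros((100, 200))
    yy, xx = np.mgrid[0:100, 0:200]
    m[(xx - 100) ** 2 + (yy - 50) ** 2 <= 4] = 1.0  # 13-pixel disk
    assert m.sum() == 13
    assert infer_landmark_from_map(m) == (100.0, 50.0)
    x, y = infer_landmark_from_map(np.ones((100, 200)))
    assert (x, y) == ((200 - 1) / 2, (100 - 1) / 2)


def _oracle_seventh_highest(m):
    flat = sorted(m.ravel(), reverse=True)
    v7 = flat[min(6, len(flat) - 1)]
    ys, xs = np.nonzero(m >= v7)
    return float(xs.mean()), float(ys.mean())


def test_gaussian_bump_matches_sort_select_average_oracle():
    yy, xx = np.mgrid[0:64, 0:64]
    cx, cy = 30.3, 41.7
    bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / 18.0)
    got = infer_landmark_from_map(bump)
    assert got == _oracle_seventh_highest(bump)
    assert np.hypot(got[0] - cx, got[1] - cy) <= 1.0


def test_inference_translation_equivariance_and_bounds():
    rng = np.random.default_rng(0)
    m = np.zeros((64, 64))
    m[20:30, 15:25] = rng.uniform(0.5, 1.0, (10, 10))
    x0, y0 = infer_landmark_from_map(m)
    shifted = np.roll(np.roll(m, 7, axis=0), -3, axis=1)
    x1, y1 = infer_landmark_from_map(shifted)
    assert (x1 - x0, y1 - y0) == (-3.0, 7.0)
    assert 0 <= x0 < 64 and 0 <= y0 < 64


def test_combined_loss_limits_and_formula_oracle():
    t = np.zeros((2, 11, 16, 16))
    t[:, :, 4:7, 4:7] = 1.0
    assert combined_loss(t, t) == pytest.approx(0.0, abs=1e-5)
    flipped = combined_loss(1.0 - t, t)
    assert flipped > 2.0  # BCE explodes, dice term ~1

    rng = np.random.default_rng(1)
    p = rng.uniform(0.01, 0.99, (3, 11, 8, 8))
    tt = (rng.uniform(size=p.shape) > 0.7).astype(float)
    eps = 1.0
    bce = -np.mean(tt * np.log(p) + (1 - tt) * np.log(1 - p))
    dice = []
    for b in range(3):
        for c in range(11):
            inter = (p[b, c] * tt[b, c]).sum()
            dice.append(1 - (2 * inter + eps) / (p[b, c].sum() + tt[b, c].sum() + eps))
    assert combined_loss(p, tt) == pytest.approx((bce + np.mean(dice)) / 2)
    with pytest.raises(ValueError):
        combined_loss(p, tt[:2])


def test_combined_loss_decreases_along_interpolation():
    t = np.zeros((1, 11, 16, 16))
    t[:, :, 6:10, 6:10] = 1.0
    alphas = np.linspace(0.0, 1.0, 6)
    losses = [combined_loss(np.clip((1 - a) * (1 - t) + a * t, 1e-6, 1 - 1e-6), t)
              for a in alphas]
    assert all(b < a for a, b in zip(losses, losses[1:]))


def test_regression_codec_round_trip_and_zero_head():
    rng = np.random.default_rng(2)
    cfg = RegressionConfig(input_size=64)
    model = build_regression_net(cfg, rng)
    img = WingImage(rng.uniform(size=(128, 160)))
    lms = LandmarkSet(rng.uniform(10, 110, (11, 2)))
    # encode to normalised targets, decode through the prediction rescaler
    encoded = native_to_model(lms.points, img.shape, 64) / 64
    from wingmarks.models_common import model_to_native
    decoded = model_to_native(encoded * 64, img.shape, 64)
    np.testing.assert_allclose(decoded, lms.points, atol=1e-9)

    for p in model.layers[-1].params:
        p[...] = 0.0
    pred = predict_regression(model, img, 64)
    np.testing.assert_allclose(pred.points, 0.0, atol=1e-12)


def test_segmentation_on_exact_disk_targets_recovers_landmarks():
    """A model emitting the targets themselves localises within 0.5 px of
    ground truth (model space); checked through the same inference path."""
    rng = np.random.default_rng(3)
    img = WingImage(rng.uniform(size=(128, 160)))
    pts = np.column_stack([rng.integers(10, 150, 11), rng.integers(10, 118, 11)])
    lms = LandmarkSet(pts.astype(float))
    model_pts = native_to_model(lms.points, img.shape, 64)
    target = make_disk_targets(lms, img.shape, 64, 3)
    for k in range(11):
        x, y = infer_landmark_from_map(target.maps[k])
        assert np.hypot(x - model_pts[k, 0], y - model_pts[k, 1]) <= 0.5


def test_model_space_centre_maps_to_native_centre():
    from wingmarks.models_common import model_to_native
    out = model_to_native(np.array([[112.0, 112.0]]), (1024, 1280), 224)
    np.testing.assert_allclose(out, [[640.0, 512.0]])


def test_segmentation_net_output_shape():
    rng = np.random.default_rng(4)
    model = build_segmentation_net(SegmentationConfig(input_size=32), rng)
    out = model.forward(rng.normal(0, 1, (2, 3, 32, 32)))
    assert out.shape == (2, 11, 32, 32)
    probs = sigmoid(out)
    assert np.all((probs > 0) & (probs < 1))


def test_baseline_mean_location():
    a = LandmarkSet(np.zeros((11, 2)))
    b = LandmarkSet(np.full((11, 2), 10.0))
    assert np.array_equal(baseline_mean_location([a]).predict().points, a.points)
    mid = baseline_mean_location([a, b]).predict()
    np.testing.assert_allclose(mid.points, 5.0)
    with pytest.raises(ValueError):
        baseline_mean_location([])


def test_trained_heads_beat_mean_location_baseline(trained_tier2):
    """Seeded training on 300 synthetic wings: both heads below baseline MAE,
    segmentation median below baseline median."""
    reg, seg, base = (trained_tier2["regression"], trained_tier2["segmentation"],
                      trained_tier2["baseline"])
    assert reg.mae < base.mae
    assert seg.mae < base.mae
    assert seg.median < base.median


def test_augmentation_helps_on_shifted_wings(augmentation_experiment):
    """Position-biased training: augmentation reduces shifted-test MAE."""
    assert augmentation_experiment["with"] < augmentation_experiment["without"]
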