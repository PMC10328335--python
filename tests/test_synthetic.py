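"""Generator correctness: determinism, geometry, damage semantics, pages."""

import numpy as np
import pytest

from wingmarks import qc, synthetic
from wingmarks.io import MM_PER_PIXEL
from wingmarks.synthetic import GenerationError, SyntheticWingSpec, generate_wing

CANVAS = dict(canvas_height=128, canvas_width=160)


def test_seeded_determinism_bytewise():
    spec = SyntheticWingSpec(**CANVAS, rotation=7.0, shift=(4.0, -3.0), rng_seed=42)
    img1, lms1, lab1 = generate_wing(spec)
    img2, lms2, lab2 = generate_wing(spec)
    assert np.array_equal(img1.pixels, img2.pixels)
    assert np.array_equal(lms1.points, lms2.points)
    assert lab1 == lab2 == 0


def test_rotation_rotates_landmarks_about_canvas_centre():
    base = SyntheticWingSpec(**CANVAS, rotation=0.0, rng_seed=1)
    rot = SyntheticWingSpec(**CANVAS, rotation=30.0, rng_seed=1)
    _, lms0, _ = generate_wing(base)
    _, lmsr, _ = generate_wing(rot)
    theta = np.deg2rad(30.0)
    c, s = np.cos(theta), np.sin(theta)
    centre = np.array([(160 - 1) / 2, (128 - 1) / 2])
    expected = (lms0.points - centre) @ np.array([[c, s], [-s, c]]) + centre
    np.testing.assert_allclose(lmsr.points, expected, atol=1e-9)


def test_zero_rotation_landmarks_match_scaled_template():
    spec = SyntheticWingSpec(**CANVAS, rotation=0.0, shift=(0.0, 0.0),
                             scale_factor=0.5, shape_sd=0.0, rng_seed=0)
    _, lms, _ = generate_wing(spec)
    centre = np.array([(160 - 1) / 2, (128 - 1) / 2])
    expected = (synthetic.template_landmarks() - 0.5) * 0.5 * 160 + centre
    np.testing.assert_allclose(lms.points, expected, atol=1e-9)


def test_landmarks_lie_on_veins():
    """Ground-truth consistency: each valid landmark sits on dark vein pixels."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        spec = synthetic.sample_spec(rng, canvas=(128, 160))
        img, lms, _ = generate_wing(spec)
        for x, y in lms.points:
            value = img.pixels[int(round(y)), int(round(x))]
            assert value < spec.brightness - 0.3 * spec.contrast


@pytest.mark.parametrize("damage,invalid_idx,label", [
    ("none", None, 0), ("missing_lm4", 3, 1), ("missing_lm6", 5, 1),
    ("torn", None, 0), ("stained", None, 0),
])
def test_damage_modes_invalidate_only_their_landmark(damage, invalid_idx, label):
    spec = SyntheticWingSpec(**CANVAS, damage=damage, rng_seed=9)
    _, lms, lab = generate_wing(spec)
    assert lab == label
    expected = np.ones(11, dtype=bool)
    if invalid_idx is not None:
        expected[invalid_idx] = False
    assert np.array_equal(lms.valid, expected)


def test_absent_wing_invalidates_everything():
    _, lms, lab = generate_wing(SyntheticWingSpec(**CANVAS, damage="absent_wing"))
    assert lab == 1
    assert not lms.valid.any()


def test_out_of_canvas_landmark_raises_naming_it():
    spec = SyntheticWingSpec(**CANVAS, scale_factor=0.99, shift=(100.0, 0.0))
    with pytest.raises(GenerationError, match=r"landmark \d+"):
        generate_wing(spec)


def test_damage_fraction_within_fpc_binomial_margin():
    """Batch of 200 wings at damage probability 0.13: count stays within the
    binomial 95% margin (oracle: brute-force count of returned labels)."""
    wings = synthetic.generate_training_set(200, incomplete_fraction=0.13,
                                            rng_seed=7, canvas=(128, 160))
    frac = float(np.mean([lab for _, _, lab in wings]))
    margin = qc.binomial_margin(0.13, 200, 14354)
    assert abs(frac - 0.13) <= margin


# ---------------------------------------------------------------------------
# pages


def test_page_identity_association_and_exact_lengths():
    page = synthetic.generate_page(6, rng_seed=2, wlm_noise_sd=0.0)
    assert page.association == list(range(6))
    for line in page.lines:
        d = np.linalg.norm(line.landmarks.point(1) - line.landmarks.point(6))
        assert line.record.wlm == pytest.approx(MM_PER_PIXEL * d)


def test_skipped_image_shifts_every_later_record():
    page = synthetic.generate_page(20, "skipped_image", 0, rng_seed=1)
    # every record is affected: one-step-behind for 19 lines, final line lost
    assert page.association[:-1] == list(range(1, 20))
    assert page.association[-1] is None
    assert all(a != i for i, a in enumerate(page.association))


def test_duplicated_image_repeats_and_shifts_ahead():
    k = 4
    page = synthetic.generate_page(10, "duplicated_image", k, rng_seed=3,
                                   render=True, canvas=(128, 160))
    assert page.association[k] == page.association[k + 1] == k
    assert page.association[k + 2:] == list(range(k + 1, 9))
    imgs = page.images
    assert np.array_equal(imgs[f"V20P001L{k + 1:02d}L"].pixels,
                          imgs[f"V20P001L{k + 2:02d}L"].pixels)


def test_page_bounds_and_error_line_validation():
    with pytest.raises(ValueError):
        synthetic.generate_page(21)
    with pytest.raises(ValueError):
        synthetic.generate_page(5, "skipped_image", 5)
    with pytest.raises(ValueError):
        synthetic.generate_page(5, "skipped_image", None)


def test_write_page_round_trips_through_csv(tmp_path):
    from wingmarks.io import read_bio_csv, read_landmark_csv
    page = synthetic.generate_page(3, rng_seed=5, render=True, canvas=(128, 160))
    synthetic.write_page(page, tmp_path)
    lms = read_landmark_csv(tmp_path / "landmarks.csv")
    recs = read_bio_csv(tmp_path / "bio.csv")
    assert len(lms) == 6 and len(recs) == 3
    np.testing.assert_allclose(lms["V20P001L01L"].points,
                               page.lines[0].landmarks.points, atol=1e-6)
    assert recs[0].wlm == pytest.approx(page.lines[0].record.wlm, abs=5e-4)
    assert (tmp_path / "V20P001L02R.png").exists()
    assert (tmp_path / "manifest.json").exists()
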