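"""Sampling margins, page-level misalignment QC, length agreement, corrections."""

import numpy as np
import pytest

from wingmarks import qc, synthetic
from wingmarks.io import BioRecord, LandmarkSet, WingID


def _predictions_for(page, noise_px=0.0, rng=None):
    """Predicted landmark sets keyed by image name, as the pipeline would emit."""
    preds = {}
    vol, pg = page.page_id
    for i, shown in enumerate(page.association):
        if shown is None:
            continue
        pts = page.lines[shown].landmarks.points.copy()
        if rng is not None and noise_px > 0:
            pts = pts + rng.normal(0, noise_px, pts.shape)
        preds[str(WingID(vol, pg, i + 1, "L"))] = LandmarkSet(pts)
    return preds


def test_binomial_margin_limits():
    assert qc.binomial_margin(0.0, 50, 1000) == 0.0
    # FPC -> 1 as N -> infinity: converges to the uncorrected margin
    uncorrected = 1.96 * np.sqrt(0.3 * 0.7 / 100)
    assert qc.binomial_margin(0.3, 100, 10 ** 9) == pytest.approx(uncorrected,
                                                                  rel=1e-6)
    # margin -> 0 as the sample exhausts the population
    assert qc.binomial_margin(0.3, 1000, 1000) == 0.0
    with pytest.raises(ValueError):
        qc.binomial_margin(0.3, 10, 5)
    with pytest.raises(ValueError):
        qc.binomial_margin(1.2, 10, 50)


def test_sample_estimate_carries_margin():
    est = qc.sample_estimate(26, 200, 14354)
    assert est.p_hat == pytest.approx(0.13)
    assert est.margin == pytest.approx(qc.binomial_margin(0.13, 200, 14354))


def test_aligned_page_has_unit_r2():
    page = synthetic.generate_page(12, rng_seed=0, wlm_noise_sd=0.0)
    reports = qc.page_r_squared([ln.record for ln in page.lines],
                                _predictions_for(page))
    assert len(reports) == 1
    assert reports[0].r_squared == pytest.approx(1.0)
    assert not reports[0].flagged and not reports[0].degenerate


def test_r2_invariant_to_wing_order_when_aligned():
    page = synthetic.generate_page(10, rng_seed=1)
    records = [ln.record for ln in page.lines]
    preds = _predictions_for(page)
    r2a = qc.page_r_squared(records, preds)[0].r_squared
    r2b = qc.page_r_squared(records[::-1], preds)[0].r_squared
    assert r2a == pytest.approx(r2b)


def test_early_misalignment_usually_flagged_late_often_missed():
    """Direction check: detection decays with error position on the page,
    and clean pages are essentially never flagged."""
    rng = np.random.default_rng(10)
    hits = {0: 0, 16: 0}
    clean_flags = 0
    reps = 120
    for r in range(reps):
        for err in hits:
            page = synthetic.generate_page(
                18, "skipped_image", err, rng_seed=int(rng.integers(2 ** 31 - 1)))
            rep = qc.page_r_squared([ln.record for ln in page.lines],
                                    _predictions_for(page, 3.0, rng))[0]
            hits[err] += bool(rep.flagged)
        page = synthetic.generate_page(18, rng_seed=int(rng.integers(2 ** 31 - 1)))
        rep = qc.page_r_squared([ln.record for ln in page.lines],
                                _predictions_for(page, 3.0, rng))[0]
        clean_flags += bool(rep.flagged)
    assert hits[0] / reps >= 0.7          # early error: mostly detected
    assert hits[16] < hits[0]             # late error: much harder
    assert clean_flags / reps < 0.05


def test_degenerate_pages_are_surfaced_not_flagged():
    records = [BioRecord((20, 9, i + 1), 4.0) for i in range(5)]  # zero variance
    page = synthetic.generate_page(5, rng_seed=2, page_id=(20, 9))
    reports = qc.page_r_squared(records, _predictions_for(page))
    assert reports[0].degenerate and not reports[0].flagged
    tiny = qc.page_r_squared([BioRecord((20, 9, 1), 4.0)], {})
    assert tiny[0].degenerate
    with pytest.raises(ValueError):
        qc.page_r_squared([], {})


def test_length_agreement_perfect_predictions():
    page = synthetic.generate_page(15, rng_seed=3, wlm_noise_sd=0.0)
    report = qc.length_agreement([ln.record for ln in page.lines],
                                 _predictions_for(page))
    assert report["r_squared"] == pytest.approx(1.0)
    assert report["outlier_vpns"] == []
    assert report["slope"] == pytest.approx(1.0)


def test_length_agreement_flags_injected_record_swaps():
    """2% gross swaps among 1000 wings: flagged fraction within binomial bounds."""
    rng = np.random.default_rng(4)
    records, preds = [], {}
    n_pages, per_page = 50, 20
    swapped = 0
    for p in range(n_pages):
        page = synthetic.generate_page(per_page, rng_seed=int(rng.integers(2 ** 31)),
                                       page_id=(20, p + 1))
        pagep = _predictions_for(page, 1.0, rng)
        # swap 2% of lines with a wing from elsewhere on the page
        for i in range(per_page):
            if rng.uniform() < 0.02:
                j = (i + 7) % per_page
                name_i = f"V20P{p + 1:03d}L{i + 1:02d}L"
                name_j = f"V20P{p + 1:03d}L{j + 1:02d}L"
                pagep[name_i] = LandmarkSet(page.lines[j].landmarks.points.copy())
                swapped += 1
        records.extend(ln.record for ln in page.lines)
        preds.update(pagep)
    report = qc.length_agreement(records, preds)
    margin = qc.binomial_margin(swapped / 1000, 1000, 10 ** 9)
    assert abs(report["outlier_fraction"] - swapped / 1000) <= margin + 0.02


def test_length_agreement_matches_normal_equations():
    rng = np.random.default_rng(5)
    page = synthetic.generate_page(20, rng_seed=6)
    records = [ln.record for ln in page.lines]
    preds = _predictions_for(page, 2.0, rng)
    report = qc.length_agreement(records, preds)
    x = np.array([r.wlm for r in records])
    y = np.array([qc._predicted_length(preds, r.vpn) for r in records])
    design = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
    assert report["slope"] == pytest.approx(slope)
    assert report["intercept"] == pytest.approx(intercept)


def test_excluded_hatchet_records_are_dropped():
    page = synthetic.generate_page(6, rng_seed=7, wlm_noise_sd=0.0)
    records = [ln.record for ln in page.lines]
    records[0].exclude_length = True
    report = qc.length_agreement(records, _predictions_for(page))
    assert report["n"] == 5


# ---------------------------------------------------------------------------
# reconciliation


def test_empty_correction_log_changes_nothing():
    out = qc.apply_corrections({(20, 1): 5}, [])
    assert out == {(20, 1): [0, 1, 2, 3, 4]}


def test_skipped_page_correction_restores_unit_r2():
    page = synthetic.generate_page(12, "skipped_image", 2, rng_seed=8,
                                   wlm_noise_sd=0.0)
    log = qc.reconcile([page])
    assoc = qc.apply_corrections({page.page_id: page.n_lines}, log)[page.page_id]
    preds = _predictions_for(page)
    wlm, pred_len = [], []
    vol, pg = page.page_id
    for line, image_line in enumerate(assoc):
        if image_line is None:
            continue
        name = str(WingID(vol, pg, image_line + 1, "L"))
        if name in preds:
            wlm.append(page.lines[line].record.wlm)
            pred_len.append(qc.wing_length_mm(preds[name]))
    assert len(wlm) == 11   # one line lost to the skip
    assert np.corrcoef(wlm, pred_len)[0, 1] ** 2 == pytest.approx(1.0)


def test_duplicated_page_correction_restores_unit_r2():
    page = synthetic.generate_page(10, "duplicated_image", 3, rng_seed=9,
                                   wlm_noise_sd=0.0)
    log = qc.reconcile([page])
    assoc = qc.apply_corrections({page.page_id: page.n_lines}, log)[page.page_id]
    preds = _predictions_for(page)
    vol, pg = page.page_id
    pairs = [(page.lines[line].record.wlm,
              qc.wing_length_mm(preds[str(WingID(vol, pg, img + 1, 'L'))]))
             for line, img in enumerate(assoc) if img is not None]
    w, pl = zip(*pairs)
    assert np.corrcoef(w, pl)[0, 1] ** 2 == pytest.approx(1.0)


def test_unknown_page_in_log_rejected():
    with pytest.raises(ValueError, match="unknown page"):
        qc.apply_corrections({(20, 1): 3}, [qc.CorrectionAction((21, 9),
                                                                "remove_page", None)])
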