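"""Quasi-identifier alignment QC and sample statistics.

The dissector-measured wing length (wlm) is the single quasi-identifier
shared by the biological records and the image-derived predictions. A
photographing slip (a duplicated or skipped image) shifts every later
association on the page, so the page-level R-squared between wlm and the
predicted landmark-1-to-6 length collapses; pages below a threshold
(default 0.1) are flagged for review. Sampling margins use the normal
approximation with the finite-population correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import BioRecord, LandmarkSet, WingID, wing_length_mm
from .synthetic import SyntheticPage

__all__ = ["SampleEstimate", "PageAlignmentReport", "binomial_margin",
           "sample_estimate", "page_r_squared", "length_agreement",
           "CorrectionAction", "reconcile", "apply_corrections"]


def binomial_margin(p_hat: float, n: int, big_n: int, z: float = 1.96) -> float:
    """95% margin z*sqrt(p(1-p)/n) shrunk by the FPC sqrt((N-n)/(N-1)).

    Converges to the uncorrected normal margin as N grows and to 0 as the
    sample exhausts the population.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    if not 1 <= n <= big_n:
        raise ValueError("need 1 <= n <= N")
    fpc = 1.0 if big_n == 1 else math.sqrt((big_n - n) / (big_n - 1))
    return z * math.sqrt(p_hat * (1.0 - p_hat) / n) * fpc


@dataclass
class SampleEstimate:
    """A proportion estimate with its finite-population 95% margin."""

    p_hat: float
    n: int
    N: int
    z: float = 1.96
    margin: float = field(init=False)

    def __post_init__(self) -> None:
        self.margin = binomial_margin(self.p_hat, self.n, self.N, self.z)


def sample_estimate(successes: int, n: int, big_n: int, z: float = 1.96
                    ) -> SampleEstimate:
    return SampleEstimate(successes / n, n, big_n, z)


@dataclass
class PageAlignmentReport:
    """Per-page QC verdict; degenerate pages go to manual review, never pass."""

    page_id: tuple[int, int]
    n_wings: int
    r_squared: float | None
    flagged: bool
    degenerate: bool


def _predicted_length(predictions: dict[str, LandmarkSet],
                      vpn: tuple[int, int, int]) -> float | None:
    vol, page, line = vpn
    for side in ("L", "R"):
        lms = predictions.get(str(WingID(vol, page, line, side)))
        if lms is not None and lms.valid[0] and lms.valid[5]:
            return wing_length_mm(lms)
    return None


def page_r_squared(records: list[BioRecord],
                   predictions: dict[str, LandmarkSet],
                   threshold: float = 0.1,
                   min_points: int = 3) -> list[PageAlignmentReport]:
    """Flag pages whose wlm / predicted-length R-squared falls below threshold.

    R-squared is the squared Pearson correlation over the page's usable
    lines (record with wlm plus a predicted length from either side's
    image). Pages with fewer than ``min_points`` usable lines or zero
    variance in either variable are marked degenerate instead of flagged.
    """
    if not records:
        raise ValueError("no records supplied")
    pages: dict[tuple[int, int], list[tuple[float, float]]] = {}
    counts: dict[tuple[int, int], int] = {}
    for rec in records:
        key = rec.vpn[:2]
        counts[key] = counts.get(key, 0) + 1
        pred = _predicted_length(predictions, rec.vpn)
        if rec.wlm is not None and pred is not None:
            pages.setdefault(key, []).append((rec.wlm, pred))

    reports = []
    for key in sorted(counts):
        pairs = pages.get(key, [])
        if len(pairs) < min_points:
            reports.append(PageAlignmentReport(key, counts[key], None, False, True))
            continue
        wlm = np.array([p[0] for p in pairs])
        pred = np.array([p[1] for p in pairs])
        if wlm.std() < 1e-12 or pred.std() < 1e-12:
            reports.append(PageAlignmentReport(key, counts[key], None, False, True))
            continue
        r2 = float(np.corrcoef(wlm, pred)[0, 1] ** 2)
        reports.append(PageAlignmentReport(key, counts[key], r2,
                                           r2 < threshold, False))
    return reports


def length_agreement(records: list[BioRecord],
                     predictions: dict[str, LandmarkSet],
                     z: float = 1.96) -> dict:
    """Measured-vs-predicted length regression with outlier flagging.

    Hatchet-cell (``exclude_length``) records are dropped; predicted
    length is regressed on wlm by OLS; points outside the global
    prediction band fit +/- z * residual-SE are returned as outliers with
    their vpn keys for manual review.
    """
    xs, ys, vpns = [], [], []
    for rec in records:
        if rec.exclude_length or rec.wlm is None:
            continue
        pred = _predicted_length(predictions, rec.vpn)
        if pred is not None:
            xs.append(rec.wlm)
            ys.append(pred)
            vpns.append(rec.vpn)
    if len(xs) < 3:
        raise ValueError("need at least 3 usable measured/predicted pairs")
    x = np.array(xs)
    y = np.array(ys)
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(len(x) - 2, 1)
    se = float(np.sqrt(np.sum(resid ** 2) / dof))
    outliers = np.abs(resid) > z * se
    return {
        "slope": float(fit.slope), "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2), "se": se, "n": len(x),
        "outlier_vpns": [vpns[i] for i in np.nonzero(outliers)[0]],
        "outlier_fraction": float(outliers.mean()),
    }


# ---------------------------------------------------------------------------
# reconciliation


@dataclass
class CorrectionAction:
    """One correction: shift the association, drop a line, or drop the page."""

    page_id: tuple[int, int]
    action: str  # shift_association | remove_line | remove_page
    parameter: tuple[int, int] | int | None
    note: str = ""


def reconcile(flagged_pages: list[SyntheticPage]) -> list[CorrectionAction]:
    """Derive corrections from pages with known true associations.

    This is the "reviewer" for synthetic data: a page's recorded ground
    truth plays the role of the person re-inspecting the laminated page.
    Skipped-image pages shift later records one image back and drop the
    never-photographed line; duplicated-image pages shift forward and
    drop the line whose wing was displaced off the page.
    """
    log: list[CorrectionAction] = []
    for page in flagged_pages:
        if page.misalignment == "none":
            continue
        k = page.error_line
        n = page.n_lines
        if page.misalignment == "skipped_image":
            log.append(CorrectionAction(page.page_id, "remove_line", k,
                                        "wing never photographed"))
            if k + 1 < n:
                log.append(CorrectionAction(page.page_id, "shift_association",
                                            (k + 1, -1),
                                            "images lag records by one line"))
        elif page.misalignment == "duplicated_image":
            if k + 1 < n:
                log.append(CorrectionAction(page.page_id, "shift_association",
                                            (k + 1, +1),
                                            "images lead records by one line"))
            log.append(CorrectionAction(page.page_id, "remove_line", n - 1,
                                        "last wing displaced off the page"))
    return log


def apply_corrections(page_sizes: dict[tuple[int, int], int],
                      log: list[CorrectionAction]
                      ) -> dict[tuple[int, int], list[int | None]]:
    """Apply a correction log to identity associations.

    Returns, per page, the image line that holds each record's wing
    (None when the record's wing is gone). With an empty log the dataset
    is unchanged. Actions naming unknown pages are an error.
    """
    assoc = {pid: list(range(n)) for pid, n in page_sizes.items()}
    for act in log:
        if act.page_id not in assoc:
            raise ValueError(f"correction references unknown page {act.page_id}")
        table = assoc[act.page_id]
        if act.action == "remove_page":
            assoc[act.page_id] = [None] * len(table)
        elif act.action == "remove_line":
            table[int(act.parameter)] = None
        elif act.action == "shift_association":
            start, offset = act.parameter  # type: ignore[misc]
            n = len(table)
            for line in range(start, n):
                if table[line] is None:
                    continue
                target = table[line] + offset
                table[line] = target if 0 <= target < n else None
        else:
            raise ValueError(f"unknown correction action {act.action!r}")
    return assoc
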