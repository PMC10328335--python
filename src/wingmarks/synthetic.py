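"""Synthetic wing-image generator with known landmark ground truth.

Real wing photographs vary in size, rotation and location, differ in
brightness and contrast, and a minority are incomplete — most of those
missing landmark 4 or 6. This module emulates exactly that structure: a fixed
skeleton of quadratic Bezier "veins" whose pairwise intersections define
the 11 ordered landmarks, rendered onto a canvas under a sampled
similarity transform, with damage variants (occluded landmark 4 or 6,
tears and stains that leave all landmarks intact, absent wings) and
multi-wing pages with injected image-to-record misalignments.

The generator is deliberately non-photorealistic; it exists so that every
downstream stage — flipping, augmentation, both network heads, Procrustes
shape bias and page-level alignment QC — can be exercised end-to-end with
exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

from .io import (
    MM_PER_PIXEL,
    N_LANDMARKS,
    BioRecord,
    LandmarkSet,
    WingID,
    WingImage,
    write_bio_csv,
    write_image,
    write_landmark_csv,
)

__all__ = [
    "DAMAGE_MODES",
    "SyntheticWingSpec",
    "SyntheticPage",
    "PageLine",
    "GenerationError",
    "template_landmarks",
    "generate_wing",
    "sample_spec",
    "generate_training_set",
    "generate_page",
    "write_page",
]

DAMAGE_MODES = ("none", "missing_lm4", "missing_lm6", "torn", "stained", "absent_wing")

# Landmarks that, when damaged, make a wing "incomplete" for tier 1.
_INCOMPLETE_MODES = {"missing_lm4", "missing_lm6", "absent_wing"}

# ---------------------------------------------------------------------------
# Wing template: 11 landmarks in a unit frame, x rightward, y downward.
# Committed constants; the layout qualitatively follows a left wing with the
# base at small x, the tip (landmark 6) at large x, landmark 4 on the leading
# edge, and the hatchet cell spanned by landmarks 7 and 11.

_TEMPLATE = np.array([
    [0.08, 0.50],   # 1  wing base (length datum)
    [0.25, 0.38],   # 2
    [0.40, 0.32],   # 3
    [0.62, 0.28],   # 4  leading edge, damage-prone
    [0.80, 0.35],   # 5
    [0.92, 0.52],   # 6  wing tip (length datum), damage-prone
    [0.70, 0.60],   # 7  hatchet cell, anterior
    [0.52, 0.55],   # 8
    [0.35, 0.58],   # 9
    [0.20, 0.62],   # 10
    [0.55, 0.72],   # 11 hatchet cell, posterior
])

# Each vein is a quadratic Bezier forced through three landmarks
# (t = 0, 1/2, 1). Every landmark lies on >= 2 veins, so each is a true
# curve intersection. Indices are 0-based into _TEMPLATE.
_VEINS = (
    (0, 1, 3),    # costal, base to leading edge
    (3, 4, 5),    # leading edge to tip
    (0, 9, 10),   # trailing edge, base side
    (10, 6, 5),   # trailing edge to tip
    (1, 8, 9),    # cross vein
    (8, 7, 6),    # median vein to tip
    (1, 2, 4),    # upper medial vein
    (2, 7, 10),   # long diagonal vein
)

# Wing outline for the membrane fill (ordered landmark loop).
_OUTLINE = (0, 1, 3, 4, 5, 6, 10, 9, 8, 0)


class GenerationError(ValueError):
    """Raised when a spec places a required landmark outside the canvas."""


@dataclass
class SyntheticWingSpec:
    """Parameters of one synthetic wing.

    ``scale_factor`` is the wing span as a fraction of the canvas width,
    ``rotation`` in degrees about the canvas centre, ``shift`` in pixels,
    ``brightness`` the background level in [0, 1] and ``contrast`` the
    vein-to-background intensity drop in [0, 1].
    """

    canvas_height: int = 1024
    canvas_width: int = 1280
    scale_factor: float = 0.55
    rotation: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    vein_width: float = 4.0
    brightness: float = 0.8
    contrast: float = 0.6
    noise_sd: float = 0.02
    shape_sd: float = 0.01
    damage: str = "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_height < 64 or self.canvas_width < 64:
            raise ValueError("canvas must be at least 64 x 64")
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must be in (0, 1]")
        if self.damage not in DAMAGE_MODES:
            raise ValueError(f"unknown damage mode {self.damage!r}")


def template_landmarks() -> np.ndarray:
    """The 11 template landmark positions in the unit frame (copy)."""
    return _TEMPLATE.copy()


def _jittered_template(spec: SyntheticWingSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-wing shape: the template plus inter-individual landmark jitter.

    Drawn first from the spec's seed so the rendered and geometry-only
    paths agree exactly.
    """
    if spec.shape_sd <= 0:
        return _TEMPLATE.copy()
    return _TEMPLATE + rng.normal(0.0, spec.shape_sd, size=_TEMPLATE.shape)


def _transform(spec: SyntheticWingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform (A, t): unit template -> canvas pixels."""
    theta = np.deg2rad(spec.rotation)
    c, s = np.cos(theta), np.sin(theta)
    span = spec.scale_factor * spec.canvas_width
    rot = np.array([[c, -s], [s, c]])
    a = rot * span
    centre = np.array([(spec.canvas_width - 1) / 2.0, (spec.canvas_height - 1) / 2.0])
    t = centre + np.asarray(spec.shift, dtype=float)
    return a, t


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int = 160) -> np.ndarray:
    """Quadratic Bezier through p0, p1 (at t=1/2), p2."""
    ctrl = 2.0 * p1 - 0.5 * (p0 + p2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * ctrl + (t ** 2) * p2


def _rasterise_curves(points_list: list[np.ndarray], shape: tuple[int, int],
                      width: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for pts in points_list:
        ij = np.clip(np.round(pts[:, ::-1]).astype(int), 0, [h - 1, w - 1])
        for (r0, c0), (r1, c1) in zip(ij[:-1], ij[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    radius = max(1, int(round(width / 2.0)))
    return binary_dilation(mask, structure=disk_footprint(radius))


def _damage_anchor(landmarks: np.ndarray, span: float, mode: str,
                   rng: np.random.Generator) -> tuple[np.ndarray, float]:
    if mode in ("missing_lm4", "missing_lm6"):
        # gross occlusion: bright tape-glare patch swallowing the landmark
        idx = 3 if mode == "missing_lm4" else 5
        return landmarks[idx], max(10.0, 0.10 * span)
    if mode == "torn":
        # notch on the trailing edge between landmarks 9 and 10, clear of all
        centre = 0.5 * (landmarks[8] + landmarks[9]) + np.array([0.0, 0.05 * span])
        radius = 0.035 * span
    else:  # stained: interior blob near the wing centroid
        centre = landmarks.mean(axis=0) + rng.uniform(-0.02, 0.02, size=2) * span
        radius = 0.035 * span
    # shrink until no landmark is invalidated (torn/stained must stay benign)
    d = np.linalg.norm(landmarks - centre, axis=1).min()
    radius = min(radius, max(2.0, 0.7 * d))
    return centre, radius


def generate_wing(spec: SyntheticWingSpec
                  ) -> tuple[WingImage, LandmarkSet, int]:
    """Render one wing; return image, ground-truth landmarks and the tier-1 label.

    The completeness label is 1 for incomplete wings (damage removing
    landmark 4 or 6, or an absent wing) and 0 for complete wings — tears
    and stains count as defects within complete wings. Identical spec and
    seed reproduce the image bit-for-bit.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.canvas_height, spec.canvas_width
    template = _jittered_template(spec, rng)
    a, t = _transform(spec)
    landmarks = template @ a.T - (np.array([0.5, 0.5]) @ a.T) + t

    valid = np.ones(N_LANDMARKS, dtype=bool)
    if spec.damage == "missing_lm4":
        valid[3] = False
    elif spec.damage == "missing_lm6":
        valid[5] = False
    elif spec.damage == "absent_wing":
        valid[:] = False

    if spec.damage != "absent_wing":
        for i in range(N_LANDMARKS):
            if not valid[i]:
                continue
            x, y = landmarks[i]
            if not (0.0 < x < w - 1 and 0.0 < y < h - 1):
                raise GenerationError(
                    f"landmark {i + 1} falls outside the canvas at ({x:.1f}, {y:.1f})")

    image = np.full((h, w), spec.brightness, dtype=float)

    if spec.damage != "absent_wing":
        # membrane fill, slightly darker than background
        outline = np.vstack([
            _bezier(landmarks[i], 0.5 * (landmarks[i] + landmarks[j]), landmarks[j], 24)
            for i, j in zip(_OUTLINE[:-1], _OUTLINE[1:])])
        rr, cc = draw_polygon(np.clip(outline[:, 1], 0, h - 1),
                              np.clip(outline[:, 0], 0, w - 1), shape=(h, w))
        image[rr, cc] = np.clip(spec.brightness - 0.15 * spec.contrast, 0.0, 1.0)

        curves = [_bezier(landmarks[i], landmarks[j], landmarks[k])
                  for i, j, k in _VEINS]
        veins = _rasterise_curves(curves, (h, w), spec.vein_width)
        image[veins] = np.clip(spec.brightness - spec.contrast, 0.0, 1.0)

        if spec.damage in ("missing_lm4", "missing_lm6", "torn", "stained"):
            span = spec.scale_factor * w
            centre, radius = _damage_anchor(landmarks, span, spec.damage, rng)
            rr, cc = draw_disk((centre[1], centre[0]), radius, shape=(h, w))
            # occluders (tape/ink) are bright; stains are dark blots
            image[rr, cc] = 0.08 if spec.damage == "stained" else 1.0

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    label = 1 if spec.damage in _INCOMPLETE_MODES else 0
    return WingImage(image), LandmarkSet(landmarks, valid), label


def sample_spec(rng: np.random.Generator, *,
                canvas: tuple[int, int] = (1024, 1280),
                damage: str = "none") -> SyntheticWingSpec:
    """Draw one wing spec from the generator's default variation model.

    Wings vary in size (span 45–65% of canvas width), rotation (±15°),
    position (±8% shift per axis) and photometry — the variation the
    classifier and landmark heads must tolerate.
    """
    h, w = canvas
    return SyntheticWingSpec(
        canvas_height=h, canvas_width=w,
        scale_factor=float(rng.uniform(0.45, 0.65)),
        rotation=float(rng.uniform(-15.0, 15.0)),
        shift=(float(rng.uniform(-0.08, 0.08) * w), float(rng.uniform(-0.08, 0.08) * h)),
        vein_width=max(2.0, w / 320.0),
        brightness=float(rng.uniform(0.72, 0.88)),
        contrast=float(rng.uniform(0.5, 0.7)),
        noise_sd=0.02,
        damage=damage,
        rng_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_training_set(n: int, *, incomplete_fraction: float = 0.5,
                          rng_seed: int = 0,
                          canvas: tuple[int, int] = (1024, 1280)
                          ) -> list[tuple[WingImage, LandmarkSet, int]]:
    """A labelled wing batch with the requested incomplete fraction.

    Incomplete wings are split evenly between missing landmark 4 and 6;
    complete wings include a 10% share of benign tears/stains, mirroring
    the "defects within complete wings" category.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        if rng.uniform() < incomplete_fraction:
            damage = "missing_lm4" if rng.uniform() < 0.5 else "missing_lm6"
        elif rng.uniform() < 0.10:
            damage = "torn" if rng.uniform() < 0.5 else "stained"
        else:
            damage = "none"
        out.append(generate_wing(sample_spec(rng, canvas=canvas, damage=damage)))
    return out


# ---------------------------------------------------------------------------
# pages and misalignment injection


@dataclass
class PageLine:
    """One line of a page: the fly's record plus its true (left-oriented) wing."""

    record: BioRecord
    landmarks: LandmarkSet
    spec: SyntheticWingSpec
    true_length_mm: float = 0.0


@dataclass
class SyntheticPage:
    """<= 20 wing pairs with a known image-to-record association.

    ``association[i]`` is the line whose wing the images *named* line i
    actually show (None when that name was never photographed). Under
    ``skipped_image`` every name from ``error_line`` on shows the wing of
    the following line (one step behind); under ``duplicated_image`` the
    names at ``error_line`` and ``error_line``+1 show the same wing and
    the association is one step ahead thereafter.
    """

    page_id: tuple[int, int]
    lines: list[PageLine]
    misalignment: str = "none"
    error_line: int | None = None
    association: list[int | None] = field(default_factory=list)
    images: dict[str, WingImage] = field(default_factory=dict)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def shown_line(self, line: int) -> int | None:
        return self.association[line]

    def image_names(self) -> list[str]:
        vol, page = self.page_id
        names = []
        for i, shown in enumerate(self.association):
            if shown is None:
                continue
            for side in ("L", "R"):
                names.append(str(WingID(vol, page, i + 1, side)))
        return names


def _association(n_lines: int, misalignment: str, error_line: int | None
                 ) -> list[int | None]:
    assoc: list[int | None] = list(range(n_lines))
    if misalignment == "none":
        return assoc
    if error_line is None or not 0 <= error_line < n_lines:
        raise ValueError("error_line must be in [0, n_lines) for misaligned pages")
    if misalignment == "skipped_image":
        for i in range(error_line, n_lines):
            assoc[i] = i + 1 if i + 1 < n_lines else None
    elif misalignment == "duplicated_image":
        for i in range(error_line + 1, n_lines):
            assoc[i] = i - 1
    else:
        raise ValueError(f"unknown misalignment mode {misalignment!r}")
    return assoc


def generate_page(n_lines: int, misalignment: str = "none",
                  error_line: int | None = None, rng_seed: int = 0, *,
                  page_id: tuple[int, int] = (20, 1),
                  canvas: tuple[int, int] = (1024, 1280),
                  wlm_noise_sd: float = 0.02,
                  render: bool = False) -> SyntheticPage:
    """Generate one page of wing pairs with an optional injected misalignment.

    Each record's true wlm is 0.007 mm/px times the landmark-1-to-6
    distance of that line's true wing, plus Gaussian dissector noise
    (default SD 0.02 mm). With ``render=True`` the page also carries the
    actual images under their (possibly misassociated) names; left and
    right images of a line are mirror twins.
    """
    if not 1 <= n_lines <= 20:
        raise ValueError("a page holds between 1 and 20 wing pairs")
    rng = np.random.default_rng(rng_seed)
    vol, pageno = page_id

    lines = []
    for i in range(n_lines):
        spec = sample_spec(rng, canvas=canvas)
        landmarks, _ = _geometry(spec)
        true_len = MM_PER_PIXEL * float(
            np.linalg.norm(landmarks.point(1) - landmarks.point(6)))
        wlm = true_len + float(rng.normal(0.0, wlm_noise_sd)) if wlm_noise_sd > 0 \
            else true_len
        record = BioRecord((vol, pageno, i + 1), max(wlm, 1e-6))
        lines.append(PageLine(record, landmarks, spec, true_len))

    assoc = _association(n_lines, misalignment, error_line)
    page = SyntheticPage(page_id, lines, misalignment,
                         error_line if misalignment != "none" else None, assoc)

    if render:
        for i, shown in enumerate(assoc):
            if shown is None:
                continue
            spec = lines[shown].spec
            img, _, _ = generate_wing(spec)
            left = WingImage(img.pixels, WingID(vol, pageno, i + 1, "L"))
            right = WingImage(img.pixels[:, ::-1].copy(),
                              WingID(vol, pageno, i + 1, "R"))
            page.images[str(left.id)] = left
            page.images[str(right.id)] = right
    return page


def _geometry(spec: SyntheticWingSpec) -> tuple[LandmarkSet, int]:
    """Landmarks and label without rasterising pixels (fast path for pages)."""
    rng = np.random.default_rng(spec.rng_seed)
    template = _jittered_template(spec, rng)
    a, t = _transform(spec)
    landmarks = template @ a.T - (np.array([0.5, 0.5]) @ a.T) + t
    valid = np.ones(N_LANDMARKS, dtype=bool)
    if spec.damage == "missing_lm4":
        valid[3] = False
    elif spec.damage == "missing_lm6":
        valid[5] = False
    elif spec.damage == "absent_wing":
        valid[:] = False
    label = 1 if spec.damage in _INCOMPLETE_MODES else 0
    return LandmarkSet(landmarks, valid), label


def write_page(page: SyntheticPage, out_dir: str | Path) -> None:
    """Write a rendered page: PNGs, landmark and bio CSVs, manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, image in page.images.items():
        write_image(image, out_dir / f"{name}.png")
    truth = {}
    for i, shown in enumerate(page.association):
        if shown is None:
            continue
        vol, pageno = page.page_id
        lm = page.lines[shown].landmarks
        truth[str(WingID(vol, pageno, i + 1, "L"))] = lm
        mirrored = lm.copy()
        mirrored.points[:, 0] = (page.lines[shown].spec.canvas_width - 1) \
            - mirrored.points[:, 0]
        truth[str(WingID(vol, pageno, i + 1, "R"))] = mirrored
    write_landmark_csv(truth, out_dir / "landmarks.csv")
    write_bio_csv([ln.record for ln in page.lines], out_dir / "bio.csv")
    manifest = {
        "page_id": list(page.page_id),
        "misalignment": page.misalignment,
        "error_line": page.error_line,
        "association": page.association,
        "specs": [ln.spec.__dict__ | {"shift": list(ln.spec.shift)}
                  for ln in page.lines],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
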