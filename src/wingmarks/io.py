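"""Dataset model for wing images and biological records.

Images are named by a volume/page/line/side convention (``V20P076L08R`` =
volume 20, page 76, line 8, right wing). Each wing carries 11 anatomical
landmarks — vein-intersection points numbered 1–11 — stored 0-based as
(x, y) = (column, row) in the native image space (1024 x 1280 by default).
The dissector-measured wing length ``wlm`` is the landmark-1-to-landmark-6
distance in millimetres; each pixel spans approximately 0.007 mm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MM_PER_PIXEL",
    "N_LANDMARKS",
    "WingID",
    "WingImage",
    "LandmarkSet",
    "BioRecord",
    "flip_to_left",
    "wing_length_mm",
    "join_records",
    "read_image",
    "write_image",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_bio_csv",
    "write_bio_csv",
]

MM_PER_PIXEL = 0.007
N_LANDMARKS = 11
NATIVE_SIZE = (1024, 1280)  # (H, W)

_NAME_RE = re.compile(r"^V(\d+)P(\d+)L(\d+)([LR])$")


@dataclass(frozen=True, order=True)
class WingID:
    """Identity of one wing image: volume, page, line and side."""

    volume: int
    page: int
    line: int
    side: str  # "L" or "R"

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    def __str__(self) -> str:
        return f"V{self.volume:02d}P{self.page:03d}L{self.line:02d}{self.side}"

    @classmethod
    def parse(cls, name: str) -> "WingID":
        m = _NAME_RE.match(name)
        if m is None:
            raise ValueError(f"not a wing image name: {name!r}")
        return cls(int(m.group(1)), int(m.group(2)), int(m.group(3)), m.group(4))

    @property
    def vpn(self) -> tuple[int, int, int]:
        """(volume, page, number) key linking the image to its biological record."""
        return (self.volume, self.page, self.line)


@dataclass
class WingImage:
    """Pixel grid plus identity; grayscale (H, W) or RGB (H, W, 3), float in [0, 1]."""

    pixels: np.ndarray
    id: WingID | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be (H, W) or (H, W, 3) with H, W >= 1")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class LandmarkSet:
    """11 ordered landmark coordinates in native pixel space.

    ``points`` is an (11, 2) array of (x, y) with x = column and y = row,
    0-based. ``valid`` marks landmarks whose ground truth is usable; a
    damaged or absent landmark keeps its slot but is flagged invalid so
    the 1–11 ordering is never disturbed.
    """

    points: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self.points = pts
        if self.valid is None:
            self.valid = np.ones(N_LANDMARKS, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (N_LANDMARKS,):
                raise ValueError("valid mask must have 11 entries")

    def point(self, index1: int) -> np.ndarray:
        """Landmark by its 1-based anatomical number (display convention)."""
        if not 1 <= index1 <= N_LANDMARKS:
            raise ValueError(f"landmark number must be 1..{N_LANDMARKS}")
        return self.points[index1 - 1]

    def in_frame(self, size: tuple[int, int]) -> np.ndarray:
        h, w = size
        x, y = self.points[:, 0], self.points[:, 1]
        return (x >= 0) & (x < w) & (y >= 0) & (y < h)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.points.copy(), self.valid.copy())


@dataclass
class BioRecord:
    """One dissection-lab line: vpn key, measured wing length and damage counts.

    ``exclude_length`` flags records whose wlm is not the landmark-1-to-6
    measurement (e.g. hatchet-cell measurements); the identification rule
    for such cases lives upstream, this is only the carrier flag.
    """

    vpn: tuple[int, int, int]
    wlm: float | None
    lmkl: int = 0
    lmkr: int = 0
    exclude_length: bool = False

    def __post_init__(self) -> None:
        if self.wlm is not None and not (self.wlm > 0):
            raise ValueError("wlm must be positive when present")
        for v in (self.lmkl, self.lmkr):
            if not 0 <= v <= N_LANDMARKS:
                raise ValueError("landmark-missing counts must be in [0, 11]")


def flip_to_left(image: WingImage,
                 landmarks: LandmarkSet | None = None
                 ) -> tuple[WingImage, LandmarkSet | None]:
    """Mirror a right-wing image horizontally so all wings share one chirality.

    Pixel columns are reversed and each landmark x maps to W - 1 - x
    (0-based); the 1–11 ordering is untouched. Left wings pass through
    unchanged. Involution: applying the flip twice is the identity.
    """
    if image.id is not None and image.id.side == "L":
        return image, landmarks
    w = image.pixels.shape[1]
    flipped = WingImage(image.pixels[:, ::-1].copy(), image.id)
    if landmarks is None:
        return flipped, None
    out = landmarks.copy()
    out.points[:, 0] = (w - 1) - out.points[:, 0]
    return flipped, out


def wing_length_mm(landmarks: LandmarkSet, scale: float = MM_PER_PIXEL,
                   pair: tuple[int, int] = (1, 6)) -> float:
    """Wing length in mm: scaled Euclidean distance between two landmarks.

    The standard measure uses landmarks 1 and 6; the hatchet-cell variant
    uses landmarks 7 and 11 (``pair=(7, 11)``).
    """
    a, b = pair
    for idx in (a, b):
        if not landmarks.valid[idx - 1]:
            raise ValueError(f"landmark {idx} is flagged invalid")
    return scale * float(np.linalg.norm(landmarks.point(a) - landmarks.point(b)))


def join_records(images: list[WingID], records: list[BioRecord]) -> dict:
    """Associate wing images with biological records by (volume, page, line).

    Each image is keyed to at most one record. Returns a dict with a
    ``matched`` DataFrame (name, volume, page, line, side, wlm, lmkl,
    lmkr, exclude_length), plus ``unmatched_images`` and
    ``unmatched_records`` lists. Duplicate image names are an error.
    """
    seen: dict[str, int] = {}
    dups = []
    for wid in images:
        key = str(wid)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            dups.append(key)
    if dups:
        raise ValueError(f"duplicate wing image names: {sorted(dups)}")

    by_vpn = {rec.vpn: rec for rec in records}
    rows = []
    matched_vpns = set()
    unmatched_images = []
    for wid in images:
        rec = by_vpn.get(wid.vpn)
        if rec is None:
            unmatched_images.append(wid)
            continue
        matched_vpns.add(wid.vpn)
        rows.append({
            "name": str(wid), "volume": wid.volume, "page": wid.page,
            "line": wid.line, "side": wid.side, "wlm": rec.wlm,
            "lmkl": rec.lmkl, "lmkr": rec.lmkr,
            "exclude_length": rec.exclude_length,
        })
    unmatched_records = [r for r in records if r.vpn not in matched_vpns]
    matched = pd.DataFrame(rows, columns=["name", "volume", "page", "line", "side",
                                          "wlm", "lmkl", "lmkr", "exclude_length"])
    return {"matched": matched,
            "unmatched_images": unmatched_images,
            "unmatched_records": unmatched_records}


# ---------------------------------------------------------------------------
# file formats


def read_image(path: str | Path) -> WingImage:
    """Read PNG/TIFF/JPEG into a float [0, 1] WingImage; name parsed if it fits."""
    path = Path(path)
    px = np.asarray(iio.imread(path), dtype=float)
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    if px.max() > 1.0:
        px = px / 255.0
    try:
        wid = WingID.parse(path.stem)
    except ValueError:
        wid = None
    return WingImage(px, wid)


def write_image(image: WingImage, path: str | Path) -> None:
    px = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), (px * 255.0 + 0.5).astype(np.uint8))


def _landmark_columns() -> list[str]:
    return ([f"x{i}" for i in range(1, N_LANDMARKS + 1)]
            + [f"y{i}" for i in range(1, N_LANDMARKS + 1)])


def write_landmark_csv(landmarks: dict[str, LandmarkSet], path: str | Path) -> None:
    """Write landmark tables as (name, x1..x11, y1..y11); invalid points as NaN."""
    rows = []
    for name, lms in landmarks.items():
        pts = lms.points.copy()
        pts[~lms.valid] = np.nan
        row = {"name": name}
        for i in range(N_LANDMARKS):
            row[f"x{i + 1}"] = pts[i, 0]
            row[f"y{i + 1}"] = pts[i, 1]
        rows.append(row)
    pd.DataFrame(rows, columns=["name"] + _landmark_columns()).to_csv(path, index=False)


def read_landmark_csv(path: str | Path) -> dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    out: dict[str, LandmarkSet] = {}
    for _, row in df.iterrows():
        pts = np.zeros((N_LANDMARKS, 2))
        valid = np.ones(N_LANDMARKS, dtype=bool)
        for i in range(N_LANDMARKS):
            x, y = row[f"x{i + 1}"], row[f"y{i + 1}"]
            if pd.isna(x) or pd.isna(y):
                valid[i] = False
            else:
                pts[i] = (float(x), float(y))
        out[str(row["name"])] = LandmarkSet(pts, valid)
    return out


def _vpn_str(vpn: tuple[int, int, int]) -> str:
    return f"V{vpn[0]:02d}P{vpn[1]:03d}N{vpn[2]:02d}"


def _parse_vpn(s: str) -> tuple[int, int, int]:
    m = re.match(r"^V(\d+)P(\d+)N(\d+)$", s)
    if m is None:
        raise ValueError(f"not a vpn key: {s!r}")
    return (int(m.group(1)), int(m.group(2)), int(m.group(3)))


def write_bio_csv(records: list[BioRecord], path: str | Path) -> None:
    """Biological table with wlm rounded to 3 decimals (0.001 mm precision)."""
    rows = [{
        "vpn": _vpn_str(r.vpn),
        "wlm": "" if r.wlm is None else f"{r.wlm:.3f}",
        "lmkl": r.lmkl, "lmkr": r.lmkr,
        "exclude_length": int(r.exclude_length),
    } for r in records]
    pd.DataFrame(rows, columns=["vpn", "wlm", "lmkl", "lmkr",
                                "exclude_length"]).to_csv(path, index=False)


def read_bio_csv(path: str | Path) -> list[BioRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        wlm = None if pd.isna(row["wlm"]) else float(row["wlm"])
        excl = bool(int(row["exclude_length"])) if "exclude_length" in df.columns else False
        out.append(BioRecord(_parse_vpn(str(row["vpn"])), wlm,
                             int(row["lmkl"]), int(row["lmkr"]), excl))
    return out
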