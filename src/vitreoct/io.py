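"""Reading B-scan series, scan calibration, and tabular output.

An eye's OCT acquisition arrives either as an AVI video (the export format
of the Spectralis device) or as a directory of numbered PNG/TIFF frames,
one frame per B-scan.  Everything downstream works on calibrated 8-bit
grayscale images.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from . import avi as _avi
from .exceptions import FormatError

__all__ = [
    "Calibration",
    "BScan",
    "EyeScanSeries",
    "default_calibration",
    "to_grayscale",
    "read_series",
    "write_opacity_table",
    "write_summary_table",
]

SIDES = ("RE", "LE")
GROUPS = ("MEPI", "Ms", "control")
SEXES = ("male", "female")
WEEKS = (0, 2, 4, 6, 8, 12, 18, 24)

#: BT.601 luminance weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Default scan geometry: 1536 x 496 px covering 3 mm x 0.969 mm.
DEFAULT_WIDTH_PX = 1536
DEFAULT_HEIGHT_PX = 496
DEFAULT_WIDTH_MM = 3.0
DEFAULT_HEIGHT_MM = 0.969


@dataclass(frozen=True)
class Calibration:
    """Physical pixel pitch of a B-scan.

    ``pixel_area_um2`` follows the square-pixel convention (lateral pitch
    squared), which reproduces the 3.815 um^2/px of the default geometry;
    pass ``square_pixels=False`` to :func:`default_calibration` for the
    lateral x axial alternative.
    """

    lateral_um_per_px: float
    axial_um_per_px: float
    pixel_area_um2: float

    def __post_init__(self) -> None:
        for name in ("lateral_um_per_px", "axial_um_per_px", "pixel_area_um2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Calibration.{name} must be strictly positive")


def default_calibration(
    width_px: int = DEFAULT_WIDTH_PX,
    height_px: int = DEFAULT_HEIGHT_PX,
    width_mm: float = DEFAULT_WIDTH_MM,
    height_mm: float = DEFAULT_HEIGHT_MM,
    square_pixels: bool = True,
) -> Calibration:
    """Calibration from the scan geometry (pixel grid and field of view)."""
    if not (width_px > 0 and height_px > 0 and width_mm > 0 and height_mm > 0):
        raise ValueError("scan geometry arguments must all be strictly positive")
    lateral = 1000.0 * width_mm / width_px
    axial = 1000.0 * height_mm / height_px
    area = lateral**2 if square_pixels else lateral * axial
    return Calibration(lateral, axial, area)


@dataclass(frozen=True)
class BScan:
    """One calibrated 2-D grayscale cross-sectional image."""

    pixels: np.ndarray
    index: int
    calibration: Calibration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError(f"BScan pixels must be a nonempty 2-D array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("BScan intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class EyeScanSeries:
    """An eye's B-scan stack plus its cohort metadata."""

    animal_id: str
    side: str
    group: str
    sex: str
    week: int
    bscans: list[BScan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.week not in WEEKS:
            raise ValueError(f"week must be one of {WEEKS}, got {self.week!r}")
        shapes = {b.shape for b in self.bscans}
        if len(shapes) > 1:
            raise FormatError(f"all B-scans of a series must share one shape, got {shapes}")
        calibs = {b.calibration for b in self.bscans}
        if len(calibs) > 1:
            raise FormatError("all B-scans of a series must share one calibration")

    def __len__(self) -> int:
        return len(self.bscans)

    def metadata_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "side": self.side,
            "group": self.group,
            "sex": self.sex,
            "week": self.week,
        }


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion of an RGB frame, rounded and clipped to uint8.

    Already-gray 2-D frames pass through unchanged (the weights sum to 1, so
    the conversion is the identity on equal channels).
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[-1] == 4:  # tolerate RGBA from PNG readers
        frame = frame[..., :3]
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise FormatError(f"expected a 2-D gray or (h,w,3) RGB frame, got shape {frame.shape}")
    if frame.min() < 0 or frame.max() > 255:
        raise FormatError("channel values must lie in [0, 255]")
    lum = frame.astype(np.float64) @ np.asarray(GRAY_WEIGHTS)
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}
_NUM_RE = re.compile(r"(\d+)")


def _frame_sort_key(p: Path):
    m = _NUM_RE.findall(p.stem)
    return (int(m[-1]) if m else -1, p.name)


def read_series(
    path: str | Path,
    metadata: dict,
    calibration: Calibration | None = None,
) -> EyeScanSeries:
    """Read an eye's B-scan series from an AVI file or an image-stack directory.

    ``metadata`` supplies ``animal_id``, ``side``, ``group``, ``sex`` and
    ``week``.  Frames are grayscale-converted if they arrive as RGB and are
    ordered by frame index (AVI) or by the trailing number in the file name
    (image stacks).
    """
    path = Path(path)
    calibration = calibration or default_calibration()
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES),
            key=_frame_sort_key,
        )
        if not files:
            raise FormatError(f"{path}: no PNG/TIFF frames found")
        frames = [iio.imread(p) for p in files]
    elif path.suffix.lower() == ".avi":
        frames = list(_avi.read_avi(path))
    elif path.is_file():
        raise FormatError(f"{path}: expected an .avi file or a frame directory")
    else:
        raise FileNotFoundError(path)

    gray = [to_grayscale(f) for f in frames]
    shapes = {g.shape for g in gray}
    if len(shapes) > 1:
        raise FormatError(f"{path}: inconsistent frame sizes {sorted(shapes)}")
    bscans = [BScan(g, i, calibration) for i, g in enumerate(gray)]
    return EyeScanSeries(bscans=bscans, **metadata)


OPACITY_COLUMNS = [
    "animal_id", "side", "group", "sex", "week",
    "bscan_index", "label", "n_pixels", "area_um2", "mean_intensity",
    "eccentricity", "orientation_deg", "size_class",
]

_CLASS_FIELDS = ["count", "pct", "mean_area_um2", "mean_intensity",
                 "mean_eccentricity", "mean_orientation_deg"]
_CLASS_NAMES = ["isolated", "non_activated", "activated", "complex"]

SUMMARY_COLUMNS = (
    ["animal_id", "side", "group", "sex", "week",
     "n_bscans", "vit_rpe_intensity", "mean_n_opacities",
     "n_opacities", "total_area_um2"]
    + [f"{c}_{f}" for c in _CLASS_NAMES for f in _CLASS_FIELDS]
)


def _write_csv(rows: list[dict], columns: Sequence[str], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False, lineterminator="\n")


def write_opacity_table(opacities: Iterable, path: str | Path, series: EyeScanSeries | None = None) -> None:
    """One CSV row per detected opacity; columns in :data:`OPACITY_COLUMNS` order."""
    meta = series.metadata_row() if series is not None else {}
    rows = []
    for op in opacities:
        row = dict(meta)
        if isinstance(op, dict):
            row.update(op)
        else:
            for col in OPACITY_COLUMNS[5:]:
                row[col] = getattr(op, col)
            sc = row["size_class"]
            row["size_class"] = getattr(sc, "value", sc)
        rows.append(row)
    _write_csv(rows, OPACITY_COLUMNS, path)


def write_summary_table(summaries: Iterable, path: str | Path) -> None:
    """One CSV row per eye x week; columns in :data:`SUMMARY_COLUMNS` order."""
    rows = [s if isinstance(s, dict) else s.to_row() for s in summaries]
    _write_csv(rows, SUMMARY_COLUMNS, path)


def downscale_calibration(calibration: Calibration, factor: int) -> Calibration:
    """Calibration for an image downscaled by an integer factor per axis."""
    return replace(
        calibration,
        lateral_um_per_px=calibration.lateral_um_per_px * factor,
        axial_um_per_px=calibration.axial_um_per_px * factor,
        pixel_area_um2=calibration.pixel_area_um2 * factor**2,
    )
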