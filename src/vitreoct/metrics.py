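"""VIT/RPE relative intensity, soma-size classes and per-eye summaries.

The VIT/RPE relative intensity — mean vitreous intensity divided by mean
RPE intensity — is the turbidity proxy of the analysis; per eye it is the
arithmetic mean over the series' B-scans.  Detected opacities are binned by
equivalent soma area into four activation classes: isolated (<10 um^2),
non-activated ([10, 50) um^2), activated ([50, 250] um^2) and cell
complexes (>250 um^2).  The class intervals partition the positive reals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ComputationError
from .io import SUMMARY_COLUMNS, BScan, EyeScanSeries
from .segmentation import RegionMasks

__all__ = [
    "SizeClass",
    "ClassStats",
    "EyeSummary",
    "classify_size",
    "vit_rpe_relative_intensity",
    "eye_relative_intensity",
    "summarize_eye",
]


class SizeClass(enum.Enum):
    ISOLATED = "isolated"
    NON_ACTIVATED = "non_activated"
    ACTIVATED = "activated"
    COMPLEX = "complex"


#: (lower, upper) um^2 boundaries between consecutive classes.
DEFAULT_CLASS_BOUNDS = (10.0, 50.0, 250.0)


def classify_size(area_um2: float, bounds: Sequence[float] = DEFAULT_CLASS_BOUNDS) -> SizeClass:
    """Map a positive soma area to its activation class.

    Boundary convention: [10, 50) non-activated, [50, 250] activated,
    (250, inf) complexes — every positive area belongs to exactly one class.
    """
    if not area_um2 > 0:
        raise ValueError(f"area must be strictly positive, got {area_um2}")
    b1, b2, b3 = bounds
    if area_um2 < b1:
        return SizeClass.ISOLATED
    if area_um2 < b2:
        return SizeClass.NON_ACTIVATED
    if area_um2 <= b3:
        return SizeClass.ACTIVATED
    return SizeClass.COMPLEX


def vit_rpe_relative_intensity(bscan, masks: RegionMasks) -> float:
    """Mean grayscale over the vitreous mask divided by the mean over the RPE mask."""
    img = (bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan)).astype(np.float64)
    if not masks.vitreous.any():
        raise ComputationError("empty vitreous mask")
    if not masks.rpe.any():
        raise ComputationError("empty RPE mask")
    rpe_mean = img[masks.rpe].mean()
    if rpe_mean == 0:
        raise ComputationError("zero RPE mean intensity")
    return float(img[masks.vitreous].mean() / rpe_mean)


def eye_relative_intensity(ratios: Sequence[float]) -> float:
    """Per-eye VIT/RPE relative intensity: the mean of the per-B-scan ratios."""
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.size == 0:
        raise ValueError("need at least one per-B-scan ratio")
    return float(ratios.mean())


@dataclass(frozen=True)
class ClassStats:
    count: int
    pct: float | None
    mean_area_um2: float | None
    mean_intensity: float | None
    mean_eccentricity: float | None
    mean_orientation_deg: float | None


@dataclass(frozen=True)
class EyeSummary:
    """Per-eye pooled morphometry over all B-scans of a series."""

    animal_id: str
    side: str
    group: str
    sex: str
    week: int
    n_bscans: int
    vit_rpe_intensity: float | None
    mean_n_opacities: float
    n_opacities: int
    total_area_um2: float
    class_stats: dict[SizeClass, ClassStats]

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "side": self.side,
            "group": self.group,
            "sex": self.sex,
            "week": self.week,
            "n_bscans": self.n_bscans,
            "vit_rpe_intensity": self.vit_rpe_intensity,
            "mean_n_opacities": self.mean_n_opacities,
            "n_opacities": self.n_opacities,
            "total_area_um2": self.total_area_um2,
        }
        for cls in SizeClass:
            st = self.class_stats[cls]
            row[f"{cls.value}_count"] = st.count
            row[f"{cls.value}_pct"] = st.pct
            row[f"{cls.value}_mean_area_um2"] = st.mean_area_um2
            row[f"{cls.value}_mean_intensity"] = st.mean_intensity
            row[f"{cls.value}_mean_eccentricity"] = st.mean_eccentricity
            row[f"{cls.value}_mean_orientation_deg"] = st.mean_orientation_deg
        assert set(row) == set(SUMMARY_COLUMNS)
        return row


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def summarize_eye(
    series: EyeScanSeries,
    opacities: Iterable,
    bscan_ratios: Sequence[float] | None = None,
    circular_orientation: bool = False,
) -> EyeSummary:
    """Pool an eye's opacities over its B-scans into an :class:`EyeSummary`.

    ``opacities`` are the detected records of the whole series (each with
    ``area_um2``, ``mean_intensity``, ``eccentricity``, ``orientation_deg``
    and ``size_class``).  Per-class means of an empty class are reported as
    missing.  Mean orientation is the arithmetic mean of signed degrees so
    that opposed orientations cancel toward zero; pass
    ``circular_orientation=True`` for the axial circular mean instead.
    """
    opacities = list(opacities)
    n_bscans = len(series)
    by_class: dict[SizeClass, list] = {cls: [] for cls in SizeClass}
    for op in opacities:
        cls = op.size_class if isinstance(op.size_class, SizeClass) else SizeClass(op.size_class)
        by_class[cls].append(op)
    total = len(opacities)
    stats = {}
    for cls, ops in by_class.items():
        if circular_orientation and ops:
            # axial data: angles are defined modulo 180 degrees
            ang = np.deg2rad([2 * op.orientation_deg for op in ops])
            mean_orient = float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) / 2)
        else:
            mean_orient = _mean_or_none([op.orientation_deg for op in ops])
        stats[cls] = ClassStats(
            count=len(ops),
            pct=(100.0 * len(ops) / total) if total else None,
            mean_area_um2=_mean_or_none([op.area_um2 for op in ops]),
            mean_intensity=_mean_or_none([op.mean_intensity for op in ops]),
            mean_eccentricity=_mean_or_none([op.eccentricity for op in ops]),
            mean_orientation_deg=mean_orient,
        )
    return EyeSummary(
        animal_id=series.animal_id,
        side=series.side,
        group=series.group,
        sex=series.sex,
        week=series.week,
        n_bscans=n_bscans,
        vit_rpe_intensity=(eye_relative_intensity(bscan_ratios) if bscan_ratios is not None else None),
        mean_n_opacities=total / n_bscans if n_bscans else 0.0,
        n_opacities=total,
        total_area_um2=float(sum(op.area_um2 for op in opacities)),
        class_stats=stats,
    )
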