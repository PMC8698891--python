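"""Per-column ILM and RPE-band segmentation of a B-scan.

The ILM is located as the onset of the dominant super-threshold run in each
A-scan (column): intensities are median-smoothed axially, a background
threshold ``mean + k*SD`` is estimated from the top rows (vitreous), and the
longest run of consecutive super-threshold samples marks the retina; its
first row is the ILM.  Using the longest run rather than the first crossing
makes the boundary robust to bright opacities floating in the vitreous.
The RPE is the brightest band below the ILM; its inner/outer boundaries are
where the smoothed intensity falls below half the peak above background.
Failed columns are filled by linear interpolation and all boundary curves
are median-filtered across columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import SegmentationError
from .io import BScan

__all__ = [
    "SegmentationParams",
    "LayerBoundaries",
    "RegionMasks",
    "find_ilm",
    "find_rpe_band",
    "build_masks",
    "segment",
]

_VERTICAL = np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters (pixel units).

    ``smooth_axial``: axial median-filter window; ``k_sigma``: threshold is
    background mean + k_sigma * background SD; ``min_run``: consecutive
    super-threshold samples required; ``guard_px``: offset below the ILM
    before the RPE peak search starts; ``median_width``: across-column
    median filter for the boundary curves; ``background_rows``: top rows
    used for the background estimate (default: height // 8).
    """

    smooth_axial: int = 5
    k_sigma: float = 3.0
    min_run: int = 3
    guard_px: int = 20
    median_width: int = 15
    background_rows: int | None = None
    strategy: str = "longest"  # or "first"


@dataclass(frozen=True)
class LayerBoundaries:
    ilm: np.ndarray
    rpe_inner: np.ndarray
    rpe_outer: np.ndarray

    def __post_init__(self) -> None:
        ok = (
            (0 <= self.ilm)
            & (self.ilm < self.rpe_inner)
            & (self.rpe_inner <= self.rpe_outer)
        )
        if not np.all(ok):
            raise SegmentationError("boundary ordering 0 <= ilm < rpe_inner <= rpe_outer violated")


@dataclass(frozen=True)
class RegionMasks:
    vitreous: np.ndarray
    rpe: np.ndarray


def _image_of(bscan) -> np.ndarray:
    px = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan)
    return px.astype(np.float64)


def _background(img: np.ndarray, params: SegmentationParams) -> tuple[float, float]:
    """Robust background level/spread from the top rows (vitreous).

    Median and scaled MAD rather than mean/SD: bright opacities floating in
    the vitreous must not inflate the background estimate.
    """
    n = params.background_rows or max(img.shape[0] // 8, 2)
    top = img[:n]
    med = float(np.median(top))
    mad = float(np.median(np.abs(top - med)))
    return med, 1.4826 * mad


def _smooth(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.smooth_axial <= 1:
        return img
    return ndimage.median_filter(img, size=(params.smooth_axial, 1), mode="nearest")


def _fill_and_median(curve: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Interpolate failed (NaN) columns, then median-filter across columns."""
    w = curve.size
    valid = ~np.isnan(curve)
    if not valid.any():
        raise SegmentationError("segmentation failed in every column")
    if not valid.all():
        x = np.arange(w)
        curve = np.interp(x, x[valid], curve[valid])
    if params.median_width > 1:
        curve = ndimage.median_filter(curve, size=params.median_width, mode="nearest")
    return np.rint(curve).astype(int)


def _column_runs(above: np.ndarray, min_run: int):
    """Label vertical runs of True; return (labels, first_row, size, col) per run."""
    labels, n = ndimage.label(above, structure=_VERTICAL)
    if n == 0:
        return labels, np.empty(0, int), np.empty(0, int), np.empty(0, int)
    rows, cols = np.nonzero(labels)
    ids = labels[rows, cols]
    sizes = np.bincount(ids, minlength=n + 1)[1:]
    first = np.full(n, above.shape[0], dtype=int)
    np.minimum.at(first, ids - 1, rows)
    col_of = np.zeros(n, dtype=int)
    col_of[ids - 1] = cols  # runs are strictly vertical: one column per run
    keep = sizes >= min_run
    return labels, first[keep], sizes[keep], col_of[keep]


def find_ilm(bscan, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Per-column row index of the internal limiting membrane."""
    img = _image_of(bscan)
    h, w = img.shape
    mu, sd = _background(img, params)
    thr = mu + params.k_sigma * sd
    smoothed = _smooth(img, params)
    above = smoothed > thr
    _, first, sizes, col_of = _column_runs(above, params.min_run)
    curve = np.full(w, np.nan)
    if first.size:
        if params.strategy == "first":
            order = np.lexsort((first, col_of))
        else:  # longest run, topmost on ties
            order = np.lexsort((first, -sizes, col_of))
        cols_sorted = col_of[order]
        first_per_col = np.concatenate(([True], cols_sorted[1:] != cols_sorted[:-1]))
        curve[cols_sorted[first_per_col]] = first[order][first_per_col]
    try:
        return _fill_and_median(curve, params)
    except SegmentationError:
        raise SegmentationError(
            f"no column crossed background mean + {params.k_sigma}*SD for "
            f">= {params.min_run} consecutive rows (flat image?)"
        ) from None


def find_rpe_band(
    bscan,
    ilm: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column inner/outer boundaries of the RPE, the brightest band below
    the ILM.  Boundaries sit where the smoothed intensity drops below
    background + half the peak elevation above background."""
    img = _image_of(bscan)
    h, w = img.shape
    mu, sd = _background(img, params)
    smoothed = _smooth(img, params)
    rows = np.arange(h)[:, None]
    search = rows >= np.minimum(ilm + params.guard_px, h - 1)[None, :]
    masked = np.where(search, smoothed, -np.inf)
    peak_row = np.argmax(masked, axis=0)
    peak_val = masked[peak_row, np.arange(w)]
    ok = peak_val > mu + params.k_sigma * sd
    if not ok.any():
        raise SegmentationError("no bright band found below the ILM in any column")
    cutoff = mu + 0.5 * (peak_val - mu)
    above_cut = smoothed >= cutoff[None, :]
    run_labels, _ = ndimage.label(above_cut, structure=_VERTICAL)
    peak_labels = run_labels[peak_row, np.arange(w)]
    inner = np.full(w, np.nan)
    outer = np.full(w, np.nan)
    rr, cc = np.nonzero(run_labels)
    ids = run_labels[rr, cc]
    n = run_labels.max()
    lo = np.full(n + 1, h, dtype=int)
    hi = np.full(n + 1, -1, dtype=int)
    np.minimum.at(lo, ids, rr)
    np.maximum.at(hi, ids, rr)
    sel = ok & (peak_labels > 0)
    inner[sel] = lo[peak_labels[sel]]
    outer[sel] = hi[peak_labels[sel]]
    inner = _fill_and_median(inner, params)
    outer = _fill_and_median(outer, params)
    if np.any(inner <= ilm):
        raise SegmentationError("RPE inner boundary reached the ILM (ordering violated)")
    return inner, np.maximum(outer, inner)


def build_masks(boundaries: LayerBoundaries, shape: tuple[int, int]) -> RegionMasks:
    """Vitreous = rows strictly above the ILM; RPE = rows within the band."""
    h, w = shape
    rows = np.arange(h)[:, None]
    vitreous = rows < boundaries.ilm[None, :]
    rpe = (rows >= boundaries.rpe_inner[None, :]) & (rows <= boundaries.rpe_outer[None, :])
    return RegionMasks(vitreous=vitreous, rpe=rpe)


def segment(bscan, params: SegmentationParams = SegmentationParams()):
    """Convenience: ILM + RPE boundaries and the derived region masks."""
    ilm = find_ilm(bscan, params)
    inner, outer = find_rpe_band(bscan, ilm, params)
    boundaries = LayerBoundaries(ilm=ilm, rpe_inner=inner, rpe_outer=outer)
    img = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan)
    return boundaries, build_masks(boundaries, img.shape)
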