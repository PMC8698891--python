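"""Hyperreflective-opacity detection and equivalent-ellipse morphometry.

Pipeline per B-scan: a 3x3 vertical-gradient filter emphasizes horizontal
edges; the rectified response is binarized at the Otsu threshold; the
binary is refined (closing and hole filling turn the kernel's boundary
bands into filled candidate regions); connected components are restricted
to the vitreous; regions whose mean grayscale intensity does not rise
above the speckle background (Tukey upper fence) are discarded as noise;
surviving candidates are snapped to their grayscale footprint and
measured.

Region shape descriptors come from the second central moments with the
1/12 pixel-extent correction, so a single pixel has a well-defined circular
equivalent ellipse.  Eccentricity is sqrt(1 - (minor/major)^2) (0 = circle,
-> 1 = line segment); orientation is the angle between the image x-axis and
the major axis, degrees in (-90, 90], counterclockwise positive with the
row index increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import BScan, Calibration
from .metrics import SizeClass, classify_size
from .segmentation import RegionMasks

__all__ = [
    "EDGE_KERNEL",
    "DetectionParams",
    "Opacity",
    "horizontal_edge_filter",
    "otsu_threshold",
    "label_components",
    "tukey_upper_fence",
    "denoise_regions",
    "measure_opacity",
    "detect_opacities",
]

#: Vertical-gradient (horizontal-edge) kernel, applied by correlation.
EDGE_KERNEL = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64)

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_VERT_3x1 = np.ones((3, 1), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """Detection stage knobs.

    ``connectivity``: 8 (default) or 4 for component labeling.
    ``fence_multiplier``: the k in Q3 + k*IQR of the denoising fence.
    ``denoise_reference``: "background" compares each region's mean
    intensity against the fence of the vitreous pixel intensities (the
    default — opacities must rise above the speckle background);
    "regions" compares against the fence of the region mean intensities
    themselves.
    ``refine``: close + fill the binary edge map before labeling,
    recovering filled candidate regions from edge outlines (plus a 3x3
    erosion of the band shell when no grayscale snap follows).
    ``grayscale_snap``: after denoising, re-derive each surviving region's
    footprint by thresholding the original grayscale at the geometric mean
    of background and region intensity (edge responses localize an
    opacity; its extent is sharpest in the grayscale image itself).
    """

    connectivity: int = 8
    fence_multiplier: float = 1.5
    denoise_reference: str = "background"
    refine: bool = True
    grayscale_snap: bool = True
    snap_window_px: int = 24

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.denoise_reference not in ("background", "regions"):
            raise ValueError("denoise_reference must be 'background' or 'regions'")
        if not self.fence_multiplier >= 0:
            raise ValueError("fence_multiplier must be non-negative")


@dataclass(frozen=True)
class Opacity:
    """One detected vitreous opacity and its morphometry."""

    bscan_index: int
    label: int
    rows: np.ndarray
    cols: np.ndarray
    n_pixels: int
    area_um2: float
    mean_intensity: float
    eccentricity: float
    orientation_deg: float
    centroid: tuple[float, float]  # (col, row)
    size_class: SizeClass


def horizontal_edge_filter(image: np.ndarray, signed: bool = False) -> np.ndarray:
    """Correlate with the 3x3 vertical-gradient kernel (edge-replicated
    border); returns the magnitude unless ``signed=True``."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {image.shape}")
    response = ndimage.correlate(image, EDGE_KERNEL, mode="nearest")
    return response if signed else np.abs(response)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over an ``nbins``-bin histogram of the image.

    Returns the bin center maximizing the between-class variance
    (equivalently minimizing the within-class variance); foreground is
    every pixel *strictly greater* than the threshold.  A constant image
    yields the constant itself (empty foreground).
    """
    values = np.asarray(image, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty image")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    integral = bool(np.all(values == np.rint(values)))
    if integral and lo >= 0 and hi <= nbins - 1:
        # 8-bit-style data: one exact bin per gray level, so the returned
        # threshold induces precisely the partition the histogram optimized
        hist = np.bincount(values.astype(np.intp), minlength=nbins).astype(float)
        centers = np.arange(nbins, dtype=np.float64)
    else:
        hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(np.float64)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # threshold candidates split after bin i; last bin cannot be a split.
    # Ties (e.g. an empty gap between two modes) break to the midpoint of
    # the tied candidates, placing the threshold between the modes.
    candidates = sigma_b[:-1]
    tied = np.flatnonzero(candidates == candidates.max())
    return float(centers[tied].mean())


def label_components(
    binary: np.ndarray,
    vitreous_mask: np.ndarray | None = None,
    connectivity: int = 8,
) -> tuple[np.ndarray, int]:
    """Connected components of the binary mask restricted to the vitreous."""
    binary = np.asarray(binary, dtype=bool)
    if vitreous_mask is not None:
        if vitreous_mask.shape != binary.shape:
            raise ValueError("binary and vitreous masks must share a shape")
        binary = binary & vitreous_mask
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    return ndimage.label(binary, structure=structure)


def tukey_upper_fence(values: Sequence[float], multiplier: float = 1.5) -> float:
    """Q3 + multiplier * IQR with interpolated quartiles.

    With fewer than 4 values the quartiles are not meaningful and the fence
    is +inf (nothing passes — conservative degenerate convention).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("tukey_upper_fence needs at least one value")
    if values.size < 4:
        return math.inf
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + multiplier * (q3 - q1))


def denoise_regions(
    labels: np.ndarray,
    image: np.ndarray,
    vitreous_mask: np.ndarray | None = None,
    reference: str = "background",
    multiplier: float = 1.5,
) -> np.ndarray:
    """Labels (sorted) of the regions surviving the intensity-outlier filter.

    A region survives when its mean grayscale intensity strictly exceeds
    the Tukey upper fence of the reference distribution: the vitreous pixel
    intensities (``reference="background"``, default — regions must rise
    above the speckle background) or the region mean intensities themselves
    (``reference="regions"``).
    """
    n = int(labels.max())
    if n == 0:
        return np.empty(0, dtype=int)
    image = np.asarray(image, dtype=np.float64)
    ids = np.arange(1, n + 1)
    means = ndimage.mean(image, labels=labels, index=ids)
    if reference == "background":
        if vitreous_mask is None:
            raise ValueError("background-referenced denoising needs the vitreous mask")
        fence = tukey_upper_fence(image[vitreous_mask], multiplier)
    elif reference == "regions":
        fence = tukey_upper_fence(means, multiplier)
    else:
        raise ValueError(f"unknown denoise reference {reference!r}")
    return ids[means > fence]


def _moment_ellipse(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """(eccentricity, orientation_deg, major/minor ratio helper) from the
    pixel-extent-corrected second central moments."""
    cxx = float(np.var(cols)) + 1.0 / 12.0
    cyy = float(np.var(rows)) + 1.0 / 12.0
    cxy = float(np.mean((cols - cols.mean()) * (rows - rows.mean())))
    common = 0.5 * (cxx + cyy)
    half_diff = math.hypot(0.5 * (cxx - cyy), cxy)
    lam1 = common + half_diff
    lam2 = common - half_diff
    ecc = math.sqrt(max(1.0 - lam2 / lam1, 0.0))
    if half_diff == 0.0:
        orient = 0.0  # circular region: tie broken to 0 degrees
    else:
        # y axis points up: negate the row covariance
        orient = 0.5 * math.degrees(math.atan2(-2.0 * cxy, cxx - cyy))
        if orient <= -90.0:
            orient += 180.0
    return ecc, orient, lam1


def measure_opacity(
    region: np.ndarray | tuple[np.ndarray, np.ndarray],
    image: np.ndarray,
    calibration: Calibration,
    bscan_index: int = 0,
    label: int = 1,
) -> Opacity:
    """Measure one region (boolean mask or (rows, cols) index pair)."""
    if isinstance(region, tuple):
        rows, cols = (np.asarray(region[0]), np.asarray(region[1]))
    else:
        rows, cols = np.nonzero(region)
    if rows.size == 0:
        raise ValueError("cannot measure an empty region")
    image = np.asarray(image, dtype=np.float64)
    n = int(rows.size)
    area = n * calibration.pixel_area_um2
    ecc, orient, _ = _moment_ellipse(rows, cols)
    return Opacity(
        bscan_index=bscan_index,
        label=int(label),
        rows=rows,
        cols=cols,
        n_pixels=n,
        area_um2=area,
        mean_intensity=float(image[rows, cols].mean()),
        eccentricity=ecc,
        orientation_deg=orient,
        centroid=(float(cols.mean()), float(rows.mean())),
        size_class=classify_size(area),
    )


_DISK_2 = np.array(
    [[0, 1, 1, 1, 0], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [0, 1, 1, 1, 0]],
    dtype=bool,
)


def refine_binary(binary: np.ndarray, erode: bool = True) -> np.ndarray:
    """Turn the edge-band binary into filled regions.

    The gradient kernel marks a band around each region boundary (one row
    on either side of horizontal edges, wider on slanted ones).  A
    radius-2 closing bridges the weak-response gaps at near-vertical
    boundary segments and hole filling recovers interiors.  With
    ``erode=True`` a 3x3 erosion strips the one-pixel shell the kernel
    support introduced — wanted when these regions are measured directly,
    counterproductive before a grayscale snap because it can erase the
    smallest (1-3 px) opacities altogether.
    """
    closed = ndimage.binary_closing(binary, structure=_DISK_2)
    filled = ndimage.binary_fill_holes(closed)
    if erode:
        filled = ndimage.binary_erosion(filled, structure=_STRUCT_8)
    return filled


def snap_to_grayscale(
    labels: np.ndarray,
    survivors: np.ndarray,
    image: np.ndarray,
    vitreous_mask: np.ndarray,
    connectivity: int = 8,
    window_px: int = 24,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Re-derive each surviving region's footprint from the grayscale image.

    Edge responses localize an opacity but blur its outline.  Around each
    candidate, the grayscale is thresholded at the geometric mean of the
    vitreous background and the candidate's mean intensity — the midpoint
    on a log scale, where multiplicative speckle misclassifies background
    and opacity pixels at comparable (tiny) rates — and the connected
    bright components touching the candidate, holes filled, join a
    footprint canvas.  The canvas is re-labeled at the end, so two
    detected arcs of one opacity merge into a single region while
    neighbouring opacities that the binary refinement had fused come out
    as the separate connected regions they are.  Returns ``(rows, cols)``
    per region.
    """
    image = np.asarray(image, dtype=np.float64)
    bg = max(float(np.median(image[vitreous_mask])), 1.0)
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    h, w = image.shape
    canvas = np.zeros(image.shape, dtype=bool)
    slices = ndimage.find_objects(labels)
    for lab in survivors:
        sl = slices[lab - 1]
        r0 = max(sl[0].start - window_px, 0)
        r1 = min(sl[0].stop + window_px, h)
        c0 = max(sl[1].start - window_px, 0)
        c1 = min(sl[1].stop + window_px, w)
        window = np.s_[r0:r1, c0:c1]
        cand = labels[window] == lab
        mean_int = float(image[window][cand].mean())
        if mean_int <= bg:
            continue
        thr = math.sqrt(bg * mean_int)
        bright = (image[window] > thr) & vitreous_mask[window]
        sub_labels, _ = ndimage.label(bright, structure=structure)
        touched = np.unique(sub_labels[cand])
        mask = np.isin(sub_labels, touched[touched > 0])
        if not mask.any():
            mask = cand  # no grayscale support above the threshold: keep as-is
        else:
            mask = ndimage.binary_fill_holes(mask)
        canvas[window] |= mask
    final_labels, n = ndimage.label(canvas, structure=structure)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for lab, sl in enumerate(ndimage.find_objects(final_labels), start=1):
        rr, cc = np.nonzero(final_labels[sl] == lab)
        out.append((rr + sl[0].start, cc + sl[1].start))
    return out


def detect_opacities(
    bscan,
    masks: RegionMasks,
    calibration: Calibration | None = None,
    params: DetectionParams = DetectionParams(),
) -> list[Opacity]:
    """Full per-B-scan detection pipeline; returns measured opacities."""
    if isinstance(bscan, BScan):
        image = bscan.pixels.astype(np.float64)
        index = bscan.index
        calibration = calibration or bscan.calibration
    else:
        image = np.asarray(bscan, dtype=np.float64)
        index = 0
        if calibration is None:
            raise ValueError("calibration required when passing a bare array")
    magnitude = horizontal_edge_filter(image)
    threshold = otsu_threshold(magnitude)
    binary = magnitude > threshold
    if params.refine:
        binary = refine_binary(binary, erode=not params.grayscale_snap)
    labels, _ = label_components(binary, masks.vitreous, params.connectivity)
    survivors = denoise_regions(
        labels,
        image,
        vitreous_mask=masks.vitreous,
        reference=params.denoise_reference,
        multiplier=params.fence_multiplier,
    )
    if params.grayscale_snap:
        regions = snap_to_grayscale(
            labels, survivors, image, masks.vitreous,
            params.connectivity, params.snap_window_px,
        )
    else:
        slices = ndimage.find_objects(labels)
        regions = []
        for lab in survivors:
            sl = slices[lab - 1]
            rr, cc = np.nonzero(labels[sl] == lab)
            regions.append((rr + sl[0].start, cc + sl[1].start))
    return [
        measure_opacity((rows, cols), image, calibration, index, new_label)
        for new_label, (rows, cols) in enumerate(regions, start=1)
        if rows.size
    ]
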