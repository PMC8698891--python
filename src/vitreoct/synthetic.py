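"""Synthetic OCT B-scans with exact planted ground truth.

The generator emulates the image anatomy the analysis pipeline assumes: a
dark speckle-noise vitreous on top, a mid-intensity retina band below the
ILM, a bright thin RPE band, and hyperreflective elliptical opacities
planted in the vitreous.  Speckle is modelled as multiplicative unit-mean
gamma noise, a standard surrogate for OCT speckle statistics.  Cohorts
follow the study design of two chronic-glaucoma groups plus controls
scanned longitudinally, with planted per-B-scan opacity counts of 10-20
(physiological) versus a mean around 70 (glaucomatous) and a glaucoma
size-class mix with roughly 40-50% activated-range opacities.

Every random draw descends from a master seed through a documented
``SeedSequence`` spawn-key scheme (group, eye, side, week, B-scan), so any
single image is regenerable in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import SceneError
from .io import (
    SEXES,
    WEEKS,
    BScan,
    Calibration,
    EyeScanSeries,
    default_calibration,
)

__all__ = [
    "OpacitySpec",
    "SceneSpec",
    "OpacityPopulation",
    "GroundTruth",
    "GroundTruthOpacity",
    "GroupDesign",
    "CohortDesign",
    "make_scene",
    "rasterize_ellipse",
    "render_bscan",
    "sample_opacities",
    "generate_series",
    "generate_cohort",
    "default_cohort_design",
]

#: Size-class boundaries in um^2 shared with the measurement side.
CLASS_BOUNDS_UM2 = {
    "isolated": (1e-9, 10.0),
    "non_activated": (10.0, 50.0),
    "activated": (50.0, 250.0),
    "complex": (250.0, 1000.0),
}


@dataclass(frozen=True)
class OpacitySpec:
    """One planted elliptical opacity.

    ``orientation_deg`` uses the measurement convention: angle between the
    image x-axis and the major axis, degrees in (-90, 90], counterclockwise
    positive with the row index increasing downward.
    """

    center: tuple[float, float]  # (col, row)
    semi_major_px: float
    semi_minor_px: float
    orientation_deg: float = 0.0
    intensity: float = 160.0

    def __post_init__(self) -> None:
        if not (self.semi_major_px >= self.semi_minor_px > 0):
            raise SceneError("semi-axes must satisfy semi_major >= semi_minor > 0")
        if not (-90.0 < self.orientation_deg <= 90.0):
            raise SceneError("orientation_deg must lie in (-90, 90]")
        if not (0 < self.intensity <= 255):
            raise SceneError("opacity intensity must lie in (0, 255]")

    @property
    def eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.semi_minor_px / self.semi_major_px) ** 2)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic B-scan before rasterization."""

    shape: tuple[int, int]  # (height, width)
    ilm_row: np.ndarray | int
    rpe_inner: np.ndarray | int
    rpe_outer: np.ndarray | int
    vitreous_level: float = 24.0
    retina_level: float = 110.0
    rpe_level: float = 230.0
    sub_rpe_level: float = 60.0
    speckle_shape: float | None = 10.0
    opacities: tuple[OpacitySpec, ...] = ()

    def __post_init__(self) -> None:
        h, w = self.shape
        for name in ("ilm_row", "rpe_inner", "rpe_outer"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=int), (w,)).copy()
            object.__setattr__(self, name, v)
        if not np.all(
            (0 < self.ilm_row)
            & (self.ilm_row < self.rpe_inner)
            & (self.rpe_inner < self.rpe_outer)
            & (self.rpe_outer < h)
        ):
            raise SceneError("layer ordering 0 < ilm < rpe_inner < rpe_outer < height violated")
        if self.speckle_shape is not None and not self.speckle_shape > 0:
            raise SceneError("speckle_shape must be positive (or None for noiseless)")


def make_scene(
    shape: tuple[int, int] = (496, 1536),
    ilm_frac: float = 0.40,
    rpe_frac: float = 0.85,
    rpe_thickness: int = 8,
    ilm_row: np.ndarray | int | None = None,
    **kwargs,
) -> SceneSpec:
    """Default flat-layer scene: ILM at 40% height, an 8-px RPE band near 85%."""
    h, _ = shape
    if ilm_row is None:
        ilm_row = int(round(ilm_frac * h))
    rpe_inner = int(round(rpe_frac * h))
    return SceneSpec(
        shape=shape,
        ilm_row=ilm_row,
        rpe_inner=rpe_inner,
        rpe_outer=rpe_inner + rpe_thickness - 1,
        **kwargs,
    )


@dataclass(frozen=True)
class GroundTruthOpacity:
    """Planted truth for one opacity.

    ``eccentricity``/``orientation_deg`` are the continuous ellipse
    parameters; ``raster_eccentricity``/``raster_orientation_deg`` are the
    moment descriptors of the actual rasterized pixel region — the values
    a perfect detector would measure, and the right reference for
    recovery benchmarks (rasterization itself distorts the continuous
    parameters for small regions).
    """

    label: int
    n_pixels: int
    area_um2: float
    intensity: float
    eccentricity: float
    orientation_deg: float
    centroid: tuple[float, float]  # (col, row)
    semi_major_px: float = float("nan")
    semi_minor_px: float = float("nan")
    raster_eccentricity: float = float("nan")
    raster_orientation_deg: float = float("nan")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one B-scan: a label mask plus per-opacity records."""

    labels: np.ndarray
    opacities: tuple[GroundTruthOpacity, ...]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def rasterize_ellipse(spec: OpacitySpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers satisfy the ellipse inequality.

    Boundary equality counts as inside (the documented tie rule).
    """
    h, w = shape
    cx, cy = spec.center
    r = max(spec.semi_major_px, spec.semi_minor_px) + 1.0
    c0, c1 = max(0, int(math.floor(cx - r))), min(w - 1, int(math.ceil(cx + r)))
    r0, r1 = max(0, int(math.floor(cy - r))), min(h - 1, int(math.ceil(cy + r)))
    mask = np.zeros(shape, dtype=bool)
    if c0 > c1 or r0 > r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    dx = cols - cx
    dy = rows - cy
    th = math.radians(spec.orientation_deg)
    # major-axis unit vector is (cos th, -sin th) in (col, row) coordinates
    u = dx * math.cos(th) - dy * math.sin(th)
    v = dx * math.sin(th) + dy * math.cos(th)
    inside = (u / spec.semi_major_px) ** 2 + (v / spec.semi_minor_px) ** 2 <= 1.0
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def _layered_background(scene: SceneSpec) -> np.ndarray:
    h, w = scene.shape
    rows = np.arange(h)[:, None]
    img = np.full(scene.shape, scene.vitreous_level, dtype=np.float64)
    img[rows >= scene.ilm_row[None, :]] = scene.retina_level
    img[rows > scene.rpe_outer[None, :]] = scene.sub_rpe_level
    band = (rows >= scene.rpe_inner[None, :]) & (rows <= scene.rpe_outer[None, :])
    img[band] = scene.rpe_level
    return img


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def render_bscan(
    scene: SceneSpec,
    calibration: Calibration | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    index: int = 0,
) -> tuple[BScan, GroundTruth]:
    """Rasterize a scene into a calibrated uint8 B-scan plus its ground truth.

    Ground-truth masks and per-opacity records are computed on the noiseless
    scene; multiplicative speckle (if any) is applied afterwards.  The same
    seed always yields a bit-identical image.
    """
    from .detection import _moment_ellipse

    calibration = calibration or default_calibration(scene.shape[1], scene.shape[0])
    img = _layered_background(scene)
    labels = np.zeros(scene.shape, dtype=np.int32)
    records = []
    rows_idx = np.arange(scene.shape[0])[:, None]
    vitreous = rows_idx < scene.ilm_row[None, :]
    for i, spec in enumerate(scene.opacities, start=1):
        mask = rasterize_ellipse(spec, scene.shape)
        n = int(mask.sum())
        if n == 0:
            raise SceneError(f"opacity {i} rasterizes to zero pixels")
        if np.any(mask & ~vitreous):
            raise SceneError(f"opacity {i} extends outside the vitreous (at or below the ILM)")
        if np.any(labels[mask]):
            raise SceneError(f"opacity {i} overlaps an earlier planted opacity")
        labels[mask] = i
        img[mask] = spec.intensity
        mrows, mcols = np.nonzero(mask)
        r_ecc, r_orient, _ = _moment_ellipse(mrows, mcols)
        records.append(
            GroundTruthOpacity(
                label=i,
                n_pixels=n,
                area_um2=n * calibration.pixel_area_um2,
                intensity=spec.intensity,
                eccentricity=spec.eccentricity,
                orientation_deg=spec.orientation_deg,
                centroid=spec.center,
                semi_major_px=spec.semi_major_px,
                semi_minor_px=spec.semi_minor_px,
                raster_eccentricity=r_ecc,
                raster_orientation_deg=r_orient,
            )
        )
    if scene.speckle_shape is not None:
        rng = _as_rng(seed)
        img = img * rng.gamma(scene.speckle_shape, 1.0 / scene.speckle_shape, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return BScan(pixels, index, calibration), GroundTruth(labels, tuple(records))


# ---------------------------------------------------------------------------
# population sampling


@dataclass(frozen=True)
class OpacityPopulation:
    """Distributional description of the opacities planted per B-scan.

    ``count`` is one of ``("fixed", k)``, ``("uniform", lo, hi)`` (inclusive
    integer range) or ``("poisson", mean)``.  ``class_mix`` gives sampling
    probabilities over the four soma-size classes; areas are drawn
    log-uniformly within each class's um^2 interval (clamped to at least one
    pixel).  Eccentricity is uniform over ``eccentricity_range`` and
    orientation uniform over (-90, 90].
    """

    count: tuple = ("fixed", 0)
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "isolated": 0.05,
            "non_activated": 0.50,
            "activated": 0.35,
            "complex": 0.10,
        }
    )
    #: when set, sizes are drawn log-uniformly over this pixel-count range
    #: instead of from the um^2 class mix (benchmarks specified in pixels)
    pixel_range: tuple[float, float] | None = None
    intensity_range: tuple[float, float] = (130.0, 210.0)
    eccentricity_range: tuple[float, float] = (0.30, 0.95)
    ilm_margin_px: int = 5
    top_margin_px: int = 3
    separation_px: int = 3
    max_place_tries: int = 400

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SceneError(f"class_mix probabilities must sum to 1, got {total}")
        if set(self.class_mix) - set(CLASS_BOUNDS_UM2):
            raise SceneError(f"unknown size classes in mix: {set(self.class_mix) - set(CLASS_BOUNDS_UM2)}")


def sample_count(rng: np.random.Generator, dist: tuple) -> int:
    kind = dist[0]
    if kind == "fixed":
        return int(dist[1])
    if kind == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    if kind == "poisson":
        return int(rng.poisson(dist[1]))
    raise SceneError(f"unknown count distribution {dist!r}")


def _axes_for_area(n_px: float, ecc: float) -> tuple[float, float]:
    ratio = math.sqrt(max(1.0 - ecc**2, 1e-6))
    a = math.sqrt(n_px / (math.pi * ratio))
    b = a * ratio
    # keep the minor axis rasterizable
    if b < 0.6:
        b = 0.6
        a = max(n_px / (math.pi * b), b)
    return a, b


def sample_opacities(
    rng: np.random.Generator,
    scene: SceneSpec,
    population: OpacityPopulation,
    calibration: Calibration,
    n: int | None = None,
) -> tuple[OpacitySpec, ...]:
    """Draw and place ``n`` non-overlapping opacities inside the vitreous.

    Placement is by rejection sampling against an occupancy mask dilated by
    ``separation_px`` so neighbouring planted regions stay resolvable.
    """
    if n is None:
        n = sample_count(rng, population.count)
    if n == 0:
        return ()
    h, w = scene.shape
    classes = sorted(population.class_mix)
    probs = np.array([population.class_mix[c] for c in classes])
    occupied = np.zeros(scene.shape, dtype=bool)
    rows_idx = np.arange(h)[:, None]
    vitreous = rows_idx < scene.ilm_row[None, :]
    specs: list[OpacitySpec] = []
    sep = population.separation_px
    struct = np.ones((2 * sep + 1, 2 * sep + 1), dtype=bool)
    for _ in range(n):
        for _try in range(population.max_place_tries):
            if population.pixel_range is not None:
                lo_px, hi_px = population.pixel_range
                n_px = math.exp(rng.uniform(math.log(lo_px), math.log(hi_px)))
            else:
                cls = classes[rng.choice(len(classes), p=probs)]
                lo, hi = CLASS_BOUNDS_UM2[cls]
                # a class finer than one pixel degenerates to single-pixel regions
                lo = max(lo, calibration.pixel_area_um2)
                hi = max(hi, lo)
                area_um2 = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                n_px = max(area_um2 / calibration.pixel_area_um2, 1.0)
            ecc = rng.uniform(*population.eccentricity_range)
            a, b = _axes_for_area(n_px, ecc)
            theta = rng.uniform(-90.0, 90.0)
            col = rng.uniform(a + 1, w - a - 2)
            lo_row = population.top_margin_px + b + 1
            hi_row = scene.ilm_row.min() - population.ilm_margin_px - b - 1
            if hi_row <= lo_row:
                raise SceneError("vitreous too shallow for the requested opacity sizes")
            row = rng.uniform(lo_row, hi_row)
            spec = OpacitySpec(
                center=(col, row),
                semi_major_px=a,
                semi_minor_px=b,
                orientation_deg=theta if theta > -90 else 90.0,
                intensity=rng.uniform(*population.intensity_range),
            )
            mask = rasterize_ellipse(spec, scene.shape)
            if not mask.any() or np.any(mask & ~vitreous) or np.any(mask & occupied):
                continue
            specs.append(spec)
            rr, cc = np.nonzero(mask)
            r0, r1 = max(rr.min() - sep, 0), min(rr.max() + sep + 1, h)
            c0, c1 = max(cc.min() - sep, 0), min(cc.max() + sep + 1, w)
            occupied[r0:r1, c0:c1] |= ndimage.binary_dilation(mask[r0:r1, c0:c1], structure=struct)
            break
        else:
            raise SceneError(
                f"could not place opacity {len(specs) + 1}/{n} after "
                f"{population.max_place_tries} tries (vitreous too crowded)"
            )
    return tuple(specs)


# ---------------------------------------------------------------------------
# series and cohorts


def generate_series(
    scene_template: SceneSpec,
    population: OpacityPopulation,
    metadata: dict,
    calibration: Calibration | None = None,
    n_bscans: int = 61,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[EyeScanSeries, list[GroundTruth]]:
    """Render an eye's series of B-scans with per-B-scan derived seeds.

    The per-B-scan opacity count is drawn from ``population.count``; all
    randomness descends from ``seed`` via spawn key ``(bscan_index,)``.
    """
    calibration = calibration or default_calibration(scene_template.shape[1], scene_template.shape[0])
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    bscans, truths = [], []
    for i in range(n_bscans):
        child = np.random.SeedSequence(entropy=base.entropy, spawn_key=base.spawn_key + (i,))
        rng = np.random.default_rng(child)
        specs = sample_opacities(rng, scene_template, population, calibration)
        scene = replace(scene_template, opacities=specs)
        bscan, truth = render_bscan(scene, calibration, seed=rng, index=i)
        bscans.append(bscan)
        truths.append(truth)
    return EyeScanSeries(bscans=bscans, **metadata), truths


@dataclass(frozen=True)
class GroupDesign:
    """Per-group planting regime of a synthetic cohort."""

    name: str
    count: tuple
    class_mix: dict[str, float]
    weeks: tuple[int, ...]

    def __post_init__(self) -> None:
        if not set(self.weeks) <= set(WEEKS):
            raise SceneError(f"weeks must be a subset of {WEEKS}")
        if self.name == "control" and not set(self.weeks) <= {0, 12, 24}:
            raise SceneError("control eyes are scanned at weeks 0, 12 and 24 only")


@dataclass(frozen=True)
class CohortDesign:
    """Groups x sides x sexes x weeks design with a master seed."""

    groups: tuple[GroupDesign, ...]
    eyes_per_group: int
    shape: tuple[int, int] = (496, 1536)
    n_bscans: int = 61
    sides: tuple[str, ...] = ("RE",)
    speckle_shape: float | None = 10.0
    intensity_range: tuple[float, float] = (130.0, 210.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups or self.eyes_per_group < 1:
            raise ValueError("cohort design must have at least one group and one eye per group")


def default_cohort_design(
    eyes_per_group: int = 10,
    shape: tuple[int, int] = (496, 1536),
    n_bscans: int = 61,
    master_seed: int = 0,
    glaucoma_groups: Sequence[str] = ("MEPI",),
    weeks: tuple[int, ...] = WEEKS,
) -> CohortDesign:
    """The study-condition defaults: control counts uniform in [10, 20] per
    B-scan versus glaucomatous counts Poisson with mean 70, and a glaucoma
    size mix with ~45% activated-range opacities."""
    control_mix = {"isolated": 0.05, "non_activated": 0.50, "activated": 0.35, "complex": 0.10}
    glaucoma_mix = {"isolated": 0.10, "non_activated": 0.40, "activated": 0.45, "complex": 0.05}
    groups = [GroupDesign("control", ("uniform", 10, 20), control_mix, (0, 12, 24))]
    for g in glaucoma_groups:
        groups.append(GroupDesign(g, ("poisson", 70), glaucoma_mix, tuple(weeks)))
    return CohortDesign(
        groups=tuple(groups),
        eyes_per_group=eyes_per_group,
        shape=shape,
        n_bscans=n_bscans,
        master_seed=master_seed,
    )


def generate_cohort(design: CohortDesign) -> list[tuple[EyeScanSeries, list[GroundTruth]]]:
    """One series per eye x side x scheduled week, reproducible from the
    master seed via spawn keys (group, eye, side, week)."""
    calibration = default_calibration(design.shape[1], design.shape[0])
    scene = make_scene(design.shape, speckle_shape=design.speckle_shape)
    base = np.random.SeedSequence(design.master_seed)
    out = []
    for gi, group in enumerate(design.groups):
        for eye in range(design.eyes_per_group):
            sex = SEXES[eye % len(SEXES)]
            for si, side in enumerate(design.sides):
                for wi, week in enumerate(group.weeks):
                    seed = np.random.SeedSequence(
                        entropy=base.entropy, spawn_key=(gi, eye, si, wi)
                    )
                    population = OpacityPopulation(
                        count=group.count,
                        class_mix=dict(group.class_mix),
                        intensity_range=design.intensity_range,
                    )
                    metadata = {
                        "animal_id": f"{group.name}-{eye:03d}",
                        "side": side,
                        "group": group.name if group.name in ("MEPI", "Ms", "control") else "MEPI",
                        "sex": sex,
                        "week": week,
                    }
                    out.append(
                        generate_series(
                            scene,
                            population,
                            metadata,
                            calibration,
                            n_bscans=design.n_bscans,
                            seed=seed,
                        )
                    )
    if not out:
        raise ValueError("empty cohort design")
    return out
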