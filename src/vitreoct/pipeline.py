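"""End-to-end orchestration: series -> segmentation -> detection -> metrics,
plus the planted-truth benchmark and cohort-level statistics report."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as oct_io
from .detection import DetectionParams, Opacity, detect_opacities
from .exceptions import ComputationError, ConfigError, SegmentationError
from .metrics import EyeSummary, SizeClass, summarize_eye, vit_rpe_relative_intensity
from .segmentation import SegmentationParams, segment
from .stats import anova_oneway, bonferroni_adjust, tukey_hsd
from .synthetic import GroundTruth

__all__ = [
    "PipelineConfig",
    "EyeRunResult",
    "BenchmarkReport",
    "run_eye",
    "match_opacities",
    "run_benchmark",
    "stats_report",
]

log = logging.getLogger("vitreoct")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a pipeline run.

    Unknown keys in a config file are rejected; class boundaries must be
    strictly increasing and positive.
    """

    mode: str = "real"
    width_px: int = oct_io.DEFAULT_WIDTH_PX
    height_px: int = oct_io.DEFAULT_HEIGHT_PX
    width_mm: float = oct_io.DEFAULT_WIDTH_MM
    height_mm: float = oct_io.DEFAULT_HEIGHT_MM
    square_pixels: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    class_bounds: tuple[float, float, float] = (10.0, 50.0, 250.0)
    alpha: float = 0.05
    outdir: str | None = None
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("real", "synthetic"):
            raise ConfigError(f"mode must be 'real' or 'synthetic', got {self.mode!r}")
        b = self.class_bounds
        if not (len(b) == 3 and 0 < b[0] < b[1] < b[2]):
            raise ConfigError(f"class boundaries must be positive and strictly increasing, got {b}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        try:
            if "segmentation" in data:
                data["segmentation"] = _build(SegmentationParams, data["segmentation"])
            if "detection" in data:
                data["detection"] = _build(DetectionParams, data["detection"])
            if "class_bounds" in data:
                data["class_bounds"] = tuple(data["class_bounds"])
            unknown = set(data) - set(cls.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown config keys: {sorted(unknown)}")
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def calibration(self) -> oct_io.Calibration:
        return oct_io.default_calibration(
            self.width_px, self.height_px, self.width_mm, self.height_mm, self.square_pixels
        )


def _build(cls, data):
    if isinstance(data, cls):
        return data
    unknown = set(data) - set(cls.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class EyeRunResult:
    summary: EyeSummary
    opacities: list[Opacity]
    failures: list[tuple[int, str]]  # (bscan index, message)


def run_eye(
    series: oct_io.EyeScanSeries,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> EyeRunResult:
    """Segment, detect and summarize one eye's series.

    B-scans whose segmentation fails are skipped (and reported in
    ``failures``); the run is deterministic given pixels and config.
    Output CSVs are written when ``outdir`` (or the config's) is set.
    """
    calibration = series.bscans[0].calibration if series.bscans else config.calibration()
    ratios: list[float] = []
    opacities: list[Opacity] = []
    failures: list[tuple[int, str]] = []
    for bscan in series.bscans:
        try:
            _, masks = segment(bscan, config.segmentation)
            ratios.append(vit_rpe_relative_intensity(bscan, masks))
            found = detect_opacities(bscan, masks, calibration, config.detection)
        except (SegmentationError, ComputationError) as exc:
            failures.append((bscan.index, str(exc)))
            log.warning("b-scan %d failed: %s", bscan.index, exc)
            continue
        log.debug("b-scan %d: %d opacities", bscan.index, len(found))
        opacities.extend(found)
    if failures:
        log.info("%d/%d b-scans failed segmentation", len(failures), len(series))
    summary = summarize_eye(series, opacities, bscan_ratios=ratios or None)
    outdir = outdir or config.outdir
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{series.animal_id}_{series.side}_w{series.week:02d}"
        oct_io.write_opacity_table(opacities, outdir / f"{stem}_opacities.csv", series=series)
        oct_io.write_summary_table([summary], outdir / f"{stem}_summary.csv")
    return EyeRunResult(summary=summary, opacities=opacities, failures=failures)


# ---------------------------------------------------------------------------
# planted-truth benchmark


def match_opacities(
    truth: GroundTruth,
    detected: Sequence[Opacity],
    iou_threshold: float = 0.3,
) -> list[tuple[int, Opacity, float]]:
    """Greedy one-to-one matching of detections to planted regions by
    intersection-over-union; pairs with IoU > ``iou_threshold`` match."""
    gt_sizes = np.bincount(truth.labels.ravel())
    candidates = []
    for op in detected:
        overlap_labels = truth.labels[op.rows, op.cols]
        for lab in np.unique(overlap_labels):
            if lab == 0:
                continue
            inter = int((overlap_labels == lab).sum())
            union = int(gt_sizes[lab]) + op.n_pixels - inter
            iou = inter / union
            if iou > iou_threshold:
                candidates.append((iou, int(lab), op))
    candidates.sort(key=lambda t: -t[0])
    used_gt: set[int] = set()
    used_det: set[int] = set()
    matches = []
    for iou, lab, op in candidates:
        if lab in used_gt or id(op) in used_det:
            continue
        used_gt.add(lab)
        used_det.add(id(op))
        matches.append((lab, op, iou))
    return matches


@dataclass(frozen=True)
class BenchmarkReport:
    """Detection quality against planted ground truth."""

    n_true: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    mean_area_rel_error: float
    median_area_rel_error: float
    mean_ecc_abs_error: float
    class_mix_max_error_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def run_benchmark(
    data: Sequence[tuple[oct_io.EyeScanSeries, Sequence[GroundTruth]]],
    config: PipelineConfig = PipelineConfig(),
    iou_threshold: float = 0.3,
    min_true_pixels: int = 10,
    min_axis_px: float = 5.0,
) -> BenchmarkReport:
    """Run the full pipeline on synthetic series and score it against truth.

    Recall counts planted opacities of at least ``min_true_pixels`` pixels;
    precision counts all detections; area errors are relative to the
    planted rasterized area over matched pairs (same size cut);
    eccentricity errors additionally require both planted ellipse axes to
    reach ``min_axis_px`` pixels.  Class-mix error is the largest absolute
    difference, in percentage points, between planted and detected
    size-class fractions.
    """
    n_true = n_matched = n_detected = n_det_matched = 0
    area_errors: list[float] = []
    ecc_errors: list[float] = []
    true_classes: list[SizeClass] = []
    det_classes: list[SizeClass] = []
    from .metrics import classify_size

    for series, truths in data:
        for bscan, truth in zip(series.bscans, truths):
            _, masks = segment(bscan, config.segmentation)
            detected = detect_opacities(bscan, masks, bscan.calibration, config.detection)
            matches = match_opacities(truth, detected, iou_threshold)
            by_label = {lab: (op, iou) for lab, op, iou in matches}
            eligible = [gt for gt in truth.opacities if gt.n_pixels >= min_true_pixels]
            n_true += len(eligible)
            n_detected += len(detected)
            n_det_matched += len(matches)
            true_classes += [classify_size(gt.area_um2) for gt in truth.opacities]
            det_classes += [op.size_class for op in detected]
            for gt in eligible:
                if gt.label not in by_label:
                    continue
                n_matched += 1
                op, _ = by_label[gt.label]
                area_errors.append(abs(op.area_um2 - gt.area_um2) / gt.area_um2)
                if 2 * gt.semi_minor_px >= min_axis_px and 2 * gt.semi_major_px >= min_axis_px:
                    # reference is the planted rasterized region's moment
                    # eccentricity: what a perfect detector would measure
                    ref = gt.raster_eccentricity
                    if np.isnan(ref):
                        ref = gt.eccentricity
                    ecc_errors.append(abs(op.eccentricity - ref))

    def mix(classes: list[SizeClass]) -> np.ndarray:
        if not classes:
            return np.zeros(len(SizeClass))
        counts = np.array([sum(c is cls for c in classes) for cls in SizeClass], float)
        return 100.0 * counts / counts.sum()

    mix_err = float(np.max(np.abs(mix(true_classes) - mix(det_classes)))) if (true_classes or det_classes) else 0.0
    return BenchmarkReport(
        n_true=n_true,
        n_detected=n_detected,
        n_matched=n_matched,
        recall=n_matched / n_true if n_true else 1.0,
        precision=n_det_matched / n_detected if n_detected else 1.0,
        mean_area_rel_error=float(np.mean(area_errors)) if area_errors else 0.0,
        median_area_rel_error=float(np.median(area_errors)) if area_errors else 0.0,
        mean_ecc_abs_error=float(np.mean(ecc_errors)) if ecc_errors else 0.0,
        class_mix_max_error_pct=mix_err,
    )


# ---------------------------------------------------------------------------
# cohort statistics report


def stats_report(
    summaries: Sequence[EyeSummary],
    metrics: Sequence[str] = ("mean_n_opacities", "vit_rpe_intensity", "total_area_um2"),
    alpha: float = 0.05,
) -> list[dict]:
    """Week-by-week group comparisons of per-eye summary metrics.

    For each metric and week with >= 2 groups of >= 2 eyes: one-way ANOVA
    across groups plus Tukey HSD pairwise comparisons; the Bonferroni
    per-test level divides alpha by the number of ANOVA tests performed.
    """
    rows: list[dict] = []
    weeks = sorted({s.week for s in summaries})
    for metric in metrics:
        for week in weeks:
            groups: dict[str, list[float]] = {}
            for s in summaries:
                if s.week != week:
                    continue
                value = getattr(s, metric)
                if value is not None:
                    groups.setdefault(s.group, []).append(value)
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            try:
                f, p = anova_oneway(groups)
            except ValueError:
                continue
            rows.append(
                {
                    "metric": metric, "week": week, "test": "anova",
                    "groups": "|".join(sorted(groups)), "statistic": f, "p": p,
                }
            )
            for cmp in tukey_hsd(groups):
                rows.append(
                    {
                        "metric": metric, "week": week, "test": "tukey",
                        "groups": f"{cmp.group_a}|{cmp.group_b}",
                        "statistic": cmp.mean_diff, "p": cmp.p_adjusted,
                    }
                )
    n_tests = sum(1 for r in rows if r["test"] == "anova")
    per_test_alpha = bonferroni_adjust(alpha, n_tests) if n_tests else alpha
    for r in rows:
        r["bonferroni_alpha"] = per_test_alpha
        r["significant"] = r["p"] < per_test_alpha
    return rows
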