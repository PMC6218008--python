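"""Full-dataset orchestration: one call runs the whole analysis.

Mirrors the original parameter block of the analysis script: the dataset
root (``updir``), the pixel size in µm, the crack area window in pixels,
the threshold polarity, and the two global-analysis flags
(``global_polarhist_output`` for the per-series orientation summaries,
``global_output_size`` for the cross-series area comparison).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circular_stats import (
    AngleSample,
    AxialSummary,
    axial_mean_resultant,
    rao_spacing_test,
)
from .errors import CrackSepError
from .group_stats import SeriesAreas, compare_all_pairs
from .image_io import DatasetIndex, load_grayscale_image, scan_dataset
from .reporting import (
    ImageOrientationSummary,
    render_comparison,
    render_image_overlays,
    render_polar_histogram,
    write_crack_csv,
    write_series_summary,
)
from .segmentation import SegmentationParams, segment_image
from .shape_analysis import CrackDescriptor, describe_crack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Run parameters (names kept close to the original script block)."""

    updir: Path
    pixel_size: float
    min_area_of_crack: int
    max_area_of_crack: int
    threshold_type: str = "min"
    global_output_size: bool = False
    global_polarhist_output: bool = False
    connectivity: int = 4
    n_bins: int = 18
    alpha: float = 0.05
    anisotropy_method: str = "eigendiff"
    figure_format: str = "pdf"


@dataclass
class PipelineResult:
    """Everything a run produced, plus per-image bookkeeping."""

    outputs: list[Path] = field(default_factory=list)
    crack_counts: dict[str, int] = field(default_factory=dict)
    failed_images: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed_images


def _undefined_summary(n: int = 0) -> AxialSummary:
    return AxialSummary(mean_angle_deg=math.nan, resultant_length=math.nan, n=n)


def _orientation_summary(image_id: str, descriptors: list[CrackDescriptor]) -> ImageOrientationSummary:
    """Unit-weight axial summary plus mean anisotropy for one crack set."""
    if not descriptors:
        return ImageOrientationSummary(
            image_id=image_id, axial=_undefined_summary(), mean_anisotropy=math.nan
        )
    sample = AngleSample(np.array([d.angle_deg for d in descriptors]))
    return ImageOrientationSummary(
        image_id=image_id,
        axial=axial_mean_resultant(sample),
        mean_anisotropy=float(np.mean([d.anisotropy for d in descriptors])),
    )


def _weighted_sample(descriptors: list[CrackDescriptor]) -> AngleSample | None:
    """Histogram sample: each orientation weighted by sqrt(principal eigenvalue)."""
    if not descriptors:
        return None
    weights = np.sqrt([max(d.eigenvalues[0], 0.0) for d in descriptors])
    if not np.any(weights > 0):
        weights = np.ones(len(descriptors))
    return AngleSample(np.array([d.angle_deg for d in descriptors]), weights)


def process_image(
    path: Path, threshold: int, config: RunConfig
) -> tuple[list[CrackDescriptor], list[Path]]:
    """Segment one image with its filename threshold and write its outputs.

    Outputs are written next to the image: ``<stem>_cracks.csv`` plus the
    inverted / labels / vectors / polarhist figures.
    """
    image = load_grayscale_image(path, pixel_size=config.pixel_size)
    params = SegmentationParams(
        threshold=threshold,
        threshold_type=config.threshold_type,  # type: ignore[arg-type]
        min_area_px=config.min_area_of_crack,
        max_area_px=config.max_area_of_crack,
        connectivity=config.connectivity,
    )
    regions = segment_image(image, params)
    descriptors = [
        describe_crack(r, config.pixel_size, anisotropy_method=config.anisotropy_method)  # type: ignore[arg-type]
        for r in regions
    ]
    prefix = path.parent / path.stem
    outputs = [write_crack_csv(descriptors, f"{prefix}_cracks.csv")]
    outputs += render_image_overlays(
        image, descriptors, regions, prefix, fmt=config.figure_format
    )
    outputs.append(
        render_polar_histogram(
            _weighted_sample(descriptors),
            f"{prefix}_polarhist.{config.figure_format}",
            n_bins=config.n_bins,
            title=path.stem,
        )
    )
    return descriptors, outputs


def run_pipeline(config: RunConfig, index: DatasetIndex | None = None) -> PipelineResult:
    """Run the full analysis over a dataset tree.

    Per-image failures are logged and skipped (the run is then flagged as
    partial via ``result.failed_images``); configuration and dataset-level
    errors propagate.  Orientation comparability across images assumes the
    user acquired them in a consistent orientation; no registration is done.
    """
    if index is None:
        index = scan_dataset(config.updir)
    result = PipelineResult()
    series_descriptors: dict[str, list[list[CrackDescriptor]]] = {}
    series_image_ids: dict[str, list[str]] = {}

    for series, entries in index.series.items():
        series_descriptors[series] = []
        series_image_ids[series] = []
        for entry in entries:
            try:
                descriptors, outputs = process_image(entry.path, entry.threshold, config)
            except CrackSepError as exc:
                logger.error("image %s failed: %s", entry.path, exc)
                result.failed_images.append(str(entry.path))
                continue
            result.outputs.extend(outputs)
            series_descriptors[series].append(descriptors)
            series_image_ids[series].append(entry.path.stem)
            result.crack_counts[str(entry.path)] = len(descriptors)
            logger.info(
                "image=%s threshold=%d cracks_kept=%d",
                entry.path, entry.threshold, len(descriptors),
            )

    if config.global_polarhist_output:
        for series in series_descriptors:
            result.outputs.extend(_series_outputs(config, index, series,
                                                  series_image_ids[series],
                                                  series_descriptors[series]))

    if config.global_output_size:
        areas = [
            SeriesAreas(
                series_name=series,
                totals_um2=np.array(
                    [sum(d.area_um2 for d in per_img) for per_img in per_image_lists]
                ),
            )
            for series, per_image_lists in series_descriptors.items()
        ]
        if len(areas) < 2:
            logger.warning("global_output_size needs >= 2 series; skipping comparison")
        else:
            comparisons = compare_all_pairs(areas, alpha=config.alpha)
            pdf, txt = render_comparison(
                comparisons, areas, Path(index.root) / "comparison",
                fmt=config.figure_format,
            )
            result.outputs.extend([pdf, txt])
    return result


def _series_outputs(
    config: RunConfig,
    index: DatasetIndex,
    series: str,
    image_ids: list[str],
    per_image_lists: list[list[CrackDescriptor]],
) -> list[Path]:
    """Pooled polar histogram + orientation summary TXT for one series."""
    series_dir = Path(index.root) / series
    pooled_descriptors = [d for per_img in per_image_lists for d in per_img]
    per_image = [
        _orientation_summary(image_id, descs)
        for image_id, descs in zip(image_ids, per_image_lists)
    ]
    pooled = _orientation_summary(f"{series} (pooled)", pooled_descriptors)
    rao = None
    if len(pooled_descriptors) >= 4:
        rao = rao_spacing_test(
            AngleSample(np.array([d.angle_deg for d in pooled_descriptors])),
            alpha=config.alpha if config.alpha in (0.10, 0.05, 0.01) else 0.05,
        )
    outputs = [
        render_polar_histogram(
            _weighted_sample(pooled_descriptors),
            series_dir / f"{series}_polarhist.{config.figure_format}",
            n_bins=config.n_bins,
            title=f"{series} (pooled)",
        ),
        write_series_summary(per_image, pooled, rao, series_dir / f"{series}_summary.txt"),
    ]
    return outputs
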