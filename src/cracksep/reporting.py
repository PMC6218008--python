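"""Per-image, per-series and cross-series outputs.

Per image: a descriptor CSV plus four vector-PDF figures (intensity-inverted
image, labeled segmentation overlay, eigenvector-cross overlay, polar
orientation histogram).  Per series: a pooled polar histogram and a plain-
text orientation summary ending in a Rao uniformity test.  Per dataset: the
routed two-sample area comparisons as a text file and a boxplot.

On the vector overlay each crack is drawn as a red cross through its
centroid: two orthogonal segments along the eigenvectors, each with
half-length 2·sqrt(eigenvalue) pixels, so long anisotropic cracks show long
principal bars.  Polar-histogram bar heights are weighted by sqrt(principal
eigenvalue); bar colors encode the raw, unweighted angle count per bin
(yellow high, purple low).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.figure import Figure

from .circular_stats import AngleSample, AxialSummary, PolarHistogram, RaoResult, polar_histogram
from .group_stats import ComparisonResult, SeriesAreas
from .image_io import IntensityImage
from .segmentation import CrackRegion
from .shape_analysis import CrackDescriptor

#: Eigenvector display magnification on the cross overlay.
VECTOR_DISPLAY_SCALE = 2.0

CSV_COLUMNS = [
    "label", "centroid_x", "centroid_y", "area_px", "area_um2", "angle_deg",
    "anisotropy", "lambda1", "lambda2", "v1_x", "v1_y", "v2_x", "v2_y",
]

# deterministic categorical palette, cycled by label
_LABEL_COLORS = colormaps["tab20"](np.linspace(0.0, 1.0, 20))


def _fmt(value: float) -> str:
    """Floats at 6 significant digits; NaN rendered as NA."""
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return format(value, ".6g")


@dataclass(frozen=True)
class ImageOrientationSummary:
    """One summary line of the per-series text report."""

    image_id: str
    axial: AxialSummary
    mean_anisotropy: float


def write_crack_csv(descriptors: list[CrackDescriptor], path: str | Path) -> Path:
    """One row per crack; floats at 6 significant digits, '.' decimal."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for d in descriptors:
            (v1, v2) = d.eigenvectors
            writer.writerow(
                [d.label, _fmt(d.centroid[0]), _fmt(d.centroid[1]), d.area_px,
                 _fmt(d.area_um2), _fmt(d.angle_deg), _fmt(d.anisotropy),
                 _fmt(d.eigenvalues[0]), _fmt(d.eigenvalues[1]),
                 _fmt(v1[0]), _fmt(v1[1]), _fmt(v2[0]), _fmt(v2[1])]
            )
    return path


def read_crack_csv(path: str | Path) -> list[CrackDescriptor]:
    """Parse a descriptor CSV back into memory (round-trips to 6 sig digits)."""
    descriptors = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            descriptors.append(
                CrackDescriptor(
                    label=int(row["label"]),
                    centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
                    area_px=int(row["area_px"]),
                    area_um2=float(row["area_um2"]),
                    angle_deg=float(row["angle_deg"]),
                    anisotropy=float(row["anisotropy"]),
                    eigenvalues=(float(row["lambda1"]), float(row["lambda2"])),
                    eigenvectors=(
                        (float(row["v1_x"]), float(row["v1_y"])),
                        (float(row["v2_x"]), float(row["v2_y"])),
                    ),
                )
            )
    return descriptors


def vector_cross_segments(
    descriptor: CrackDescriptor, scale: float = VECTOR_DISPLAY_SCALE
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Endpoints of the two overlay cross segments, in pixel coordinates.

    Each eigenvector is drawn through the centroid with half-length
    ``scale * sqrt(eigenvalue)`` (display magnification, default 2x).
    """
    cx, cy = descriptor.centroid
    segments = []
    for lam, (vx, vy) in zip(descriptor.eigenvalues, descriptor.eigenvectors):
        half = scale * math.sqrt(max(lam, 0.0))
        segments.append(((cx - half * vx, cy - half * vy), (cx + half * vx, cy + half * vy)))
    return segments


def invert_intensities(pixels: np.ndarray) -> np.ndarray:
    """Pixel-intensity inversion i -> 255 - i (the base layer of all overlays)."""
    return (255 - np.asarray(pixels, dtype=np.uint8)).astype(np.uint8)


def _new_image_figure(image: IntensityImage):
    h, w = image.pixels.shape
    fig = Figure(figsize=(max(w / 100.0, 2.0), max(h / 100.0, 2.0)))
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_axis_off()
    ax.imshow(invert_intensities(image.pixels), cmap="gray", vmin=0, vmax=255,
              interpolation="nearest")
    return fig, ax


def render_image_overlays(
    image: IntensityImage,
    descriptors: list[CrackDescriptor],
    regions: list[CrackRegion],
    out_prefix: str | Path,
    fmt: str = "pdf",
) -> list[Path]:
    """The three per-image figures: inverted, label overlay, vector overlay."""
    out_prefix = Path(out_prefix)
    paths = []

    fig, _ = _new_image_figure(image)
    paths.append(Path(f"{out_prefix}_inverted.{fmt}"))
    fig.savefig(paths[-1])

    fig, ax = _new_image_figure(image)
    overlay = np.zeros((*image.pixels.shape, 4))
    for region in regions:
        color = _LABEL_COLORS[(region.label - 1) % len(_LABEL_COLORS)].copy()
        color[3] = 0.6
        overlay[region.coords[:, 0], region.coords[:, 1]] = color
    ax.imshow(overlay, interpolation="nearest")
    paths.append(Path(f"{out_prefix}_labels.{fmt}"))
    fig.savefig(paths[-1])

    fig, ax = _new_image_figure(image)
    for d in descriptors:
        for (x0, y0), (x1, y1) in vector_cross_segments(d):
            ax.plot([x0, x1], [y0, y1], color="red", linewidth=1.0)
    paths.append(Path(f"{out_prefix}_vectors.{fmt}"))
    fig.savefig(paths[-1])
    return paths


def render_polar_histogram(
    sample: AngleSample | None,
    path: str | Path,
    n_bins: int = 18,
    title: str | None = None,
) -> Path:
    """Axial rose plot: bars on [0°, 180°) mirrored to [180°, 360°).

    Bar height is the summed weight per bin; bar color is the raw count per
    bin on a viridis map (yellow high, purple low).  ``sample=None`` (no
    cracks) produces an empty but valid figure.
    """
    path = Path(path)
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    if sample is not None:
        hist: PolarHistogram = polar_histogram(sample, n_bins=n_bins)
        centers = np.radians(hist.bin_edges_deg[:-1] + np.diff(hist.bin_edges_deg) / 2.0)
        width = math.radians(180.0 / n_bins)
        cmap = colormaps["viridis"]
        max_count = hist.counts.max() if hist.counts.max() > 0 else 1
        colors = cmap(hist.counts / max_count)
        # mirror so the axial rose is symmetric under 180° rotation
        theta = np.concatenate([centers, centers + math.pi])
        heights = np.concatenate([hist.heights, hist.heights])
        ax.bar(theta, heights, width=width, color=np.vstack([colors, colors]),
               edgecolor="black", linewidth=0.3)
    if title:
        ax.set_title(title)
    fig.savefig(path)
    return path


def write_series_summary(
    per_image: list[ImageOrientationSummary],
    pooled: ImageOrientationSummary,
    rao: RaoResult | None,
    path: str | Path,
) -> Path:
    """Per-series text report: one line per image, then the pooled block.

    Pooled statistics are computed on all cracks of the series concatenated;
    an undefined circular mean (resultant length below tolerance) is printed
    as NA with an explanatory note.
    """
    if not per_image:
        raise ValueError("series summary needs at least one image")
    path = Path(path)
    lines = ["image\tmean_angle_deg\tresultant_length\tmean_anisotropy"]
    na_seen = False
    for s in per_image:
        lines.append(
            f"{s.image_id}\t{_fmt(s.axial.mean_angle_deg)}\t"
            f"{_fmt(s.axial.resultant_length)}\t{_fmt(s.mean_anisotropy)}"
        )
        na_seen = na_seen or not s.axial.mean_defined
    lines.append("")
    lines.append("# Pooled analysis (all cracks of the series)")
    lines.append(f"pooled_mean_angle_deg\t{_fmt(pooled.axial.mean_angle_deg)}")
    lines.append(f"pooled_resultant_length\t{_fmt(pooled.axial.resultant_length)}")
    lines.append(f"pooled_mean_anisotropy\t{_fmt(pooled.mean_anisotropy)}")
    lines.append(f"n_cracks\t{pooled.axial.n}")
    if rao is not None:
        lines.append(
            f"rao_spacing_U_deg\t{_fmt(rao.U_deg)}\tcritical_{rao.alpha:g}\t"
            f"{_fmt(rao.critical_value_deg)}\t"
            + ("significant_angular_bias" if rao.significant else "uniform_not_rejected")
        )
    else:
        lines.append("rao_spacing_U_deg\tNA\t(fewer than 4 cracks)")
    if na_seen or not pooled.axial.mean_defined:
        lines.append(
            "# NA mean angle: resultant length ~ 0, no preferred orientation"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_comparison_summary(results: list[ComparisonResult], path: str | Path) -> Path:
    """Text report of every pairwise routed comparison, with the audit trail."""
    path = Path(path)
    lines = []
    if len(results) > 1:
        lines.append(
            "# Note: multiple pairwise comparisons, no multiple-testing correction applied"
        )
    for r in results:
        lines.append(f"comparison\t{r.names[0]}\tvs\t{r.names[1]}")
        lines.append(f"shapiro_p\t{_fmt(r.shapiro_p[0])}\t{_fmt(r.shapiro_p[1])}")
        lines.append(
            f"bartlett_p\t{'n/a' if math.isnan(r.bartlett_p) else _fmt(r.bartlett_p)}"
        )
        lines.append(f"chosen_test\t{r.chosen_test}")
        lines.append(f"statistic\t{_fmt(r.statistic)}")
        lines.append(f"p_value\t{_fmt(r.p_value)}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def render_comparison(
    results: list[ComparisonResult],
    per_series_areas: list[SeriesAreas],
    out_prefix: str | Path,
    fmt: str = "pdf",
) -> tuple[Path, Path]:
    """Boxplot of per-image total areas per series + the comparison TXT."""
    if len(per_series_areas) < 2:
        raise ValueError("comparison requires at least 2 series")
    out_prefix = Path(out_prefix)
    fig = Figure(figsize=(1.5 + 1.2 * len(per_series_areas), 4.5))
    ax = fig.add_subplot()
    ax.boxplot(
        [s.totals_um2 for s in per_series_areas],
        tick_labels=[s.series_name for s in per_series_areas],
    )
    ax.set_ylabel("total crack area per image (µm²)")
    pdf_path = Path(f"{out_prefix}_boxplot.{fmt}")
    fig.savefig(pdf_path)
    txt_path = write_comparison_summary(results, Path(f"{out_prefix}_tests.txt"))
    return pdf_path, txt_path
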