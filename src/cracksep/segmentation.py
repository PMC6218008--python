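"""Threshold segmentation and connected-component extraction of cracks.

A crack is a connected set of pixels on one side of an intensity threshold:
``threshold_type="min"`` selects pixels at least as bright as the threshold
(light cracks on a dark background), ``"max"`` selects pixels at most as
bright (dark cracks).  Components are filtered by an inclusive area window —
the lower bound removes speckle noise, the upper bound removes the image
background — and labeled deterministically in raster-scan order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image_io import IntensityImage

ThresholdType = Literal["min", "max"]

# structuring elements for the two pixel connectivities
_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation configuration.

    ``min_area_px``/``max_area_px`` bound the surviving component areas
    (inclusive both ends).  ``connectivity`` is 4 (edge-adjacent, default) or
    8 (edge- or corner-adjacent).
    """

    threshold: int
    threshold_type: ThresholdType = "min"
    min_area_px: int = 1
    max_area_px: int = 10**9
    connectivity: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ConfigurationError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.threshold_type not in ("min", "max"):
            raise ConfigurationError(
                f"threshold_type must be 'min' or 'max', got {self.threshold_type!r}"
            )
        if self.min_area_px < 1 or self.max_area_px < 1:
            raise ConfigurationError("area bounds must be positive")
        if self.min_area_px > self.max_area_px:
            raise ConfigurationError(
                f"min_area_px ({self.min_area_px}) exceeds max_area_px ({self.max_area_px})"
            )
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass(frozen=True)
class CrackRegion:
    """One labeled connected component.

    ``coords`` is an ``(n, 2)`` integer array of (row, col) pixel
    coordinates in raster order; the pixels form one connected component
    under the configured connectivity and regions of one image are pairwise
    disjoint.
    """

    label: int
    coords: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])

    @property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.coords.tolist()))


def binarize(
    image: IntensityImage | np.ndarray, threshold: int, threshold_type: ThresholdType
) -> np.ndarray:
    """Boolean foreground mask of the thresholded image.

    The comparison is inclusive on both polarities (>= for ``"min"``, <= for
    ``"max"``), matching the behavior of the interactive threshold tool used
    to calibrate the per-image threshold.
    """
    if not 0 <= threshold <= 255:
        raise ConfigurationError(f"threshold must be in [0, 255], got {threshold}")
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if threshold_type == "min":
        return pixels >= threshold
    if threshold_type == "max":
        return pixels <= threshold
    raise ConfigurationError(f"threshold_type must be 'min' or 'max', got {threshold_type!r}")


def extract_regions(mask: np.ndarray, params: SegmentationParams) -> list[CrackRegion]:
    """Connected components of ``mask`` within the inclusive area window.

    Labels are assigned 1..k in raster-scan order of each surviving
    component's first pixel, so outputs are reproducible run to run.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n_components = ndimage.label(mask, structure=_STRUCTURES[params.connectivity])
    if n_components == 0:
        return []

    areas = np.bincount(labeled.ravel())[1:]  # area per original label
    keep = np.flatnonzero(
        (areas >= params.min_area_px) & (areas <= params.max_area_px)
    ) + 1

    # first-pixel raster position of each kept label -> deterministic order
    flat = labeled.ravel()
    first_idx = {}
    order = np.argsort(flat, kind="stable")
    boundaries = np.searchsorted(flat[order], np.arange(1, n_components + 1))
    for lab in keep:
        first_idx[lab] = order[boundaries[lab - 1]]
    kept_sorted = sorted(keep, key=lambda lab: first_idx[lab])

    regions: list[CrackRegion] = []
    for new_label, lab in enumerate(kept_sorted, start=1):
        rows, cols = np.nonzero(labeled == lab)
        coords = np.column_stack([rows, cols]).astype(np.int64)
        regions.append(CrackRegion(label=new_label, coords=coords))
    return regions


def segment_image(image: IntensityImage, params: SegmentationParams) -> list[CrackRegion]:
    """Binarize with the configured threshold and extract filtered regions."""
    mask = binarize(image, params.threshold, params.threshold_type)
    return extract_regions(mask, params)
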