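"""Ground-truthed synthetic crack images and dataset trees.

Emulates the image class the pipeline consumes: bright (or dark) closed
crack domains of known position, orientation, area and anisotropy on a
contrasting background, with additive Gaussian noise.  Ellipses are the
canonical crack shape because their orientation and anisotropy have exact
ground truth; the ground-truth shape statistics are computed from the
*rasterized* pixel set so recovery tests compare like with like.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import NamingConventionError, SceneError
from .image_io import IntensityImage, save_grayscale_tiff
from .segmentation import CrackRegion
from .shape_analysis import principal_angle, principal_axes, shape_anisotropy


@dataclass(frozen=True)
class CrackSpec:
    """One elliptical crack: center (x, y) px, semi-axes px, screen-view
    orientation of the major axis in [0°, 180°), fill intensity in [0, 255]."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float
    intensity: int = 200

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise SceneError(
                f"need semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if not 0 <= self.orientation_deg < 180:
            raise SceneError(f"orientation must be in [0°, 180°), got {self.orientation_deg}")
        if not 0 <= self.intensity <= 255:
            raise SceneError(f"intensity must be in [0, 255], got {self.intensity}")


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic image: size, background, noise level, cracks, seed.

    Defaults mirror the imaging conditions the pipeline targets: bright
    cracks (intensity ≈ 200) on a dark background (≈ 20), i.e. a contrast
    large enough that an intermediate threshold separates them exactly when
    ``noise_sigma`` is 0.
    """

    shape: tuple[int, int] = (256, 256)
    background_intensity: int = 20
    noise_sigma: float = 0.0
    cracks: tuple[CrackSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cracks", tuple(self.cracks))
        if self.noise_sigma < 0:
            raise SceneError("noise_sigma must be >= 0")
        if not 0 <= self.background_intensity <= 255:
            raise SceneError("background_intensity must be in [0, 255]")


@dataclass(frozen=True)
class GroundTruthCrack:
    """Rasterized ground truth for one crack."""

    coords: np.ndarray  # (n, 2) (row, col)
    area_px: int
    orientation_deg: float  # of the rasterized pixel set
    anisotropy: float  # eigenvalue-based, of the rasterized pixel set
    spec: CrackSpec


def rasterize_ellipse(spec: CrackSpec, shape: tuple[int, int]) -> np.ndarray:
    """(row, col) coordinates of pixels whose centers fall inside the ellipse."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    cx, cy = spec.center
    dx = cols - cx
    dy = rows - cy
    theta = np.radians(spec.orientation_deg)
    # major-axis direction in storage coords (y = row increases downward)
    ux, uy = np.cos(theta), -np.sin(theta)
    p_major = dx * ux + dy * uy
    p_minor = -dx * uy + dy * ux
    inside = (p_major / spec.semi_major) ** 2 + (p_minor / spec.semi_minor) ** 2 <= 1.0
    r, c = np.nonzero(inside)
    return np.column_stack([r, c]).astype(np.int64)


def generate_crack_image(scene: SceneSpec) -> tuple[IntensityImage, list[GroundTruthCrack]]:
    """Rasterize a scene into an 8-bit image plus its ground-truth table.

    Crack interiors must be pairwise disjoint and not touching under
    8-connectivity (each crack must stay a closed, separable domain);
    violating scenes raise :class:`SceneError`.  Gaussian noise of sd
    ``noise_sigma`` is added, then intensities are clipped to [0, 255] and
    rounded.  Deterministic given ``scene.seed``.
    """
    h, w = scene.shape
    canvas = np.full((h, w), float(scene.background_intensity))
    occupied = np.zeros((h, w), dtype=bool)
    truth: list[GroundTruthCrack] = []

    for i, spec in enumerate(scene.cracks):
        coords = rasterize_ellipse(spec, scene.shape)
        if coords.shape[0] == 0:
            raise SceneError(f"crack {i} rasterizes to zero pixels inside the image")
        mask = np.zeros((h, w), dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        grown = ndimage.binary_dilation(occupied, structure=np.ones((3, 3), dtype=bool))
        if np.any(mask & grown):
            raise SceneError(
                f"crack {i} overlaps or touches a previous crack; crack domains "
                "must be closed and pairwise separated"
            )
        occupied |= mask
        canvas[mask] = spec.intensity

        region = CrackRegion(label=i + 1, coords=coords)
        _, (lam1, lam2), (v1, _) = principal_axes(region)
        truth.append(
            GroundTruthCrack(
                coords=coords,
                area_px=coords.shape[0],
                orientation_deg=principal_angle(v1),
                anisotropy=shape_anisotropy(lam1, lam2),
                spec=spec,
            )
        )

    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, scene.noise_sigma, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = IntensityImage(
        pixels=pixels, pixel_size=1.0, source_path=f"<synthetic seed={scene.seed}>"
    )
    return image, truth


def random_scene(
    seed: int,
    n_cracks: int = 8,
    shape: tuple[int, int] = (256, 256),
    semi_major_range: tuple[float, float] = (8.0, 22.0),
    aspect_range: tuple[float, float] = (2.0, 5.0),
    background_intensity: int = 20,
    crack_intensity: int = 200,
    noise_sigma: float = 0.0,
    max_tries: int = 2000,
) -> SceneSpec:
    """Place ``n_cracks`` random non-touching ellipses by rejection sampling.

    Crack margins keep every ellipse fully inside the image so areas are
    exact; orientation is uniform on [0°, 180°).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cracks: list[CrackSpec] = []
    occupied = np.zeros(shape, dtype=bool)
    tries = 0
    while len(cracks) < n_cracks:
        tries += 1
        if tries > max_tries:
            raise SceneError(
                f"could not place {n_cracks} disjoint cracks in {shape} "
                f"after {max_tries} tries"
            )
        a = rng.uniform(*semi_major_range)
        b = max(1.0, a / rng.uniform(*aspect_range))
        margin = a + 2.0
        if 2 * margin >= min(h, w):
            raise SceneError("cracks too large for the image")
        spec = CrackSpec(
            center=(rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)),
            semi_major=a,
            semi_minor=b,
            orientation_deg=float(rng.uniform(0.0, 180.0)),
            intensity=crack_intensity,
        )
        coords = rasterize_ellipse(spec, shape)
        if coords.shape[0] == 0:
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        grown = ndimage.binary_dilation(occupied, structure=np.ones((3, 3), dtype=bool))
        if np.any(mask & grown):
            continue
        occupied |= mask
        cracks.append(spec)
    return SceneSpec(
        shape=shape,
        background_intensity=background_intensity,
        noise_sigma=noise_sigma,
        cracks=tuple(cracks),
        seed=seed,
    )


def write_ground_truth_csv(truth: list[GroundTruthCrack], path: str | Path) -> Path:
    """Sidecar ground-truth table: one row per crack (synthetic data only)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["crack", "center_x", "center_y", "semi_major", "semi_minor",
             "orientation_deg", "intensity", "area_px", "raster_orientation_deg",
             "raster_anisotropy"]
        )
        for i, gt in enumerate(truth, start=1):
            writer.writerow(
                [i, gt.spec.center[0], gt.spec.center[1], gt.spec.semi_major,
                 gt.spec.semi_minor, gt.spec.orientation_deg, gt.spec.intensity,
                 gt.area_px, f"{gt.orientation_deg:.6g}", f"{gt.anisotropy:.6g}"]
            )
    return path


def generate_dataset(
    root: str | Path,
    layout: dict[str, list[SceneSpec]],
    thresholds: dict[str, list[int]] | int,
    overwrite: bool = False,
) -> Path:
    """Write a full dataset tree ``root/<series>/img<k>_XXXthld.tif``.

    ``thresholds`` is either one integer applied to every image or a mapping
    series -> list of per-image thresholds.  Each image gets a ground-truth
    sidecar CSV.  Scanning the result with ``image_io.scan_dataset``
    reproduces the layout exactly.
    """
    root = Path(root)
    if not layout or all(len(v) == 0 for v in layout.values()):
        raise SceneError("layout is empty: nothing to generate")
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"refusing to write into non-empty {root} (use overwrite)")

    for series, scenes in layout.items():
        series_dir = root / series
        series_dir.mkdir(parents=True, exist_ok=True)
        for k, scene in enumerate(scenes):
            if isinstance(thresholds, int):
                thld = thresholds
            else:
                thld = thresholds[series][k]
            if not 0 <= thld <= 999:
                raise NamingConventionError(
                    f"threshold {thld} cannot be encoded as three digits"
                )
            image, truth = generate_crack_image(scene)
            stem = f"img{k}_{thld:03d}thld"
            save_grayscale_tiff(image, series_dir / f"{stem}.tif")
            write_ground_truth_csv(truth, series_dir / f"{stem}_groundtruth.csv")
    return root
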