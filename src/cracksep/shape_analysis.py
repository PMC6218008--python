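"""Per-crack shape descriptors from principal component analysis.

Each segmented region is summarised by the eigendecomposition of the 2x2
population covariance matrix of its pixel coordinates: the leading
eigenvector gives the crack's principal orientation (an axial angle in
[0°, 180°)), and the eigenvalue pair gives a shape-anisotropy scalar in
[0, 1] (0 = isotropic blob, 1 = perfect line).

Coordinate conventions
----------------------
Pixel coordinates are handled as (x = column, y = row).  Angles are measured
counter-clockwise from the horizontal axis of the *displayed* image, i.e.
with y pointing up; because image rows increase downward, the angle of a
direction (dx, dy) in storage coordinates is ``atan2(-dy, dx)`` reduced
modulo 180°.  Eigenvectors are unit-norm with non-negative x-component
(non-negative y if x is 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ContractViolationError
from .segmentation import CrackRegion

AnisotropyMethod = Literal["eigendiff", "ratio"]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class CrackDescriptor:
    """The full per-crack record (one CSV row).

    ``centroid`` is (x, y) in pixel units; ``eigenvalues`` = (λ1, λ2) with
    λ1 ≥ λ2 ≥ 0 in px²; ``eigenvectors`` = (v1, v2), orthonormal, each as
    an (x, y) pair; ``angle_deg`` ∈ [0°, 180°); ``anisotropy`` ∈ [0, 1];
    ``area_um2 = area_px * pixel_size**2``.
    """

    label: int
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    angle_deg: float
    anisotropy: float
    eigenvalues: tuple[float, float]
    eigenvectors: tuple[tuple[float, float], tuple[float, float]]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        return -v
    return v


def principal_axes(
    region: CrackRegion,
) -> tuple[tuple[float, float], tuple[float, float], tuple[np.ndarray, np.ndarray]]:
    """Centroid and eigenpairs of a region's pixel-coordinate covariance.

    The covariance uses divisor N (population form): a region is the complete
    pixel set of a crack, not a sample from it.  Returns
    ``(centroid_xy, (lambda1, lambda2), (v1, v2))`` with λ1 ≥ λ2 and v1, v2
    orthonormal in (x, y) coordinates.  Degenerate regions (single pixel, or
    exactly isotropic) get v1 = (1, 0), v2 = (0, 1) by convention; their
    anisotropy of 0 flags the orientation as uninformative.
    """
    coords = region.coords
    xy = np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)  # (x, y)
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    cov = centered.T @ centered / xy.shape[0]

    vals, vecs = np.linalg.eigh(cov)  # ascending
    lam1, lam2 = float(vals[1]), float(vals[0])
    if lam1 < 0:  # numerical noise on a PSD matrix
        lam1 = max(lam1, 0.0)
    lam2 = min(max(lam2, 0.0), lam1)

    if lam1 - lam2 <= _TIE_RTOL * max(lam1, 1.0):
        v1 = np.array([1.0, 0.0])
        v2 = np.array([0.0, 1.0])
    else:
        v1 = _fix_sign(vecs[:, 1].copy())
        v2 = _fix_sign(vecs[:, 0].copy())
    return (float(centroid[0]), float(centroid[1])), (lam1, lam2), (v1, v2)


def principal_angle(v1: np.ndarray) -> float:
    """Axial angle of a unit vector, in degrees in [0°, 180°).

    Measured counter-clockwise from horizontal in screen view; rows increase
    downward, so a vector pointing down-right on screen maps above 90°.
    """
    angle = np.degrees(np.arctan2(-float(v1[1]), float(v1[0]))) % 180.0
    return 0.0 if angle == 180.0 else float(angle)


def shape_anisotropy(
    lam1: float, lam2: float, method: AnisotropyMethod = "eigendiff"
) -> float:
    """Shape anisotropy from the covariance eigenvalues.

    Default ``"eigendiff"`` is (λ1 − λ2)/(λ1 + λ2): bounded in [0, 1],
    rotation- and scale-invariant, 0 for isotropic shapes and 1 for a
    perfect line.  ``"ratio"`` gives the alternative 1 − λ2/λ1 for matching
    other implementations.  Degenerate (λ1 + λ2 = 0) regions return 0.
    """
    if lam2 > lam1 or lam2 < 0:
        raise ContractViolationError(
            f"eigenvalues must satisfy lambda1 >= lambda2 >= 0, got ({lam1}, {lam2})"
        )
    if lam1 + lam2 == 0:
        return 0.0
    if method == "eigendiff":
        return (lam1 - lam2) / (lam1 + lam2)
    if method == "ratio":
        return 1.0 - lam2 / lam1
    raise ContractViolationError(f"unknown anisotropy method {method!r}")


def describe_crack(
    region: CrackRegion,
    pixel_size: float,
    anisotropy_method: AnisotropyMethod = "eigendiff",
) -> CrackDescriptor:
    """Assemble the full descriptor for one segmented crack."""
    if not pixel_size > 0:
        raise ContractViolationError(f"pixel_size must be > 0, got {pixel_size}")
    centroid, (lam1, lam2), (v1, v2) = principal_axes(region)
    return CrackDescriptor(
        label=region.label,
        centroid=centroid,
        area_px=region.area_px,
        area_um2=region.area_px * pixel_size**2,
        angle_deg=principal_angle(v1),
        anisotropy=shape_anisotropy(lam1, lam2, method=anisotropy_method),
        eigenvalues=(lam1, lam2),
        eigenvectors=((float(v1[0]), float(v1[1])), (float(v2[0]), float(v2[1]))),
    )
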