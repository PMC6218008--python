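"""Axial circular statistics over crack orientations.

Crack orientations are *axial*: a crack at 10° is the same crack at 190°.
All statistics therefore double the angles onto the full circle first
(the standard axial correction), compute circular quantities there, and
halve the resulting mean back into [0°, 180°).

Provided here: the weighted mean resultant vector (mean angle and resultant
length R, with R = 1 for perfectly aligned orientations and R = 0 for
homogeneously distributed ones), Rao's spacing test of uniformity, and the
weighted polar histogram used for the rose plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rao_table
from .errors import ConfigurationError, ContractViolationError, InsufficientSampleError

#: Resultant lengths below this are treated as 0: the mean angle is undefined.
MEAN_UNDEFINED_TOL = 1e-9


@dataclass(frozen=True)
class AngleSample:
    """Axial angles in [0°, 180°) with non-negative weights (default 1)."""

    angles_deg: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ContractViolationError("angles_deg must be a non-empty 1D sequence")
        if np.any((angles < 0) | (angles >= 180)):
            raise ContractViolationError("all angles must lie in [0°, 180°)")
        if self.weights is None:
            weights = np.ones_like(angles)
        else:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != angles.shape:
                raise ContractViolationError("weights must match angles in length")
            if np.any(weights < 0) or not np.any(weights > 0):
                raise ContractViolationError(
                    "weights must be non-negative with at least one positive"
                )
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "weights", weights)

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


@dataclass(frozen=True)
class AxialSummary:
    """Mean orientation and resultant length of an axial sample.

    ``mean_angle_deg`` is NaN when the resultant length is below tolerance
    (no preferred orientation: the mean is undefined, never silently 0).
    """

    mean_angle_deg: float
    resultant_length: float
    n: int

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean_angle_deg)


@dataclass(frozen=True)
class RaoResult:
    """Outcome of Rao's spacing test of circular uniformity."""

    U_deg: float
    n: int
    alpha: float
    critical_value_deg: float
    significant: bool


@dataclass(frozen=True)
class PolarHistogram:
    """Equal-width binning of axial angles over [0°, 180°).

    ``heights`` are the weighted bar heights (sum of weights per bin);
    ``counts`` are the raw, unweighted angle counts used to color the bars.
    Bins are half-open [lo, hi).
    """

    bin_edges_deg: np.ndarray
    heights: np.ndarray
    counts: np.ndarray


def axial_mean_resultant(sample: AngleSample, axial: bool = True) -> AxialSummary:
    """Weighted circular mean and resultant length of an angle sample.

    With ``axial=True`` (default) angles are doubled before averaging and the
    mean is halved back, so the statistics respect the 0° ≡ 180° identity.
    R = 1 means all cracks share one orientation; R = 0 means the
    orientations are homogeneously distributed.
    """
    factor = 2.0 if axial else 1.0
    theta = np.radians(factor * sample.angles_deg)
    w = sample.weights
    wsum = w.sum()
    c = float((w * np.cos(theta)).sum() / wsum)
    s = float((w * np.sin(theta)).sum() / wsum)
    r = min(math.hypot(c, s), 1.0)
    if r < MEAN_UNDEFINED_TOL:
        mean = math.nan
        r = 0.0 if r < MEAN_UNDEFINED_TOL else r
    else:
        mean = (math.degrees(math.atan2(s, c)) / factor) % (360.0 / factor)
        if factor == 2.0:
            mean %= 180.0
    return AxialSummary(mean_angle_deg=mean, resultant_length=r, n=sample.n)


def rao_spacing_statistic(angles_deg: np.ndarray) -> float:
    """Rao's U on angles already mapped to the full circle [0°, 360°)."""
    phi = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    n = phi.size
    spacings = np.diff(phi)
    wrap = 360.0 - phi[-1] + phi[0]
    t = np.concatenate([spacings, [wrap]])
    lam = 360.0 / n
    return float(0.5 * np.abs(t - lam).sum())


def rao_spacing_test(
    sample: AngleSample, alpha: float = 0.05, axial: bool = True
) -> RaoResult:
    """Rao's spacing test: is the orientation distribution uniform?

    Sorted angular gaps are compared with the equal-spacing value 360°/n;
    U is half the summed absolute deviations.  U exceeding the tabulated
    critical value rejects uniformity (a significant angular bias).  With
    ``axial=True`` the test runs on doubled angles, so uniformity means no
    preferred *axis*.  Weights are ignored: the test operates on the raw
    orientations.  Requires n >= 4 and alpha in {0.10, 0.05, 0.01}.
    """
    if sample.n < 4:
        raise InsufficientSampleError(
            f"Rao's spacing test needs at least 4 angles, got {sample.n}"
        )
    if not any(math.isclose(alpha, a) for a in rao_table.ALPHAS):
        raise ConfigurationError(
            f"alpha must be one of {rao_table.ALPHAS} (table-backed levels), got {alpha}"
        )
    factor = 2.0 if axial else 1.0
    u = rao_spacing_statistic(factor * sample.angles_deg)
    crit = critical_value(sample.n, alpha)
    return RaoResult(
        U_deg=u, n=sample.n, alpha=alpha, critical_value_deg=crit, significant=u > crit
    )


def critical_value(n: int, alpha: float) -> float:
    """Tabulated critical value of U, linearly interpolated in n.

    Beyond the largest tabulated n the last tabulated value is used.
    """
    col = min(range(len(rao_table.ALPHAS)), key=lambda i: abs(rao_table.ALPHAS[i] - alpha))
    ns = np.array(sorted(rao_table.CRITICAL_VALUES))
    crits = np.array([rao_table.CRITICAL_VALUES[k][col] for k in ns])
    return float(np.interp(n, ns, crits))


def polar_histogram(sample: AngleSample, n_bins: int = 18) -> PolarHistogram:
    """Weighted axial histogram with equal-width half-open bins on [0°, 180°).

    Bar heights sum each bin's weights (for the rose plots the weight of an
    orientation is the square root of its crack's principal eigenvalue, so
    long cracks count more); the raw per-bin counts are kept separately to
    drive the bar colormap.
    """
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    idx = np.minimum((sample.angles_deg / (180.0 / n_bins)).astype(int), n_bins - 1)
    heights = np.bincount(idx, weights=sample.weights, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return PolarHistogram(bin_edges_deg=edges, heights=heights, counts=counts)
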