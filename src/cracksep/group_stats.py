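"""Rule-based two-sample comparison of per-image total crack areas.

The compared quantity is one number per image: the total segmented crack
area in µm².  Two sample series are compared with a test chosen by a fixed
decision tree driven by normality and homoscedasticity:

1. Shapiro-Wilk on each series.  If either rejects normality (p < alpha),
   run the two-sided Wilcoxon rank-sum (Mann-Whitney) test.
2. Otherwise Bartlett's test for equal variances.  If it does not reject
   (p >= alpha), run Student's t-test (pooled variance); if it rejects,
   run Welch's t-test.

Exactly one final test is executed per comparison, and every intermediate
p-value is recorded so the routing can be audited.  No multiple-testing
correction is applied when more than two series are compared pairwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientSampleError

#: Minimum observations per series (Shapiro-Wilk requirement).
MIN_SERIES_SIZE = 3


@dataclass(frozen=True)
class SeriesAreas:
    """Per-image total crack areas (µm²) of one sample series."""

    series_name: str
    totals_um2: np.ndarray

    def __post_init__(self) -> None:
        totals = np.asarray(self.totals_um2, dtype=float)
        if totals.ndim != 1:
            raise ValueError("totals_um2 must be a 1D sequence")
        if np.any(totals < 0):
            raise ValueError("total crack areas cannot be negative")
        object.__setattr__(self, "totals_um2", totals)

    @property
    def n(self) -> int:
        return int(self.totals_um2.size)


@dataclass(frozen=True)
class ComparisonResult:
    """Routed two-sample test outcome with its full audit trail.

    ``bartlett_p`` is NaN when the route bypassed Bartlett (non-normal data).
    """

    names: tuple[str, str]
    shapiro_p: tuple[float, float]
    bartlett_p: float
    chosen_test: str  # student_t | welch_t | wilcoxon_rank_sum
    statistic: float
    p_value: float
    alpha: float


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney: exact distribution for small tie-free samples,
    normal approximation with tie correction otherwise."""
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_series(a: SeriesAreas, b: SeriesAreas, alpha: float = 0.05) -> ComparisonResult:
    """Compare two series of per-image total crack areas.

    ``alpha`` gates both the Shapiro and Bartlett routing decisions and is
    recorded in the result; all final tests are two-sided.
    """
    for s in (a, b):
        if s.n < MIN_SERIES_SIZE:
            raise InsufficientSampleError(
                f"series {s.series_name!r} has {s.n} images; at least "
                f"{MIN_SERIES_SIZE} are required for the normality test"
            )
    sh_a = float(stats.shapiro(a.totals_um2).pvalue)
    sh_b = float(stats.shapiro(b.totals_um2).pvalue)

    if sh_a < alpha or sh_b < alpha:
        statistic, p = _wilcoxon_rank_sum(a.totals_um2, b.totals_um2)
        return ComparisonResult(
            names=(a.series_name, b.series_name),
            shapiro_p=(sh_a, sh_b),
            bartlett_p=float("nan"),
            chosen_test="wilcoxon_rank_sum",
            statistic=statistic,
            p_value=p,
            alpha=alpha,
        )

    bart_p = float(stats.bartlett(a.totals_um2, b.totals_um2).pvalue)
    equal_var = bart_p >= alpha
    res = stats.ttest_ind(a.totals_um2, b.totals_um2, equal_var=equal_var)
    return ComparisonResult(
        names=(a.series_name, b.series_name),
        shapiro_p=(sh_a, sh_b),
        bartlett_p=bart_p,
        chosen_test="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
    )


def compare_all_pairs(
    series: list[SeriesAreas], alpha: float = 0.05
) -> list[ComparisonResult]:
    """All pairwise comparisons, in lexicographic pair order, uncorrected."""
    return [
        compare_series(a, b, alpha=alpha) for a, b in itertools.combinations(series, 2)
    ]
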