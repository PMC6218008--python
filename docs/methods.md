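# Methods

## Scope and model

`cracksep` quantifies *emerging* cracks: bounded, closed domains of
contrasting intensity in a 2D grayscale image (cell separations in a plant
epidermis, microcracks in a material). It deliberately does not handle long
overlapping fissures or images where crack and background intensities
interleave — in those cases no single threshold separates the cracks, and
the method does not apply. Preprocessing (8-bit conversion, channel
selection, optional contrast enhancement, median smoothing) happens before
the pipeline and determines the per-image threshold the user encodes in the
filename; the package validates but never converts input images, because a
silent conversion would change the meaning of that threshold.

## Segmentation

Thresholding is inclusive (≥ for bright cracks, ≤ for dark ones), matching
the interactive threshold tool users calibrate against. Connected
components use 4-connectivity by default — the common default of labeling
routines, and it avoids merging cracks that touch only at corners — with
8-connectivity available for matching other tools. The area window is
inclusive at both ends; regions touching the image border are kept (the
background, which always touches the border, is removed by the upper area
bound, not by a border rule). Labels are assigned in raster-scan order of
each component's first pixel so every output is reproducible run to run.

## Shape descriptors

Per-crack PCA uses the **population** covariance (divisor N) of pixel
coordinates: a region is the complete pixel set of a crack, not a sample.
Angles are reported in screen view — counter-clockwise from horizontal with
y up, so in storage coordinates θ = atan2(−Δrow, Δcol) mod 180°, half-open
range [0°, 180°). Eigenvectors carry a deterministic sign (non-negative x;
non-negative y if x = 0), and exact eigenvalue ties (single pixels,
isotropic blobs) fall back to v₁ = (1, 0), i.e. angle 0°; their anisotropy
of 0 flags the orientation as uninformative downstream.

Anisotropy defaults to (λ₁ − λ₂)/(λ₁ + λ₂): bounded in [0, 1], invariant
under rotation and scaling, 0 for isotropic shapes, 1 for a line. The
alternative 1 − λ₂/λ₁ is available (`anisotropy_method="ratio"`) for
matching implementations that use that form.

## Axial circular statistics

Orientations are axial (0° ≡ 180°), so the mean, resultant length **and**
Rao's spacing test all operate on doubled angles; applying circular methods
directly would misbehave near the wrap point. When the resultant length
falls below 1e-9 the mean angle is reported as NA, never silently 0.

Summary statistics (per image, per series) use unit weights. The √λ₁
weighting applies only to polar-histogram bar heights, where it emphasises
long cracks; bar colors encode the raw, unweighted count per bin. The
default 18 bins (10° each) over [0°, 180°) are a display choice and
configurable; bins are half-open [lo, hi).

Rao's spacing test compares U = ½ Σ|Tᵢ − 360°/n| against critical values at
levels 0.10/0.05/0.01, linearly interpolated in n between tabulated sizes
(n = 4…30 singly, then coarser up to 1000; beyond that the last value is
used). The table in `rao_table.py` was computed once by seeded Monte Carlo
simulation of the null distribution — 400,000 replicates per n up to 50 and
150,000 beyond, giving quantile standard errors well under half a degree —
rather than transcribed from print; no asymptotic approximation is used.
The test needs n ≥ 4 and ignores weights.

## Two-sample comparison

The compared quantity is the per-image total crack area in µm² (one number
per image). The routing gates (Shapiro–Wilk, then Bartlett) both use
α = 0.05 by default, configurable. The Wilcoxon rank-sum step is the
two-sided Mann–Whitney test: exact when both samples have ≤ 20 observations
and no ties, normal approximation with tie correction otherwise. All final
tests are two-sided. With more than two series every pair is compared
separately and **no multiple-testing correction is applied**; the output
file says so whenever more than one comparison is present.

## Synthetic data

The generator emulates the target image class: bright elliptical crack
domains (default intensity 200) on a dark background (default 20) with
additive Gaussian noise, clipped to [0, 255] and rounded. The ~180-intensity
gap mirrors the strong contrast the protocol demands of suitable images;
with noise σ up to ~10 a mid-gap threshold still recovers cracks nearly
perfectly. Ellipses are used because their orientation and anisotropy have
closed-form ground truth; the recorded ground-truth orientation/anisotropy
are computed from the **rasterized** pixel set so recovery tests compare
like with like. Cracks are required to be pairwise disjoint and
non-touching under 8-connectivity, enforcing the closed-domain assumption.

What the generator does not emulate: cell-wall texture, staining
heterogeneity, uneven illumination, and cracks with concave or branched
outlines. Passing recovery tests therefore demonstrates correctness of the
segmentation→PCA→statistics chain under the method's stated assumptions,
not robustness to real-microscopy artifacts — the protocol's own
image-suitability check remains the user's responsibility.

## Numerical and design choices

- Thresholds parse from the filename in [0, 999] but must lie in [0, 255]
  at segmentation time.
- CSV floats are written at 6 significant digits; round-trips are tested at
  that precision. Text outputs are byte-stable across reruns; PDF metadata
  (timestamps) is not.
- Problem sizes in the test suite (images up to 128×128, 50-scene recovery
  sweeps, 200–2000 Monte-Carlo replicates for calibration checks) keep the
  full suite around ten seconds while leaving Monte-Carlo standard errors
  several times smaller than the asserted tolerance bands.
- The per-series Rao test is skipped (reported NA) when a series has fewer
  than 4 cracks; the cross-series comparison requires ≥ 3 images per
  series (the Shapiro–Wilk minimum).
- Figures default to vector PDF; PNG is available for raster-only contexts.

## Known limitations

Merged cracks are not split (no watershed); boundaries are whole-pixel; the
orientation comparison across images assumes consistent acquisition
orientation (no registration is performed — the CLI only documents the
assumption); and p-values from many pairwise series comparisons are
uncorrected by design.
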