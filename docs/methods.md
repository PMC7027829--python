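# Methods

## The model

Spectral diversity is cast as multivariate variance. Let **Y** = [y_ij] hold
the positions of *n* pixels (rows *i*) along *p* spectral features (columns
*j*) — original reflectance bands, vegetation indices, or principal-component
scores. All quantities derive from squared deviations:

* from the global feature means: s_ij = (y_ij − ȳ_j)², summing to the total
  sum of squares SS_γ and the regional diversity SD_γ = SS_γ/(n−1);
* from community centroids to the global means: s_kj = (ŷ_kj − ȳ_j)², each
  weighted by the community size m, summing to SS_β and SD_β = SS_β/(n−1);
* from pixels to their community centroid: s_ijk = (y_ijk − ŷ_kj)², summing
  per community to SS_α,k and SD_α,k = SS_α,k/(m−1), and overall to SS_α.

The ANOVA identity SS_γ = SS_β + SS_α holds exactly when every community has
the same pixel count m — this is the method's one structural assumption, and
the reason rarefaction exists (below). Communities are square image tiles
standing in for vegetation inventory plots; their side length is a user
parameter (`plot_size_px`), with partial edge tiles discarded.

Contribution indices are shares of the corresponding sum of squares:
LCSD_γ,i = SS_γ,i/SS_γ per pixel, LCSD_β,k = SS_β,k/SS_β per community,
FCSD_γ,j = SS_γ,j/SS_γ, FCSD_β,j = SS_β,j/SS_β and FCSD_α,jk = SS_α,jk/SS_α,k
per feature. Each family sums to 1; a share whose denominator is zero
(e.g. FCSD_β when all communities have identical centroids) is reported as
undefined (None/NaN), never as 0/0.

Because type-1-scaled PCA scores are an isometry of the centered data, every
SS, SD and LCSD quantity is identical whether computed on the original bands
or on the full set of PCs, and FCSD_γ of PC j equals its relative eigenvalue.
FCSD values on truncated or band features are basis-dependent by design —
that is their point.

Note that this beta is *non-directional* — the dispersion of community
centroids — not a turnover/nestedness decomposition, and no significance
testing of LCSD values is attempted.

## Preprocessing defaults

| parameter | default | meaning |
|---|---|---|
| `drop_windows` | 1340–1455, 1790–1955 nm | atmospheric water-vapour bands |
| `keep_range` | 400–2400 nm | outside it detector noise dominates |
| `sg_order`, `sg_window` | 3, 7 | Savitzky–Golay polynomial order / window (bands) |
| `ndvi_threshold` | 0.8 | pixels with NDVI < 0.8 are masked (equality kept) |
| `red_wl`, `nir_wl` | 670, 800 nm | NDVI bands, nearest-band snapping |
| `shade_mask` | off, quantile 0.2 | optional NIR-quantile shadow mask |

The NDVI band wavelengths follow the standard broadband definition and are
configurable per sensor. Brightness normalization divides each valid pixel
spectrum by its L2 norm, removing per-pixel illumination scaling — the
property the downstream variance accounting relies on. The shade mask is a
simple NIR-quantile threshold (shadowed canopy is dark in the NIR); it is
off by default since shadow removal has little effect on the partition in
closed-canopy scenes.

Savitzky–Golay smoothing is applied independently within each contiguous
wavelength segment, so the polynomial fit never bridges the >100 nm holes
left by water-band removal; segments are detected where the band spacing
exceeds 1.5× the median spacing. At segment edges the filter fits a
least-squares polynomial to the terminal window (scipy's `interp` mode)
rather than padding: reflection padding would break the filter's defining
property of reproducing polynomials up to the fit order exactly, which the
test suite asserts.

## PCA features

Covariance PCA (divisor n−1) on the brightness-normalized reflectance, full
SVD, scores = centered data × orthonormal eigenvectors (type-1 scaling).
Component count is an explicit `n_components` parameter or a cumulative
variance target (`variance_target`), mutually exclusive; visual inspection of
component maps — the usual practice for excluding acquisition artefacts —
cannot be automated and is deliberately out of scope. Eigenvector signs are
fixed by making each column's largest-magnitude element positive (ties to
the lowest feature index) so repeated runs are bit-identical; signs do not
affect any SS/SD/LCSD/FCSD value. When both preprocessing and PCA run in the
pipeline, the PCA is fit once on all valid pixels and rarefaction subsamples
the scores, not the fit.

## Rarefaction

Masking leaves plots with unequal usable-pixel counts, violating the equal-m
assumption. `rarefied_partition` takes m_min = the smallest count over
retained plots (optionally dropping plots under a `min_fraction` of the
largest count first; off by default), draws m_min pixels per plot without
replacement, partitions, and repeats (default 30), aggregating elementwise
by mean (default) or median. Per-pixel LCSD_γ is averaged only over repeats
in which the pixel was drawn. Randomness is one master seed; each
(repeat, community) pair gets an independent substream via a counter-keyed
seed sequence, so results do not depend on iteration order and rerunning
with the same seed is bit-identical.

## Region merging

Total sums of squares of adjacent regions sharing one feature space can be
added, and the joint SD divides by the total pixel count minus one
(`merge_regions`). This is exact only when each region's deviations are
taken from the joint mean; regions centered on their own means understate
the joint SS. The function documents this caveat and leaves the centering
convention to the caller rather than silently re-centering.

## Numerical choices

* Deviations are computed against explicitly materialized column means
  (two-pass), never via E[x²]−E[x]², keeping the additive identity stable;
  `partition_all` asserts SS_γ = SS_β + SS_α to a relative 1e−9 and raises
  rather than returning inconsistent numbers.
* Global column sums use exactly-rounded summation (`math.fsum`), which makes
  SS_γ bitwise invariant under any permutation of the pixels — a property the
  method guarantees mathematically and the simulator tests assert exactly.
* Community centroids are computed relative to a per-community reference
  pixel (ŷ_k = y₀ + mean(y − y₀)), so a community of identical pixels has
  exactly zero within-community deviations, not rounding dust.
* Degenerate inputs: SS_γ = 0 (all pixels identical) yields zero diversities
  with undefined contribution indices; q = 1 yields SS_β = 0 with LCSD_β
  undefined; m = 1 raises unless SS-only output is requested.

## The simulator

The synthetic-landscape generator reproduces a two-scenario design on a
25 × 25-pixel region of 25 communities (5 × 5 pixels): community species
drawn with probabilities 0.60/0.35/0.05 from three species, each pixel
assigned an individual's spectrum (uniform over 5 individuals per species,
with replacement) — the *high-β* scenario — and a uniform permutation of
pixel positions that preserves the spectrum multiset exactly — the *low-β*
scenario. All draws (species per community, individual per pixel,
permutation) use separate substreams of one seed.

Leaf spectra are parametric stand-ins on a 400–2400 nm, 10 nm grid: a smooth
continuum (dark visible, logistic red-edge rise to a NIR plateau, gentle
SWIR decline) attenuated by Gaussian absorption features for pigments
(~450, ~680 nm) and leaf water (~1450, ~1940 nm). The three species
archetypes differ in plateau height, red-edge position and water-feature
depth, spaced so that interspecific spectral distances clearly exceed
individual-level variation (depth and amplitude jitter, `individual_sd`
default 0.04) — the regime in which a species-pure landscape is
β-dominated, matching published partitions of comparable temperate-forest
designs (β ≈ 84% of γ). All spectra pass an NDVI ≥ 0.8 vegetation mask, so
the full preprocessing chain can run on simulated cubes.

What the generator does *not* emulate: canopy structure and viewing-geometry
effects (BRDF), sensor noise and striping, mixed pixels, shadows, and
radiative-transfer realism of leaf optics. Passing tests on simulated
landscapes therefore demonstrate the correctness of the variance accounting
and the workflow plumbing, not the ecological fidelity of any particular
absolute SS value; on real imagery the preprocessing choices (masking
threshold, component selection) dominate the absolute numbers.

The scenario Monte-Carlo in the tests and the acceptance script partitions
*brightness-normalized* reflectance, as the workflow prescribes: the
generator's per-individual amplitude jitter is exactly the per-pixel
brightness variation the normalization step exists to remove, and on raw
reflectance it would leak into the within-community component.

## Problem sizes

The test suite and acceptance script run on the simulator's native design
(625 pixels × 201 bands, 25 plots), random matrices up to n = 200 for the
distance oracle, 1000 random instances for the additivity check and 100
seeded landscape pairs for the Monte-Carlo — the full suite completes in
well under a minute on one CPU.

## Known limitations

* GeoTIFF support is pixel-data + sidecar wavelengths; CRS metadata is not
  preserved (no GDAL dependency). ENVI `map info` carries the affine
  transform.
* `merge_regions` implements the stated additive rule; it is the caller's
  responsibility to ensure a common centering (see above).
* Unequal-m inputs are only handled by rarefaction; no weighted/unbalanced
  ANOVA variant is offered, keeping the decomposition exact.
* The spectral-feature basis affects FCSD (by design) and, when truncated,
  all absolute SS values; comparisons across regions should fix the basis.
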