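# Methods

This note documents the models, parameter choices and numerical conventions
behind histokurt, and what its synthetic-data experiments do and do not
establish about real tissue.

## Stain model and deconvolution

Light transmission through a two-stain section follows Beer–Lambert in
optical density (log base 10): `OD(px) = c_h(px) · v_h + c_e(px) · v_e`,
with `v_h, v_e` unit 3-vectors in RGB-OD space and nonnegative
concentrations. `rgb_to_od` floors intensities at 1 count so black pixels
stay finite; the blank-field intensity `I0` defaults to 255 and is a config
override rather than being estimated per slide, because frozen sections
rarely contain reliable blank regions.

Stain vectors are estimated per slide by the Macenko procedure: discard
pixels with OD norm below β = 0.15, project the rest onto the two leading
eigenvectors of the (biased) OD covariance, and take the directions at the
α = 1 and 99 angle percentiles, sign-corrected to the nonnegative octant
and ordered so hematoxylin is the blue-heavy vector. β and α are the
method's published defaults. Percentiles use the inverted-CDF convention so
the estimate is exactly invariant to pixel order and duplication.
Degenerate inputs raise explicit errors: fewer than 100 tissue pixels
("insufficient tissue") or an effectively rank-1 OD cloud.

Unmixing solves the per-pixel least-squares problem via the pseudoinverse
of the 2×3 basis and clips negatives at zero. Per-pixel nonnegative least
squares is available behind a flag; it differs from clip-at-zero only where
the unconstrained solution leaves the nonnegative cone (near-background or
single-stain pixels), by less than 0.02 concentration units on tissue.

Cross-slide normalization rescales each channel so the slide's 99th
percentile over tissue pixels equals 1.0. The reference is per slide — that
is the only reading under which "each slide's percentile equals the target"
can hold exactly — and is serialized to YAML so cohorts can be normalized
incrementally. The percentile (not the max) is used because frozen sections
show bright eosin tails. All shape statistics (skewness, kurtosis,
histogram energy/entropy with bins scaled to the target) are invariant
under this per-channel affine scaling; the pipeline's central feature is
therefore insensitive to staining intensity differences between slides,
which the test suite checks end-to-end at a 0.7× stain-intensity ratio.

"Intensity" is taken to mean the normalized deconvolved concentration, not
a re-rendered 8-bit channel image; the concentration scale is the one on
which the Beer–Lambert model is linear.

## Segmentation and the perinuclear compartment

Nuclei: Gaussian smoothing (σ = 1 px) → Otsu threshold (or fixed) → fill
holes → remove objects under 10 µm² → Euclidean distance transform → local
maxima at least 3 µm apart as markers → watershed on the negative distance
within the foreground. Labels are renumbered in raster order of centroids
so output is reproducible. All defaults are exposed in config; none of
them is prescribed by the underlying study, which names only watershed. A
blank channel yields an empty mask with a warning, not an error. Objects
touching the tile border are kept but flagged, since excluding them would
bias against vacuole-rich tiles.

Cytoplasm: every background pixel within 4 µm (Euclidean, in physical
units) of a nucleus is assigned to its *nearest* nucleus; exact ties go to
the lower label. This label-expansion construction, rather than independent
dilation, guarantees disjoint compartments and implements the shrinkage of
rings between adjacent nuclei at the equidistant line. The implementation
computes one distance transform per label (exact tie semantics, O(K·HW));
at the tile sizes used here this costs milliseconds.

## Features

Twelve statistics per region, conventions fixed for bit-reproducibility:
sample SD (n−1); IQR from linear-interpolation percentiles; MAD unscaled;
skewness `m3/m2^1.5` and *excess* kurtosis `m4/m2² − 3` with biased moment
estimators (the common scientific-software default; the convention only
shifts kurtosis by a constant and cannot change cutpoint or Cox results);
histograms with 32 equal-width bins over (0, 2× normalization target) with
out-of-range values clipped into the end bins, energy `Σp²` and entropy
`−Σp ln p`. Fixed bins keep energy/entropy comparable across cells.
Regions with fewer than 8 pixels or constant values are dropped with a
logged reason — fourth-moment estimates below that are meaningless — and
drop counts always reconcile with detected-cell counts.

Patient aggregation is the median over all of the patient's cells pooled
across patches and slides (not a median of patch medians), making it
permutation- and duplication-invariant. The spatial heatmap bins cell
centroids on a grid (step = bandwidth/4) padded by 4σ and smooths with a
Gaussian kernel, so each density integrates to its cell count; the
low-kurtosis subset is cells at or below the 10% quantile of
`kurtosis_hC` by default.

## Survival stage

Cox models maximize the Efron-corrected partial likelihood (ties are
frequent at day resolution) by Newton iterations with tolerance 1e−9,
via lifelines; Wald 95% CIs. The univariate screen and stepwise selection
run on cohort-standardized features — p-values are unchanged and the
Newton steps stay well-scaled for features with tiny raw variance — while
cutpoints and KM groups use raw feature values. Stepwise selection is
bidirectional AIC descent from the full candidate model (candidates =
univariately significant features at p < 0.05 plus age, gender, stage);
the pipeline caps the stepwise candidate list at the 10 smallest screen
p-values and backs off further if the full model is unfittable, which
small synthetic cohorts (48 collinear features, tens of patients) require.
Gender enters as a 0/1 indicator and stage as ordered numeric 1–4.

The maximally selected rank statistic uses log-rank (Savage) scores
`a_i = δ_i − Λ̂(t_i)` (Nelson–Aalen cumulative hazard). For a candidate
cutpoint μ, `S(μ) = Σ_{x_i≤μ} a_i` is standardized by its permutation mean
and variance; candidates are observed values whose groups both hold at
least minprop = 0.1 of patients (the cited implementation's default), and
ties in the maximum resolve to the smaller cutpoint. The familywise
adjusted p-value is the Brownian-bridge crossing approximation
`p(b) ≈ φ(b)(b − 1/b)·log[ε₂(1−ε₁)/(ε₁(1−ε₂))] + 4φ(b)/b`, floored at the
pointwise two-sided normal p (the adjustment can never be
anti-conservative relative to the naive test) and capped at 1. A seeded
permutation mode validates the approximation. Measured calibration: null
rejection ≈ 3–4% at α = 0.05 (n = 200), i.e. conservative-to-nominal.
Cutpoints are computed per endpoint; no multiple-testing correction is
applied across the 48 features, mirroring the analysis this package
reimplements (a deliberate, documented omission).

## Synthetic data: what it emulates, what it does not

Scenes are a Beer–Lambert forward model of clear-cell-like tissue on a
256×256 grid at 0.5 µm/px (384×384 for well-separated 50-nucleus recovery
scenes): elliptical nuclei (semi-axes 3–5 µm, hematoxylin concentration
1.0), a 6 µm cytoplasm band, additive truncated-Gaussian concentration
noise (SD 0.02), and circular lipid vacuoles (radius 0.8–2 µm, both
channels ≈ 0) punched into the band — never into nuclei, keeping
segmentation difficulty constant across vacuole fractions — until a target
area fraction is clear.

The non-vacuole cytoplasm carries gamma-distributed multiplicative
staining texture (mean 1, relative SD 0.9, truncated at 3× so rendered
optical densities stay within the 8-bit-recoverable range), independent
per channel. This texture is load-bearing in two ways. First, it makes the
OD point cloud span hematoxylin-dominant to eosin-dominant directions, as
real tissue does, which is what lets the Macenko percentile estimator work.
Second, it fixes the direction of the vacuole–kurtosis relation: a binary
uniform-band/vacuole mixture has U-shaped kurtosis in the vacuole fraction
(minimum at 0.5), whereas with a broad stained component the clear-pixel
spike adds peakedness monotonically. With these defaults the band's excess
kurtosis rises monotonically over vacuole fractions 0.1–0.6 (≈ 0.4 → 4.1,
10-seed means) — the direction required for the biomarker to mean what it
means in tissue, confirmed numerically rather than assumed, since the
underlying lipid-to-kurtosis mechanism is only a verbal hypothesis.

Survival simulation is exponential proportional hazards with independent
exponential censoring — one parameter fewer than Weibull, and the PH
structure is all the Cox stage consumes. The end-to-end cohort (20
patients × 4 tiles, vacuole fractions 0.15 vs 0.55, log hazard ratio −1.2
per SD of true band kurtosis, baseline hazard 0.4, censor rate 0.05)
yields events in both kurtosis groups so the dichotomized hazard ratio is
finite. The cohort generator writes all-ones tumor masks: the scenes are
entirely tumor, and an OD-based tissue heuristic would otherwise
preferentially discard vacuole-rich (sparsely stained) patches and bias
the cohort.

Not emulated: realistic chromatin or stromal texture, necrosis/fibrosis,
overlapping nuclei beyond watershed separability, scanner optics and noise,
whole-slide scale, and any tumor/non-tumor classification problem (the
synthetic scenes are all tumor). Passing tests therefore demonstrate that
the measurement chain is correct and well-calibrated on its declared
forward model — not that the biomarker is prognostic in real cohorts, which
requires real slides and outcomes.

## Problem sizes and runtime choices

Recovery experiments use the sizes their claims name: 200 random vectors
for statistic-oracle equivalence (1e−10), 10⁶ uniform draws for the −1.2
kurtosis closed form, 10 seeds × 50 nuclei for segmentation, 100
replicates at n = 1000 for Cox recovery, 500 null replicates at n = 200
for cutpoint calibration, and the 20×4 cohort end-to-end. The stepwise
selection-consistency experiment runs 20 replicates at n = 500. The
acceptance script reuses the same designs with 3–5 scene seeds so a full
from-scratch reproduction stays within a few minutes on one CPU.

## Known limitations

- The tumor-region classifier of the original analysis is replaced by
  masks / external verdicts / an OD heuristic; no neural network is
  trained or run.
- Whole-slide formats are out of scope; the pipeline operates on
  pre-extracted tiles.
- The Lausen-type adjusted p-value is an asymptotic approximation;
  at very small n prefer the permutation mode.
- Whether the original univariate screen used continuous or dichotomized
  features for all 48 covariates is unstated; this implementation screens
  on continuous (standardized) features and dichotomizes only the
  configured cutpoint feature.
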