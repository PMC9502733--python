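# Methods

This note documents the models, estimators and numerical choices behind
`ploidycal`, and what the synthetic benchmark does and does not show
about real data.

## Measurement model

### Integrated optical density (IOD)

Under stoichiometric PI staining, summed fluorescence over a nucleus is
proportional to its DNA content. The estimator is

```
ID = Σ_{p ∈ O} I(p) − |O| · BkgInt
```

with `BkgInt` the mean intensity of the local background set `B`: pixels
belonging to no object, within Euclidean distance `D` of the measured
object, and farther than `d` from **every** object. Excluding the
proximity halo of *all* objects (not only the measured one) prevents a
bright neighbor from inflating the background estimate. Distances are
exact Euclidean distances between pixel centers (computed by distance
transform; verified in tests against full pairwise enumeration).

* `D = 35 px` — the average object size at the source magnification of
  0.1625 µm/px, large enough for a stable mean, small enough to track
  local background drift (dye accumulation, uneven illumination).
* `d = 5 px` — the distance at which the bulk of the object-proximity
  intensity effect has decayed.
* Empty annulus (an object fully enclosed by neighbors): the estimator
  falls back to the tile-level background (mean of all unlabeled pixels
  farther than `d` from any object) and logs the event. Tile-level
  background is known to be inferior in the presence of dye
  accumulation, but it is the only defined fallback.
* `ID` may be negative (dim object on bright background) and is not
  clipped.

Two invariances characterize the estimator and are enforced by tests:
adding a constant to every pixel leaves `ID` unchanged; scaling all
pixels by α scales `ID` by α (the linear-response property that
justifies a linear ICM→FCM transfer function).

### Area and granularity

Area is the raw pixel count of the label (the ICM analog of the
forward-scatter signal). Granularity — the analog of side scatter,
which responds to internal structure — is the sum of an edge-strength
image over the object after eroding its mask by the operator's kernel
radius (radius 1 for DMG/Roberts/Prewitt/Sobel, 2 for Canny whose
σ = 1 Gaussian spreads edges). The erosion suppresses the object's
outline edge so the value reflects internal texture, and the *sum* (not
mean) matches the integral character of the scatter signal. Gradients
are computed on raw intensities; for linear operators the result is
background-shift invariant anyway. Canny hysteresis thresholds are
derived per image from Otsu's threshold on the Sobel magnitude
(high = t_otsu, low = t_otsu/2) since no canonical values exist; its
granularity value counts edge pixels and is intensity-scale invariant.

## Granularity-operator selection

The best side-scatter model is chosen by clustering robustness: for each
sample and operator, the gap statistic (uniform bounding-box reference,
`B = 50` reference draws, seeded k-means++ with 10 restarts, `k` in
1..6, one-standard-error rule) estimates the population count in the
standardized (area, granularity) plane. An operator disagreeing with the
per-sample majority vote scores a fault; the operator with the highest
match ratio wins, with DMG > Prewitt > Roberts > Sobel > Canny
precedence on ties. `k` range and `B` are conventional choices; axes are
standardized because area and granularity have incomparable units. Both
the match ratio and the raw fault count are reported.

## PCA decorrelation

A per-sample PCA over (area, DNA content, granularity) serves two
purposes: confirming the three measurements are nearly independent, and
supplying noise-filtered coordinates. **The PCA operates on the raw
covariance by default** (`scaling="none"`). This is deliberate: the
three features' variances differ by orders of magnitude (DNA ≫
granularity ≫ area in typical units), so with weak correlation each
eigenvector aligns almost perfectly with one feature axis — the
near-identity loading structure the method relies on. Scaling to unit
variance would make the spectrum nearly degenerate, and the eigenbasis
of a near-identity correlation matrix is numerically arbitrary: any
nonzero correlation then yields fully mixed components. Unit-variance
mode remains available for exploration.

Components are identified with features by largest absolute loading
(row-wise), never by index; the sign convention makes each component's
dominant loading positive. The "denoised" DNA and area coordinates are
the matching component scores mapped back to original units (score ×
scale + mean) — for exactly uncorrelated input this is the identity, in
general it discards the variance carried by the other components.
`correct` refuses to proceed when DNA and area map to the same
component (the two measurements are then inseparable) and the sample is
quarantined.

## Population identification

Fuzzy c-means (Bezdek's alternating optimization) with `c = 3` (debris,
2N, 4N), fuzzifier `m = 2`, tolerance `1e-5` on the maximum center
shift, ≤ 300 iterations, centers initialized from `c` distinct seeded
data points. A point coincident with a center receives membership 1.
Soft memberships let the pipeline drop ambiguous objects: the default
uncertainty filter keeps objects whose maximum membership is ≥ 0.6
(configurable; the margin and entropy alternatives were considered and
max-membership retained as the simplest monotone choice).

The clustering plane is (denoised area, denoised DNA) with **both axes
divided by the same factor** (the DNA standard deviation). This
preserves the raw-unit aspect ratio, in which DNA content dominates the
Euclidean metric — per-axis z-scoring was evaluated and rejected, since
it inflates within-population area scatter to parity with the DNA gaps
and c-means then splits the dense 2N population along the area axis
instead of isolating debris (label recovery drops from 100% to ~71% on
synthetic samples). Clusters are named debris/2N/4N by ascending DNA
coordinate of their centers (membership-weighted means in original
units), and a sample is rejected as mis-clustered when the 4N/2N center
ratio falls outside [1.5, 2.5]. FCM event streams pass through the same
gating in one dimension, so both modalities are peak-estimated
identically.

## Peak estimation

Histograms use 256 half-open bins over the per-population data range
(flow-cytometer channel resolution; the last bin is closed). Two peak
estimators:

* `bin_peak` — center of the modal bin; ties resolve to the lower bin
  and are logged.
* `gauss_fit` — mean of `A·exp(−(x−μ)²/2σ²)` fitted by least squares to
  the binned counts, initialized at (modal count, modal center, sample
  SD). On optimizer failure the location falls back to the inner-90%
  trimmed mean and the estimate is flagged.

Fits are restricted to cluster-assigned members of each population.
Across synthetic cohorts the fitted-peak ratio consistently shows a
several-fold smaller between-sample SD than the modal-bin ratio (the
bin estimator inherits quantization noise of order bin-width/peak); the
suite asserts the ordering across 20 cohort seeds.

## Calibration

For each sample, the through-origin least-squares scale mapping its
(2N, 4N) ICM peaks to the FCM peaks is
`s = (f₂i₂ + f₄i₄)/(i₂² + i₄²)`. The naive transfer is the cohort mean
(and SD) of these scales. The pooled regression `fcm = a·icm + b` uses
both peaks of every sample as points by default (`2N_only` mode
available, for workflows that prioritize the 2C peak); it reports RMSE
(`√(Σr²/n)`), R², and Shapiro–Wilk residual normality. Nonlinear
transfer functions are out of scope by design: a nonlinear map could
distort the 2N:4N relation that anchors the whole comparison.

Low-intensity outlier slides are flagged when the modified z-score
(0.6745·(x−median)/MAD) of the log 2N ICM peak falls below −3.5 — a
robust automation of exclusion-by-visual-inspection; a manual exclusion
list can augment it, and with zero MAD or fewer than 5 samples only the
manual list applies. The regression is reported both with and without
flagged samples.

## Synthetic data generator

The generator emulates a healthy-blood ploidy cohort measured by both
instruments. Per cell, the *true* DNA content is exact — `mu_2N` for 2N
cells, `2·mu_2N` for 4N (the 1:2 relation holds identically), uniform
on (0, 0.7·mu_2N) for debris — and each modality observes
`scale · content · (1 + ε)` with independent ε ~ N(0, cv) truncated at
zero, so within-population marginals are Normal(μ, cv·μ) and the two
modalities are correlated views of the same cells. Defaults: 2000
cells/sample, cv 0.03–0.05 (chosen to produce histograms of realistic
sharpness; published per-population CVs for this preparation do not
exist), 25% 4N, 10% debris, `fcm_scale = 0.04` (placing 2N near channel
200 of a 10-bit range), `icm_scale = 1`. Cohorts share one `fcm_scale`
(the reference instrument is untouched) while per-sample `icm_scale`
jitter and sub-unity outlier factors model exposure and bleaching
differences between slides.

Non-DNA features are deliberately only weakly informative, mirroring
the weak cross-correlations measured on real stained slides: area
shifts mildly by population (4N 1.3×, debris 0.5×, CV 0.15) and
granularity depends on population only through a texture factor (4N
1.5×, debris 0.6×, CV 0.35), never on the per-cell DNA draw.

Image scenes render cells as disks with zero-mean sinusoidal internal
texture on an integer background (optionally ramped left-to-right);
per-pixel increments are rounded to integers and the recorded
ground-truth IOD is their exact integer sum, so noise-free scenes admit
bit-exact end-to-end verification of the feature extractor. Object
placement is rejection-sampled to a minimum separation with a bounded
retry count.

**What the generator does not model** — and hence what passing tests do
not certify on real data: optics/PSF blur, JPEG artifacts, doublets and
aggregates, the S-phase continuum between 2N and 4N, aneuploid
populations, dye-bleaching kinetics, and segmentation errors (masks are
taken as given; a naive Otsu fallback exists only as CLI convenience).
Real 17-sample cohort statistics (peak-ratio SDs, regression
coefficients) therefore cannot be reproduced numerically here; what the
benchmark establishes is the correctness of each estimator against
oracles and the qualitative cohort-level behavior: theoretical ratio
recovery, scale recovery on homogeneous cohorts, and the breakdown of a
single linear transfer (structured, non-normal residuals) under
per-slide intensity heterogeneity.

## Determinism and problem sizes

Every stochastic step (generator, k-means, c-means initialization, gap
reference draws) is seeded; cohort runs derive per-sample sub-seeds
from one root seed via `SeedSequence`, and a fixed configuration
reproduces byte-identical reports. The default benchmark sizes — 17
samples × 2000 cells, 100 oracle scenes at 64×64, 20-seed replicate
studies — were chosen so the complete suite and the acceptance script
each run in well under a minute per study on a single core while
keeping Monte-Carlo standard errors far below the asserted tolerances.
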