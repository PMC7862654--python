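# Methods

## The imaging model

Secondary-ion mass spectrometry (SIMS/NanoSIMS) images a specimen by
rastering a focused primary-ion beam (Cs⁺ or O⁻) over the surface; each
scan sputters a few nm of material and the emitted secondary ions are
mass-analyzed pixel by pixel.  Repeating the scan through the cell depth
produces a multi-channel image stack — a 4D ion-count cube indexed
(z-slice, mass channel, row, column).  The forward model implemented in
`ibt.simulate` is

I(x, y, z) = (P_out / P_in) · [O(x, y, z) ⊗ PSF(x, y)] · N(x, y, z)

with:

- **O** — the true object: point emitters, uniform half-planes (edge
  targets) and uniform-density spheres (isotope-doped silica nanotags).
  Spheres are rasterized by the analytic chord length of each supersampled
  (3×) pixel column through the sphere, restricted to the slab the current
  scan collects from; this avoids aliasing in sub-pixel colocalization
  tests.
- **PSF** — separable: a 2D Gaussian laterally whose width is the beam
  width expressed as FWHM (σ = FWHM / 2.3548; "width" is taken as FWHM,
  the field convention for beam size), and a uniform box axially over
  `axial_extent_nm` (default 100 nm), because the beam extracts ions from
  up to ~100 nm below the currently ablated layer while each scan strips
  only ~5 nm.  Each slice therefore integrates object content over
  [z·Δz, z·Δz + axial_extent).  A decaying axial profile would also be
  defensible; the uniform box is the simplest model consistent with the
  sub-surface extraction and is exposed as a parameter.
- **N** — i.i.d. multiplicative gamma noise, shape k, scale 1/k, so the
  mean is pinned at exactly 1 and the variance at 1/k.  Pinning the mean
  keeps the extraction efficiency interpretable as an expected-count
  scale.  Default k = 3 (relative fluctuation ≈ 58 %, a realistically
  harsh low-count SIMS regime); the shape is configurable because real
  instruments vary.
- **P_out/P_in** — ion extraction efficiency, default 0.03: only ~3 % of
  sputtered material registers as counts.
- Additive background is omitted by default (background is very low in
  ion-beam imaging); an optional Poisson dark-count floor exists for
  threshold testing.

Pixel geometry: Δx = A_scan,x / N_x.  The sampling rule Δx, Δy ≤ Δw_beam
is exposed as a `nyquist_ok` predicate.  The canonical cellular scan —
20 µm at 256 × 256 — gives Δx = 78.125 nm (displayed as 78 nm; internal
values are never rounded), adequate for a 100 nm beam.

Coordinates are 0-based and pixel-center: pixel (i, j) sits at
((j + 0.5)·Δx, (i + 0.5)·Δy) nm.  Axis order is (z, channel, y, x)
everywhere.  On disk a stack is one multi-page grayscale TIFF per mass
channel (16-bit unsigned for integer counts, 32-bit float otherwise) plus
a JSON sidecar holding geometry, channel labels and the seed; required
sidecar fields are never silently defaulted on read.

## Preprocessing

**Sliding-window binning** sums n consecutive slices advancing one slice
at a time, so the output is only n − 1 slices shorter and the axial
sampling is retained while the SNR grows.  n = 10 is the default working
point; the binning is exact integer arithmetic for integer stacks.

**SNR** is reported as 20·log₁₀(μ_signal / RMS(background)), the RMS being
the root-mean-square deviation of background pixels from their mean.  The
deviation term is squared under the radical; a version without the square
is identically zero and cannot produce finite dB values, so the RMS
reading is the only usable one.  Zero background deviation raises an
explicit "undefined SNR" error rather than returning infinity.

**Drift registration**: lateral stage/beam drift during an hours-long
depth scan is estimated from a fiducial channel (e.g. a 2–6 µm iron
microparticle imaged alongside the cell) by cross-correlation of every
slice against slice 0, with sub-pixel refinement via upsampled-DFT peak
location (scikit-image's phase correlation; an integer-only mode and a
previous-slice chaining mode are flags).  Slice 0 is the fixed reference
to avoid error accumulation.  The same negated trace is applied to every
channel; shifted-in pixels are zero-filled, never fabricated.

## Deconvolution reconstruction

Each binned section is deblurred by the multiplicative Lucy–Richardson
update

Oⁿ⁺¹ = Oⁿ · [ (I / (Oⁿ ⊗ PSF)) ⊛ PSF ]

(⊗ convolution, ⊛ correlation with the flipped kernel), run in 2D per
binned slice; a true-3D iteration is out of scope since sections are
processed independently.  Numerical choices:

- Reflective boundary padding for both convolution and correlation.  With
  a symmetric normalized kernel the resulting operator is symmetric, so
  total flux is conserved *exactly* per iteration and the estimate stays
  non-negative; the tests assert conservation at 1e-6 relative.
- The ratio denominator is floored at 1e-12 to avoid 0/0 in dark regions.
- Default 5 iterations (middle of the useful 3–10 band; more iterations
  amplify noise).
- The deconvolved section is lightly post-filtered (2×2 Gaussian,
  σ = size/2.355 px, or a median filter), applied per slice after the LR
  iterations.

The **blind PSF** is parametric, not estimated from data: beam current is
recorded for every acquisition and maps to a PSF FWHM log-linearly from
(0.2 pA → 100 nm) to (4 pA → 200 nm), clamped to [100, 200] nm outside.
Only the endpoints are physically calibrated; log-linearity in current is
a design choice, exposed in config, and every run logs the width used.
An explicit width override exists (the simulation-validation preset is
120 nm).

## SILM — localization reconstruction

Each thin scan captures a sparse, stochastic subset of an object's ions;
the depth axis plays the role that time plays for blinking fluorophores
in localization microscopy.  The pipeline: 3× bilinear upsampling
(intensities are interpolated as a field, not redistributed as counts,
matching the Fiji-style bilinear step; thresholds are computed on the
upsampled field consistently) → per-slice detection at a robust threshold
(median + k·1.4826·MAD, k = 4; MAD is robust to the sparse bright events
themselves; candidates must also exceed `min_counts` = 3) → least-squares
2D Gaussian fit in a ~2·FWHM window.

The fit refines its candidate rather than re-detecting: its center is
bounded within FWHM/4 of the candidate pixel and its width within twice
the beam sigma.  Without these bounds, fits launched on either flank of
two partially overlapping structures all converge to the joint centroid
and the structures can never separate.  Non-converging fits fall back to
the intensity centroid (flagged `centroid-fallback`).  Detections closer
than FWHM/2 within one slice merge to the brighter fit: one event, one
localization.

Fitted integrated signal is converted to acquisition-pixel count units
(dividing by upsample_factor², since interpolation spreads each raw count
over factor² output pixels).  Localization precision is estimated as
σ_PSF/√counts — the simplest standard estimator; Monte-Carlo tests check
it agrees with the empirical per-cluster scatter within a factor of two.

Rendering: each localization contributes a Gaussian of tunable sigma
(default 15 nm), normalized on its evaluated support and scaled by its
counts (a unit-weight flag exists), summed over a 20–100-slice window;
sliding the window one slice at a time yields a depth-resolved SILM
stack.  Rendered mass equals the summed counts exactly.

The nanotag pair fixture places two equal-brightness 109.8 nm tags
115 nm apart laterally — below a 120 nm beam width, so every raw sum
shows a single blob — at different depths, so successive scans sample
them at different times.  The SILM render separates them; this is the
depth-stochastic analogue of resolving blinking emitters.

## Quantification metrics

- **2D correlation** r: the zero-mean normalized cross-correlation sum
  over all pixels; undefined (error) for a constant image.  Per-depth r
  series are summarized as median/quartiles with the 1.57·IQR/√n notched
  median CI, and two conditions are compared with the two-sided
  rank-sum (Wilcoxon) test.
- **SSIM**: computed on [0, 1] min-max normalized images.  The stabilized
  form (2μxμy + C₁)(2σxy + C₂) / ((μx² + μy² + C₁)(σx² + σy² + C₂)) is
  used with the conventional C₁ = (0.01·L)², C₂ = (0.03·L)², L = 1; both
  constants are arguments.  The primary value uses global image
  statistics (matching single-number usage); an 11×11 Gaussian-window
  mean is available behind a flag.
- **Edge resolution**: least-squares fit of offset + amplitude·Φ((x −
  center)/σ) (Φ the standard normal CDF, i.e. an erf edge) to a line
  scan across a sharp interface; resolution is the distance between the
  88 % and 12 % crossings of the fitted plateau-to-floor range, which is
  2·z₀.₈₈·σ = 2.350·σ — exactly the FWHM of the effective Gaussian PSF.
  This identity is what lets resolution claims be verified against
  synthetic edges with known blur.  Initialization uses robust
  percentiles and the 50 % crossing; non-convergent fits raise with the
  residual report.

## Spatial statistics

- **Chromatin states** (fuzzy C-means, written in-repo): voxel
  intensities partitioned into C = 3 states, fuzzifier m = 2, tolerance
  1e-5, max 300 iterations (all exposed).  Centroids initialize at evenly
  spaced data quantiles, which makes the whole iteration equivariant
  under positive affine rescaling of the input — so the hard labels are
  invariant to dynamic-range differences between scans, the property that
  motivates fuzzy segmentation here.  States are named by ascending
  centroid: very-low < decondensed < compacted.
- **3D K-means** (scikit-learn, k-means++ at fixed seed): per-voxel
  M-channel vectors are standardized per channel and then min-max
  normalized to [0, 1] — both steps, in that order, each optional by
  flag.  Per-cluster z-score means are computed on the standardized
  features used for clustering (the heatmap input).
- **Block peaks**: 20×20-pixel blocks, each thresholded at its own
  median + 4·1.4826·MAD; local maxima above threshold; incomplete edge
  blocks dropped and counted.  Mean peaks/block across images supports
  treated-vs-untreated comparisons.
- **Pairwise peak distances** in nm with anisotropic scaling (Δx, Δy
  lateral, z-step axial); duplicate peaks are flagged as zero distances.
- **Euclidean hierarchical clustering** of voxel coordinates with average
  linkage; inputs are capped at 2000 voxels by seeded subsampling because
  the full voxel count is quadratically infeasible.
- **Channel correlation/association**: Pearson over common voxels;
  the association matrix is the non-negative clip of the correlations
  (export only — chord-diagram drawing is cosmetic and out of scope).
  Constant channels are flagged NaN.
- **Delaunay neighborhoods**: blocks of 2/4/8 pixels are summarized by
  intensity-weighted centroids and per-channel signal sums;
  triangulation (2D) or tetrahedralization (3D) of the centroids gives
  per-simplex mean signals for heatmap tables.  Zero-signal blocks are
  dropped (counted); degenerate centroid sets (collinear/cospherical) get
  a deterministic seeded 1e-6 px jitter and one retry.

## What the simulator does and does not emulate

The generator reproduces the statistical structure the methods are
designed for: multiplicative gamma noise, ~3 % extraction, sub-surface
axial mixing, beam-width blur, drift, low counts (≤ 10/pixel for the
localization regime).  It does not model sputter-rate matrix effects,
charge buildup, detector dead-time, chained-mode acquisition, or
concentration-dependent ionization differences between elements.  Passing
tests therefore demonstrate the correctness and the resolution behavior
of the algorithms under the stated noise model, not instrument-calibrated
performance on real scans; real-data headline figures (e.g. measured
55 nm cesium-source resolution, SSIM of real channel pairs) depend on raw
scans and are intentionally not asserted.

## Problem sizes used in tests and the acceptance script

Simulated validations use 64–128 px fields, 30–80 slices and 3–20
replicate seeds — large enough that every recovery property is measured
well away from its threshold (e.g. six-molecule recovery succeeds in
20/20 seeds; the acceptance property requires 18/20), while the whole
suite runs in well under a minute per module.

## Known limitations

- LR deconvolution is 2D-per-section; axial deblurring relies on the
  binning geometry only.
- The blind-PSF interior map (log-linear in current) is a convention;
  only its endpoints are anchored.
- SILM assumes structures persist across multiple slices; transient
  single-slice events localize but cannot be distinguished from noise
  spikes at very low counts (single-ion detection is not claimed).
- The localization precision estimator ignores background and pixelation
  terms; it is validated only to within a factor of two of the empirical
  scatter.
- Registration is rigid translation; rotation and nonrigid deformation
  are out of scope.
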