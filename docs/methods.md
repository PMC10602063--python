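# Methods

This note records the models, parameter choices and numerical conventions
behind `iscatflow`, and what the synthetic tests do and do not establish
about real data.

## Forward model (synthetic scenes)

A field of view is rendered as

    counts = offset + N₀ · illumination · (1 + Σᵢ cᵢ·PSF(x−xᵢ, y−yᵢ) + L)

with `N₀` the mean background camera counts, `cᵢ` the signed peak
contrast of particle *i*, and `L` an optional low-frequency additive
contrast field. Conventions and defaults:

- **Geometry.** 6.5 μm camera pixels at 100× magnification → 65 nm
  sample pixels; 1024² px FOV = 66.56 μm per side. Coordinates are
  0-based, x = column (rightward), y = row (downward), positions at pixel
  centres.
- **PSF.** Radially symmetric Gaussian with FWHM equal to the 250 nm
  lateral resolution (σ ≈ 1.63 px). An Airy profile would change the
  far tails only; for localisation and contrast tests the Gaussian is
  sufficient and keeps the ground truth analytic.
- **Illumination.** A radial super-Gaussian flat-top of 89.5 μm beam
  diameter (wider than the recorded FOV, so the field is near-uniform
  with corner rolloff) times a smooth multiplicative inhomogeneity:
  three low-order cosine modes with random orientation/phase,
  peak-normalised to a relative amplitude of 0.1. The mode seed is a
  fixed offset from the scene seed so that scenes sharing an optical
  alignment share an illumination field — flat-field tests then have an
  exact truth.
- **Shot noise.** The instrument averages 100 frames at 100 Hz; the
  per-pixel count noise of the average is Gaussian with variance
  counts/frames (relative std 1/√(counts·frames) ≈ 3.2×10⁻³ at 1000
  counts). At ≥ 10⁵ accumulated counts the Gaussian approximation to the
  averaged Poisson is exact to well below the 5% closure tolerance the
  tests use.
- **Out-of-focus structure.** Low-pass-filtered white noise with a 30 px
  correlation length and configurable RMS stands in for chip-surface
  features; real out-of-focus backgrounds are not random fields, but
  only their bandwidth matters to the median-filter stage under test.
- **Particle populations.** Background defects draw |c| log-uniformly
  from [1.5×10⁻³, 7×10⁻³], signal particles from [10⁻², 10⁻¹] — strictly
  below/above the 7.5×10⁻³ classification cut-off so classifier tests
  have exact truth. Contrast signs are configurable (interferometric
  spots may be dark or bright); the default population is positive.
- **Raster scans.** All frames of a scan crop one contrast canvas, each
  receiving the per-FOV illumination and its own noise draw; applied
  offsets (nominal step + integer stage jitter) go into the layout
  metadata, so stitching tests are bookkeeping-exact.

Everything regenerates bit-identically from (parameters, seed); every
random stream derives from the scene or scenario seed.

## Binding kinetics

Immunocapture is modelled as a saturable pure-birth process: with *n*
particles bound of *N*max = b_max·A/100 available sites, the arrival rate
is k_obs·C·(A/100)·(1 − n/N_max), with k_obs the arrival-rate coefficient
(per (particles/mL)·h per 100 μm²), C the analyte concentration and A the
channel area. Waiting times are exponential, so the exact trajectory is
simulated in one vectorised pass (the rates depend only on *n*). No
unbinding is simulated: rinse-phase detachment is negligible in this
assay regime (multivalent EV binding and re-attachment to proximal
antibodies suppress it).

Defaults are the platform's operating point: b_max = 200 counts per
100 μm² (the upper detection limit, where neighbouring spots start to
merge), k_obs = 5×10⁻⁹ per (particles/mL)·h per 100 μm², chosen once so
that a 2×10¹⁰ particles/mL sample (the fingerprinting concentration
range) has a loading time constant b_max/(k_obs·C) = 2 h and plateaus
between 5 and 9 hours. Along-channel analyte depletion multiplies the
rate by exp(−x/L_d) in the along-flow coordinate; event positions are
drawn from that profile by inverse CDF.

Rate constants (k_on, k_off, K_D) are deliberately out of scope: the
assay operates in the titration, partly transport-limited regime where
equilibrium fits are biased. The analysis reports the time to reach
steady state and the plateau density instead.

- **Steady state**: earliest time where the relative density change over
  a trailing 2 h window falls below 5%; the plateau is the mean density
  from that time on. Both parameters are configurable; the rule reads
  slightly below the asymptote when invoked mid-approach, which is why
  recovery tests measure saturation from the fully saturated tail.
- **Dose-response linear range**: ascending doses are included while a
  zero-intercept weighted fit keeps every included residual within 2×
  its counting error. The intercept is forced through the origin because
  densities are net of the pre-assay defect baseline (baseline handling
  is density subtraction of a pre-assay scan; positional masking of
  pre-existing spots is out of scope).
- **Fold changes** are ratios of signal densities with Poisson-bootstrap
  CIs; a zero-count denominator returns a one-sided lower bound (rule of
  three) instead of a ratio.

## Fingerprint scenarios

Each channel's arrival rate is nonspecific_rate + k_obs·C·f_m, with f_m
the fraction of the population displaying marker *m* and the
isotype-control channel at f = 0. The nonspecific rate defaults to 0.3
per 100 μm² per hour, putting the control channel at ~1.5 counts per
100 μm² after a 5 h assay — two-to-three-fold above the ~0.5 baseline
defect density, matching the platform's observed control levels. The
CaOV3-like preset orders the cancer markers CD326 ≫ HE4 > CA125 with
tetraspanins high, and optionally links expression to mean contrast
magnitude (log-normal, σ_log = 0.4) to model larger vesicles binding
preferentially.

The positivity rule — normalised density > 1 + k·CV of the control, k = 3
— is this package's own (no standard rule exists); with three replicates
its null false-positive rate calibrates below 5%, which the acceptance
suite measures over 100 seeds. With a single control replicate the CV
falls back to the Poisson counting CV and the call is flagged.

## Detection chain: numerical choices

- **Noise.** σ_global = 1.4826 × MAD (Gaussian-consistent). The local
  map is the RMS over 65×65 reflect-padded windows of pixels within
  2.5·σ_global; windows with < 10% inliers fall back to σ_global, and the
  map is floored at 0.1·σ_global. Because the inlier cut truncates the
  distribution, the estimator's expectation falls below the true σ
  wherever local noise exceeds the global scale (−15% at 2×); tests
  therefore validate it against its closed-form truncated-RMS
  expectation. "Kernel size of 65" is read as a 65×65 window, consistent
  with the 17-px median-kernel phrasing.
- **Segmentation.** SNR = |pixels|/σ_local (both polarities; reported
  contrast keeps its sign). Pixels with SNR ≥ 4 group by 8-connectivity;
  a group survives iff at least one 3×3 window contains ≥ 3
  above-threshold pixels of that group. Peaks take the max-SNR pixel,
  ties broken toward smaller row then column.
- **Localisation.** Radial symmetry centres: gradients on the half-pixel
  midpoint lattice from diagonal differences of 2×2 blocks, 3×3 mean
  smoothing, closed-form 2×2 weighted least squares over the
  gradient-direction lines, weights |∇I|²/distance-to-centroid with the
  distance floored at 0.1 px. Singular systems (flat ROI) fall back to
  the intensity centroid, flagged. ROI half-width 7 px (≈ 3.7 PSF σ) so
  the smoothed gradient field is fully contained; edge-clipped ROIs are
  flagged.
- **Contrast.** Signed extremal pixel within 1 px of the localised
  centre; integrated contrast sums same-signed ROI pixels above
  1·σ_local (ROI shape and threshold configurable — no standard
  definition exists). The peak-pixel convention under-reads a spot
  centred between pixels by up to ~9%; the 17-px median stage itself
  attenuates PSF-scale peaks by < 2%.
- **Mosaics.** Detection runs on the stitched canvas restricted to the
  valid mask; localisations closer than 2 px are merged keeping the
  higher SNR (the cross-FOV duplicate case).

## Preprocessing and stitching

Normalisation divides by the whole-frame median (robust to a few percent
spot cover; the background-region definition is not otherwise specified,
so whole-frame is the flagged choice). The flat field is the pixel-wise
median of ≥ 60 normalised frames from distinct positions, renormalised to
mean 1; fewer frames raise an error in strict mode and a warning
otherwise. Stage order is normalise → divide → subtract 17-px median;
each stage is idempotent on its own output class.

Offsets are estimated by phase correlation
(`skimage.registration.phase_cross_correlation`, DFT-upsampled to 0.05 px)
with whitened spectra on full frames. When a nominal stage offset is
supplied, both frames are first cropped to the nominally overlapping
region and only the residual is estimated with plain (unwhitened)
cross-correlation — whitened correlation is fragile on narrow strips
where a large fraction of content is unshared. The correlation confidence
is the normalised cross-power peak height (≈ 1 for pure translation);
estimates below the floor fall back to the nominal offset and are
flagged. Placement is translation-only at integer pixels with a
first-placed-wins overlap policy — no feathering, because blending would
bias the contrast values used downstream. A loop-closure discrepancy
above 2 px between the left- and top-chain estimates raises a warning
naming the grid position.

## Transport calculators

The two-plate sensor framework: Pe_H = Q/(D·W), Pe_s = 6(L_s/H)²·Pe_H,
δ_s = L_s·Pe_s^(−1/3), Da = k_on·b_m·δ_s/D, with internal unit
conversion (EV defaults D = 3 μm²/s, Q = 1.3 μL/h, W = 300 μm give
Pe_H ≈ 401 and δ_s ≈ 5.0 μm). k_on is always user-supplied; the
calculator reports Da rather than asserting a regime. The effective
capture-probe concentration b_m/H is returned in dimensionally correct
units: 0.08 pmol/cm² over a 10 μm channel is 0.08 μM (80 nM), one to
three orders of magnitude above typical antibody–antigen K_D — the
titration regime. The default channel volume computes to 9 nL
(3 × 0.3 × 0.01 mm). IgG and NeutrAvidin molar masses (150, 60 kDa) are
implementation constants.

## Problem sizes in the test and acceptance suites

Imaging suites run on 256²–1024² frames: the 50-spot recall benchmark
uses one 1024² FOV at a 5×10⁻⁴ contrast-noise floor (set through the
photon budget) with spots placed ≥ 12 px apart — two emitters inside one
diffraction-limited spot are physically a single localisation, so recall
is only defined over resolvable placements. Blank-FOV false positives
use 20 noise-only 1024² fields. Kinetics recovery uses 20 seeds on
2×10⁴ μm² channels; depletion fits use ~4×10⁴ events on the full 0.2 mm²
scan area; fingerprint calibration uses 100 seeds × 7 channels × 3
replicates at ground-truth count level. The rendered-image path is
exercised by the detection and round-trip suites; the counting-statistics
suites run on the generator's event lists directly, since rendering adds
nothing to what they measure.

## What passing tests do and do not show

The generator produces Gaussian spots on smooth backgrounds with
spatially uncorrelated noise. Real data add PSF aberrations, focus
drift, correlated backgrounds (fringes, speckle residues), detector
fixed-pattern noise and particle motion during averaging — none of which
are modelled, so the measured recall/precision and localisation RMSE are
upper bounds on real-data performance, not predictions. Conversely the
oracle-equivalence, round-trip, conservation and calibration results are
properties of the algorithms themselves and transfer directly.

## Known limitations

- The local-noise estimator inherits the truncation bias described
  above; SNR values in locally hot regions are correspondingly inflated.
- Stitching is translation-only (no rotation/scale, no global bundle
  adjustment); chained offsets accumulate error on large grids, bounded
  in practice by the loop-closure check.
- Absolute particle sizing from contrast is out of scope (size and
  refractive index are not decoupled).
- Time-linking of localisations into tracks and differential-imaging
  modes are not implemented.
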