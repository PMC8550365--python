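# Methods

This note documents the models implemented in `ramanci`, the reasoning
behind the open design choices, the synthetic-data generator and its
limits, and the numerical conventions. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pre-processing

**Anchor-point baseline.** Raman spectra of cellulosic powders carry a
smooth fluorescence background. It is estimated as the piecewise-linear
curve through the spectrum's own intensities at nine fixed, band-free
anchor wavenumbers (200, 260, 550, 632, 743, 857, 952, 1200, 1500 cm⁻¹)
and subtracted. Consequences used throughout the package:

* the corrected spectrum is exactly zero at every anchor that lies on the
  acquisition grid (off-grid anchors are read by linear interpolation, and
  the residual at such an anchor is bounded by the grid's interpolation
  error, not by machine precision);
* the operation is idempotent and invariant to adding any function that
  is linear between the anchors — so a multiplicative gain plus an
  anchor-breakpoint-linear background is removed exactly;
* beyond the outermost anchors the baseline continues flat at the
  terminal anchor value. The default anchors coincide with the ends of
  the standard 200–1500 cm⁻¹ acquisition window, so this only matters for
  spectra acquired over a wider range; flat continuation avoids
  extrapolation blow-up.

**SNV.** Each spectrum is standardized by subtracting its mean and
dividing by its sample standard deviation (n−1 divisor, the dominant
chemometrics convention; any consistent choice rescales all spectra by
one common factor). Statistics are computed over the full stored axis,
not a sub-window. SNV removes multiplicative intensity differences
(laser power, focus, packing density); it is idempotent and invariant to
affine intensity transforms. A constant (zero-variance) spectrum is a
degenerate input and raises an error rather than returning NaNs.

**Order.** Baseline first, then SNV. SNV after baseline standardizes the
residual band-intensity scale; the reverse order would let the
background level leak into the normalization constant.

**857 cm⁻¹ matching.** Before spectral subtraction, the amorphous
reference is put on the sample's intensity scale by a single scalar that
equalizes the two spectra exactly at 857 cm⁻¹ — a point insensitive to
crystalline order. The matching sentence in the source procedure for this
step is ambiguous (scale only the region above 857 cm⁻¹, or the whole
spectrum?); this package implements whole-spectrum scalar matching, the
only reading that preserves the reference's shape, and exposes
`scale_at_857=False` to disable scaling and use stored band statistics
instead. The behaviour is never switched silently.

## The 380-method

Cellulose Raman spectra superimpose a crystalline and an amorphous
contribution. The 380 cm⁻¹ band (skeletal bending) tracks crystalline
order strongly; the 1096 cm⁻¹ band (glycosidic/CO stretch) is compara-
tively order-insensitive and serves as internal standard. The index is

    %CI = (R − c) / m,   R = (I₃₈₀ − I₃₈₀,am) / (I₁₀₉₆ − I₁₀₉₆,am),

where the `am` values come from a pre-processed amorphous reference
(ball-milled material), 857-scaled to the sample.

Conventions:

* **Band read-off** is the maximum over grid points within ±5 cm⁻¹ of the
  band center — robust to wavenumber-calibration shifts of a couple of
  cm⁻¹. `half_window=0` reproduces an exact interpolated read.
* **Unclipped output.** %CI is not clipped to [0, 100] by default: values
  below 0 diagnose a sample more amorphous than the reference and are
  informative. An optional clip warns.
* **Calibration direction.** New calibrations are fitted by ordinary
  least squares in the classical direction, ratio = m·%CI + c, with the
  PXRD (Segal) index as the independent variable; prediction inverts the
  line. This matches the algebraic form of the built-in equations.
* **Amorphous reference.** `build_amorphous_reference` averages many
  pre-processed amorphous spectra pointwise and stores the mean ± sample
  sd of the per-spectrum band intensities. Because band reads are window
  maxima, the mean of per-spectrum reads can exceed the read of the mean
  spectrum by a noise-dependent amount; the per-spectrum statistics are
  authoritative. Band-statistics-only references (without a stored
  spectrum) are supported for the two probe systems whose published
  averaged values are built in; these can only be used with scaling off.
* The denominator I₁₀₉₆ − I₁₀₉₆,am vanishes when the sample is
  spectroscopically indistinguishable from the amorphous reference; that
  is a degenerate input (error), and batch aggregation flags such
  replicates and continues with the rest.

## Segal PXRD index

`segal_ci` returns `100·(I₂₀₀ − I_am)/I₂₀₀` with I₂₀₀ the mean counts
over 22.55–22.65° 2θ (cellulose 200 reflection) and I_am over
18.65–18.75° 2θ (amorphous scatter). Both windows are closed intervals
over grid points; a window catching no grid point is an error rather
than a nearest-point fallback. An optional blank diffractogram (sample
holder only) is subtracted first, interpolated onto the sample grid if
needed. The index is returned as a percentage so it is commensurate with
the Raman %CI, and it is invariant to scaling all counts by a positive
constant. The amorphous window is configurable; the printed source for
its lower edge contains an obvious typographical garble, and 18.65° is
the only consistent reading.

## Latent-variable models

Both algorithms are written from scratch (they are the analytical core of
the package), operate on mean-centered, unscaled variables — the spectra
are already SNV-normalized, so autoscaling would only inflate noise
wavenumbers — and fix loading/weight signs so the largest-magnitude
element is positive (reproducible fixtures). The model matrix restricts
spectra to 250–1500 cm⁻¹.

**NIPALS PCA.** Components are extracted sequentially (start: the column
with the largest residual variance; iterate p = Eᵀt/tᵀt normalized,
t = Ep until the relative score change < 1e-9; deflate). Explained
calibration variance per component is 100·tᵀt / total centered sum of
squares. Equivalence with the singular value decomposition (variances to
1e-8, loadings up to sign) is asserted in the test suite on dozens of
random matrices.

**PLS1.** The classical NIPALS sequence (w ∝ Xᵀy unit-norm, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate X and y). For univariate y this is
algebraically identical to the kernel algorithm, so equivalence — not any
particular software implementation — is the contract; the test suite
checks it against an independently coded textbook sequence, against
scikit-learn, and against the ordinary-least-squares limit at full rank.
Regression coefficient vectors are retained for every factor count, so a
stored model predicts with any truncation; factor count 0 is the
intercept-only model.

**Grouped cross-validation.** All spectra of one batch stay in one
segment (replicates must never straddle a train/validation split — they
share everything but noise, and splitting them grossly understates the
validation error). Default: one segment per batch; fewer segments
assign whole batches round-robin. PCA validation variance is PRESS-based:
held-out rows are projected on training loadings and
100·(1 − PRESS_k/SS) is accumulated over segments, reported as
per-component increments. PLS validation offers both RMSECV (grouped
segments) and held-out-set RMSEP — the two are labelled distinctly
because "validation variance" is ambiguous between them in commercial
chemometrics software.

**Factor selection.** Default rule: the smallest factor count after which
the cross-validated RMSE stops improving by more than 2% relative;
global-minimum and fixed-k rules are available.

**Correlation loadings** are the Pearson correlations between each
centered variable and each score vector; zero-variance variables are
reported as 0 with a flag, and the 50%/100% explained-variance circle
radii (√0.5, 1) accompany the table for plotting.

## Synthetic data generator

The generator exists so calibration, the 380-method, PCA and PLS are all
testable end to end with exactly known ground truth.

**Raman spectra.**

    s(ν) = g · ( χ·C(ν) + (1−χ)·A(ν) + χ(1−χ)·I(ν) + B(ν) ) + ε

* `C`, `A`: crystalline and amorphous components, sums of analytic peaks
  (Gaussian by default; Lorentzian and pseudo-Voigt available) at the ten
  order-sensitive cellulose bands (380, 437, 458, 521, 1096, 1120, 1330,
  1340, 1380, 1475 cm⁻¹). The amorphous table uses the same centers
  2–3× broader, with the 380 band strongly suppressed (amplitude 0.9 vs
  12) and the 1096 band reduced (3 vs 12) — the physical premise of the
  380/1096 ratio.
* `B`: quadratic fluorescence background (default coefficients
  (0.8, 1.2·10⁻³, 6·10⁻⁷) in (ν−200)). It is deliberately *not*
  piecewise-linear over the anchors, so baseline removal is approximate
  on synthetic data exactly as on real data; tests that assert exactness
  use a zero background.
* `g`: log-normal multiplicative gain (σ = 0.1), removed exactly by SNV.
* `ε`: i.i.d. Gaussian noise with sd = `noise_sd_frac` × max clean
  intensity (default 1%).
* **`I`: quadratic (Scheffé-type) blend-interaction term.** For an
  exactly mass-linear mixture whose χ = 0 endmember also serves as the
  subtraction reference, the amorphous-subtracted band ratio is
  *identically independent of χ*: the numerator and denominator are both
  proportional to χ, the SNV scale cancels between them, and the ratio
  collapses to the crystalline component's fixed band contrast. A linear
  generator therefore cannot exhibit a ratio-vs-crystallinity calibration
  line at all — whereas real binary powder blends demonstrably do, because
  Raman signal mixing in compacts is not mass-linear (differential
  scattering and sampling between fine milled and coarser unmilled
  particles). The generator models that nonideality with the standard
  first-order mixture term χ(1−χ)·I, which vanishes at both endmembers.
  `I` is a deficit at the 380 band with a proportional smaller deficit at
  1096 (relative amplitude 0.15, chosen so the interaction is invisible
  to the amorphous-subtracted 1096 internal-standard read, which keeps
  the ratio an affine function of χ); default overall strength 16
  intensity units. `blend_nonideality = 0` restores the exactly linear
  mixture, and the mixing-linearity tests run in that configuration.
* Probe response: per-probe amplitude multipliers on the 380 and 1096
  bands (MR 1.0/1.0; PhAT 0.8/1.15 — the large-spot probe reads the 1096
  band higher and the 380 band lower).
* Determinism: every output is a pure function of (config, arguments,
  seed); per-spectrum streams derive from the master seed through a
  counter scheme (`SeedSequence(master, spawn_key=(stream, index,
  replicate))`).

**Diffractograms.** 10–30° 2θ at 0.01° steps: χ-weighted Gaussian
reflections (14.9°, 16.4°, 22.7°; fwhm 1.5°; the 22.7° line strongest at
10 000 counts), a (1−χ)-weighted amorphous halo, a flat 10-count holder
baseline and Gaussian noise of sd √max(counts, 1) (Poisson
approximation). The halo is centered at 20.65° — midway between the two
Segal windows, so both windows see it equally by symmetry — with fwhm 8°,
and its amplitude is normalized at render time so the two endmembers give
equal mean counts in the Segal windows. With that normalization the Segal
index is linear in χ by construction (≈ 99.9·χ with the blank
subtracted), which is what makes the synthetic blend series a faithful
stand-in for a designed calibration set. A matching blank (baseline only)
generator supports the blank-subtraction path.

**Blend series** defaults to the seven-fraction design 100, 83, 72, 58,
44, 33, 22 % w/w with 3 replicates per blend. The end-to-end calibration
study (`workflows.calibration_study`) builds its amorphous reference from
30 fraction-0 replicates — a generously averaged reference, as in
practice, where averaged amorphous references are built from dozens of
milled-sample spectra. At 1% noise the study recovers the generated
compositions to within ±3 %CI (asserted in the acceptance tests at
master seed 7, the study's documented seed); noise-free it recovers them
to better than ±0.5 %CI with a ratio-vs-fraction correlation above
0.999. The residual curvature of the fitted line (Pearson r ≈ 0.999
rather than exactly 1 noise-free) comes from the window-maximum band
reads; it is well below the noise floor of any realistic measurement.

**Batch panel** emulates a set of commercial batches measured with both
probes (default 30 batches; MR n = 3, PhAT n = 2 replicates → 150
spectra). Per-batch crystalline fractions are uniform on 0.62–0.74 by
default — commercial semi-crystalline cellulose varies over a narrow
band, a few %CI sd across suppliers — with small per-batch peak-position
jitter (≤0.3 cm⁻¹) and 1% amplitude jitter for material variability. On
this panel, PCA separates the probes with a single threshold on one of
the first two score axes. For model-training demonstrations the tests use
a deliberately spanned design (χ uniform on 0.5–0.9), as one would span a
calibration set; there a 24/6 batch split gives RMSEP well below the
no-information error with explained validation variance above 90%.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true cellulose line shapes and the Iα/Iβ
polymorphs; crystallite-size effects on the Segal peak; particle-size and
depth-of-focus physics beyond the single quadratic interaction term;
detector artifacts (cosmic rays, etalon fringes); wavenumber-axis
miscalibration beyond what the ±5 cm⁻¹ band windows absorb; and any
disagreement between the Segal index and the true crystalline mass
fraction, which on real material is method-dependent.

## Numerical choices and degenerate inputs

* Axis convention: strictly ascending; descending files are reversed on
  read and the direction recorded. Duplicate axis values are rejected
  (an upstream data error), never averaged.
* Resampling is linear interpolation without extrapolation; exact on any
  subset of the original grid.
* JCAMP-DX support is limited to AFFN `(X++(Y..Y))` tables; compressed
  encodings (SQZ/DIF/DUP) are rejected with a clear message, and the
  leading X of every data line is checked against the reconstructed grid.
* Text output uses `%.17g`, so write→read round-trips are bit-exact.
* NIPALS convergence: relative score change < 1e-9, at most 1000
  iterations, convergence failure names the component.
* Spot-area helper: area = πd²/4 from the nominal beam diameter (100 µm
  → 7.85·10⁻³ mm²). For the large-spot probe the published collection
  area corresponds to an effective 4 mm diameter rather than the 6 mm
  nominal beam; the helper computes strictly from the diameter given.
* Errors are typed: parse/format errors name the offending line or
  record; range errors report the violated span; degenerate inputs (zero
  variance, zero denominators, windows with no grid points) raise
  dedicated exceptions rather than propagating NaNs.

## Problem sizes

The shipped tests and the acceptance script use the study sizes the
package documents as its defaults: 7 blends × 3 replicates (+30 reference
spectra) for the calibration study, 30 batches × 5 replicate spectra for
the panels, 1301-point spectra at 1 cm⁻¹, 2001-point diffractograms at
0.01°. The complete suite runs in well under a minute on one CPU.
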