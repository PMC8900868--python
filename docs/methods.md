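# Methods

## Geometry and conventions

Parallel-beam, single-tilt-axis acquisition: the object rotates about an
axis parallel to detector rows' normal (`z`), each frame is `N_y` rows by
`N_t` columns, and the sinogram of one slice is `p(t, θ)`.  All COR
quantities are 0-based pixel coordinates along `t`:

* array center `c0 = (N_t − 1)/2`;
* `t'` — signed COR error, positive when the axis sits at larger `t`;
* absolute COR column `c0 + t'` (what reconstruction codes want).

The rotation axis is assumed parallel to the detector columns; axis tilt is
out of scope.

## Phase-symmetry estimator

The sum of two projections 180° apart (no mirroring) is even about the
axis column: a point at radius `r` contributes `δ(t − t(θ))` and
`δ(t − t(θ+180°)) = δ(2c − t − t(θ))` with `c = c0 + t'`, and integrating
over a full turn gives the arcsine density `1/(π sqrt(r² − u²))`,
`u = t − c` — even in `u` for every point, hence for any superposition.

Evenness about `c` means the Fourier transform factors as
`e^{−iωc}·A(ω)` with `A` real.  `phase_at_fmin` evaluates one FFT bin,
rotates the phase origin to the array center (multiplication by
`e^{+2πi k c0' / N}`), and returns `phi = arctan(I/R)` on the principal
branch.  `phase_to_shift` then gives `t' = −phi·N/(2πk)`.  Consequences:

* **Polarity/affine invariance.** `arctan(I/R)` is unchanged under
  `d → αd + β` (`α ≠ 0`): constants live only in bin 0, scaling cancels in
  the ratio, and sign flips negate `R` and `I` together.  Transmission and
  emission data need no flag.
* **Capture range.** The principal branch restricts `|phi| < π/2`, i.e.
  `|t'| < N_t/4`; larger offsets alias by `N_t/2` (asserted in tests).
  The two-argument arctangent would double the range but break polarity
  blindness; the quarter-width range is ample for real alignment errors.
* **Frequency bin.** For multi-row frames the `(N_y, N_t)` sum is
  flattened row-major and the bin with one cycle per detector row
  (`k = N_y` of the length-`N_y N_t` array) is used.  By DFT linearity it
  equals bin 1 of the row-summed profile exactly (tested to 1e−15); bin 1
  of the flattened array would be degenerate for identical rows.  The bin
  is overridable for fidelity experiments.
* **Preconditions.** The object must stay fully inside the field of view
  (the evenness argument needs the whole arcsine support); a constant
  signal or a zero-magnitude bin raises a degenerate-input error.

### Edge-background normalization

The lowest-frequency phase is sensitive to illumination gradients along
`t`.  Flat/dark normalization removes most; `normalize_background_edges`
removes the rest by fitting a straight line through the mean of the left
and right margin columns (default margin 5% of `N_t`) and *dividing* by
it, then rescaling to preserve the overall mean.  The correction is
multiplicative because illumination multiplies transmitted intensity: an
additive ramp leaves the object region modulated and, on the low-contrast
phantom, a residual COR bias of order 1 px, while division removes a pure
linear gradient exactly.  Margins must contain background only — that is a
caller contract, not something the function can verify.

## Reference estimators

**Phase correlation.**  The 180° partner is mirrored about the array
center, making it a translate of the first projection by `2t'`.  The shift
is located on the phase-only cross-power spectrum with coarse peak search
plus matrix-multiplication-DFT refinement at upsampling `m = 10`
(scikit-image's `phase_cross_correlation`); the row-axis component is
reported as a sample-drift diagnostic and never applied.  Caveat measured
here: on hard-edged, low-contrast phantoms the unit-magnitude weighting
amplifies aliased high frequencies and biases the estimate by ~0.1 px;
on band-limited content it is exact to `1/m`.

**Sinogram FFT (double wedge).**  A centered 360° sinogram has 2-D
Fourier support inside a bow-tie `|n| ≤ r·|ω|` (angular harmonic `n`,
t-frequency `ω`, object radius `r`).  A 180° sinogram is mirrored to 360°;
the mirrored half carries the axis at `c0 − t'`, so cyclically shifting it
by `u` and minimizing the mean spectral magnitude outside the wedge finds
`u* = 2t'`.  Integer scan (default ±20 px) with parabolic refinement over
the three best shifts; a minimum at the scan edge raises an error rather
than returning an unbracketed value.  Wedge slope defaults to the object
filling the field of view (`r = N_t/2`) with a 2-harmonic pad around DC;
both are configurable since the support argument fixes only the shape, not
the margin.  Cyclic shifting assumes the object clears the frame edges.

## Synthetic data

Projections of ellipse/ellipsoid phantoms are evaluated in closed form
(chord length × attenuation), giving exact sub-pixel COR offsets — the
ground truth the recovery tests compare against.  Three sampling flavours
serve different purposes:

* `ellipse_projection` — point samples of the chord function (simple, used
  for chord/mass spot checks);
* `make_sinogram` — per-pixel *integrals* via the antiderivative of
  `sqrt(s² − τ²)`, so row mass `π a b ρ` is conserved to machine precision
  at every angle;
* `project_intensity` — line integrals on an 8× supersampled grid,
  converted to intensity (`exp(−L)` for transmission, peak-normalized `L`
  for emission), then box-averaged per pixel.  This models a detector that
  integrates intensity over its pixel area; it matters because point
  sampling of edge-singular profiles aliases into the lowest Fourier bin
  and would limit noiseless recovery to ~0.1 px, versus ≤ 0.002 px with
  pixel integration.

The head phantom uses the standard ten-component table (low-contrast
variant) scaled by `fill · grid/2`; `fill = 0.8` in offset experiments
keeps the object inside the field of view up to `|t'| = 16` on a 256-px
detector.  For transmission phantoms the attenuations are rescaled by one
global factor so the median projected transmission over the object support
at angle 0 equals 0.989 (bisection to 1e−6) — the one number that pins the
"low-contrast" condition.  Poisson noise is drawn per pixel with expected
count `fluence × intensity`; every draw takes a named integer seed, and
reflection pairs spawn two independent child seeds from one parent.

What the generator does *not* model: detector blur/PSF, read noise,
phase-contrast propagation, axis tilt, and object truncation.  Passing
tests therefore demonstrate estimator correctness under ideal sampling and
pure Poisson statistics, not robustness to those effects.

## SNR estimation and dose bookkeeping

Two images of the same scene with independent noise have Pearson
correlation `r = s²/(s² + n²)` over pixels, so the amplitude SNR is
`sqrt(r/(1 − r))`.  The amplitude convention (not the power ratio) is used
because Poisson counting gives SNR ∝ sqrt(fluence), which the estimator
reproduces (ratio 2.0 for a 4× fluence step in the tests).  Correlation is
taken over *all* pixels — background legitimately depresses the value; it
is the SNR of the frame.  At very low SNR the estimate is noisy
(`std(r̂) ≈ 1/sqrt(N_pixels)` against `r ≈ SNR²`) and slightly biased by
clipping negative `r` to zero, so low-dose figures are averaged over many
(100–200) seeds.  `r = 1` (identical inputs) is reported as a saturated
estimate rather than infinity popping out of arithmetic.

Bookkeeping helpers: contrast parameter `Θ = |I_max − I_min| /
sqrt(I_max + I_min)` (per-photon detectability; 0.0078 for transmissions
1 vs 0.989), required fluence `(SNR_target/Θ)²` (≈ 4.1e5 photons/pixel at
target 5), per-angle fluence `total/N_θ`, and the Crowther count
`(π/2)·D` for full angular sampling of a `D`-pixel object.

The low-dose acceptance simulation reports the SNR of a single 512-px
projection *row* (one sinogram row of the central slice), the natural unit
when working per-slice; over the full 512² frame, whose area is mostly
rows through the weakly-absorbing poles plus background, the same
procedure gives ≈ 0.06.

## Workflows and scales

Sweep drivers (`run_snr_sweep`, `run_dtheta_sweep`,
`run_dose_fractionation`) derive one child seed per (condition, repeat)
cell from a base seed via `SeedSequence`, so runs are bit-reproducible and
the Δθ = 0 column of the departure sweep reproduces the fluence sweep
exactly.  Method failures are logged per cell, not fatal.  Default problem
sizes are desk-scale — 256-px detector, 25 seeds (10 for dose
fractionation), 360–2880 angles — chosen so the full suite and the
acceptance script run in minutes on one core; all sizes are arguments.
The noise-ordering test condition "projection SNR ≈ 1" is realized at
fluence 3e4 on the 256-px low-contrast phantom (measured 0.8–1.2 by the
package's own estimator).

`fbp_reconstruct` is a qualitative diagnostic only: it re-centers the
sinogram with a cubic spline shift and runs a ramp-filtered backprojection
(scikit-image `iradon`, which places the axis at column `N_t//2`); a
mis-set COR shows up as ring/tuning-fork artifacts and strictly higher
total variation.

## Known limitations

* Capture range `|t'| < N_t/4`; beyond it the estimate wraps (documented
  and asserted, not detected at runtime).
* Objects touching the frame edge violate the evenness premise; no
  truncation detection is attempted.
* The Δθ tolerance is empirical: ±2° costs well under 1 px on the centered
  phantom, but the bias grows with both Δθ and the object's angular
  asymmetry.
* Phase correlation inherits its documented small bias on hard-edged
  synthetic content; comparisons against it at the 0.1 px level should use
  band-limited data.
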