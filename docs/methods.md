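# Methods

`sbsmicro` models the computational chain of a pulsed pump–probe
stimulated-Brillouin-scattering (SBS) microscope: the physics that turns a
mechanical resonance into a measured gain spectrum, the simulation of
realistic acquisitions, and the analysis that turns raw acquisition
streams back into per-pixel mechanical parameters and instrument
figures of merit.

## Gain model and pulse enhancement

A pump beam (intensity I₁) and a counter-propagating probe interact via
GHz acoustic phonons.  Scanning the pump–probe detuning Ω across the
Brillouin resonance Ω_B produces a stimulated Brillouin gain (SBG)
spectrum

    G(Ω) = ±η · g(Ω) · l · I₁,

where g(Ω) is Lorentzian with full width Γ_B, η is the pump–probe overlap
efficiency, and l the interaction length.  η and l are not independently
measurable at analysis time, so both default to 1 and the amplitude is
carried in detector-referred units; the stimulated-loss branch is the
exact negative of the gain branch.  Frequencies are carried in GHz
everywhere; only `longitudinal_modulus` converts to Hz, computing

    M* = ρ (λ₁/2n)² Ω_B² (1 + i Γ_B/Ω_B)

with Ω_B, Γ_B as ordinary frequencies (the acoustic velocity is
V = λ₁Ω_B/2n, and M′ = ρV²; 5.07 GHz in water-like material gives
M′ ≈ 2.21 GPa).

Pulsing both beams at duty cycle dc = T_pulse/T_period while holding the
average powers fixed concentrates the same energy into 1/dc higher peak
intensities.  Because the SBS signal is bilinear in pump and probe
intensity while the shot noise follows the average probe power, the SNR
gains a factor E = 1/dc: the enhancement arithmetic
(`duty_cycle`, `enhancement_factor`, `equivalent_cw_pump`) is exact
closed form, and a width exceeding the pulse period is an error rather
than a clipped duty cycle.

## Synthetic data

The generator produces every input the analysis consumes, with ground
truth attached:

* **Noise model.**  Additive i.i.d. Gaussian noise with
  σ = (max peak amplitude)/SNR, matching the instrument convention of
  quoting SNR as fitted amplitude over off-resonance standard deviation.
  No Poisson/photon-counting simulation: the detector operates far above
  single-photon level and the lock-in output noise is well described as
  Gaussian.  Noise is homoscedastic across frequency bins.
* **Shot-noise scaling.**  Repeat series specify SNR at a reference
  integration time (38 at 20 ms by default) and scale σ ∝ t^(−1/2).
* **Default water conditions.**  Single Lorentzian at 5.00 GHz,
  0.459 GHz FWHM, on a 100-point 4–6 GHz axis — the standard water
  calibration spectrum at 20 ms integration.
* **Phantoms.**  `water` (uniform), `bead_in_agarose` (4.07 GHz disk in
  5.12 GHz background, the lateral-resolution target),
  `oil_glass_edge` (7.04 GHz oil below an axial boundary, cover glass
  with no in-band resonance above), and `two_layer` (5.03/5.80 GHz with
  a double-peak overlap stripe).  Phantom edges are geometrically sharp:
  no optical PSF convolution is applied, so spatial-resolution numbers
  are exercised through explicit erf-profile recovery rather than full
  imaging simulation.
* **Raster streams.**  Acquisition is emulated sample by sample:
  frequency fastest, serpentine fast axis (odd lines reversed), odd
  z-planes traversed in reversed line order, and a stage lag that
  displaces every second line's content by round(delay/pixel time)
  pixels, blanking the samples recorded before the stage reaches the
  line.  All generators take explicit integer seeds and are
  bit-reproducible.

What passing tests on these data do **not** show: performance on real
tissue spectra with non-Lorentzian baselines, aberration-induced
asymmetries, refractive-index-mismatch effects, or drifting calibration.
The generator's scope is the instrument's own validation measurements
(water, bead, oil phantoms), not biology.

## Spectral fitting

The concatenated stream is detrended by a zero-phase (forward–backward)
first-order Butterworth high-pass, 50 Hz cutoff at the acquisition
sample rate — about one spectrum period — chosen zero-phase so the
filter cannot bias peak centers.  Each spectrum is then fit by
trust-region least squares with a model of 1–3 Lorentzians plus a
constant baseline (kept even after detrending, as insurance against
filter residuals).

Initialization is data-driven: center at the arg-max of a
Savitzky–Golay-smoothed copy (window 11, order 2), FWHM from the
half-maximum crossings, amplitude from max-minus-baseline.  Multi-peak
fits seed at the K most prominent smoothed local maxima, requiring
prominence ≥ 5× a robust noise estimate (median absolute deviation of
first differences); if fewer significant maxima exist, the dominant
starter is split into two overlapped components at c ± w/4.  Bounds:
centers within the axis, FWHM in [2×axis step, axis span], amplitudes
non-negative.  Peaks are reported sorted by shift (ties: larger
amplitude first); two fitted centers within one axis step raise the
`degenerate` flag.  A spectrum whose initial amplitude estimate is below
3× the robust noise is returned non-converged rather than raising — a
blank or masked pixel is a data condition, not a programming error.

Model order is never selected inside the fitter; the 1-vs-2 decision is
the classifier's job.

Per-peak derived quantities: Brillouin gain G_B = amplitude/DC level,
and SNR = amplitude / std of the spectrum in a configurable off-resonance
window (the window must stay ≥3 FWHM away from every fitted peak, hold
at least 5 samples, and a zero-variance window raises a dedicated
"unbounded SNR" error).  The window is configurable because the scanned
band and the quiet band depend on the sample (water is scanned 4–6 GHz
while its quiet band is 7–9 GHz).

## Single- versus multi-peak classification

An asymmetric-looking spectrum can be one distorted resonance or two
genuine components.  The test fits the two-Lorentzian model, takes the
*analytic* derivative of the fitted sum, normalizes it by its maximum
absolute value, and counts zero crossings:

* a single peak (symmetric or not) crosses once — its maximum;
* two resolved extrema cross three times;
* a shoulder with no second extremum still bends the derivative, and
  sliding the normalized derivative by offsets swept over [−0.5, +0.5]
  (21 evenly spaced values) exposes the bend: a pure single Lorentzian
  crosses exactly twice at any offset 0 < |o| < 1, so any count above
  that baseline (above one at zero offset) indicates a second component.

The per-pixel **multi-peak metric** is the fraction of swept offsets
that detect extra crossings; "single" pixels are exactly 0.  The metric
is an explicit convention of this package (no standard formula exists
for a multi-peak map), and it is scale free, because the derivative
normalization cancels the spectrum's amplitude.  Crossings within one grid step of the axis boundary are
ignored as finite-scan-range artifacts.

Two robustness guards make the test noise-proof:

1. **Width floor.**  The classification fit bounds each component's FWHM
   below by the instrument's spectral resolution (default 0.15 GHz).
   Without it, the second Lorentzian collapses onto single-sample noise
   excursions at the generic 2×step bound, and their steep flanks read
   as bumps.  No genuine optical feature can be narrower than the
   instrument response, so the floor discards only unphysical solutions.
2. **Significance gate.**  A fitted component whose amplitude is below
   4× the robust residual noise is excluded from the derivative test —
   the standard detection-limit convention: a component indistinguishable
   from the noise floor is not evidence of a second mechanical mode.

Both guards are scale free and irrelevant for genuine peaks, which sit
tens of σ above the floor at working SNR.  With them, 10,000 simulated
water spectra at SNR 38 classify as single-peak at ≥ 99.9%, while
two-component spectra at SNR 30 are detected essentially always.

## Scan reconstruction

Reconstruction is the exact inverse of the generator's traversal:
reshape the 1-D stream to [frequency; pixels], fold pixels onto the grid
reversing odd serpentine lines, displace every second line by
round(stage delay / pixel time) pixels (+x when serpentine — the stage
lag appears mirrored on reversed lines — configurable for other
hardware), and flip odd z-planes along the slow axis.  It is a pure
permutation plus masking: vacated pixels are masked, never wrapped or
interpolated, and the multiset of retained samples is preserved exactly.
Coordinates are 0-based, the fast axis is x, and line parity counts from
line 0 of each plane.

Maps of shift, linewidth, amplitude, gain, SNR and metric are assembled
in phantom coordinates; a multi-peak pixel contributes its
highest-amplitude peak to the scalar maps (a map needs one number per
pixel) while every fitted peak of every pixel is retained in the
accompanying table.

## Metrology

* **Frequency calibration** subtracts the fast-minus-slow differential
  shift of a reference material from the axis, the swept-laser
  equivalent of wavelength calibration.
* **Spectral resolution** is the stated linear subtraction
  measured − reference FWHM (459.2 − 308 → 151 MHz at 20 ms;
  410 − 308 → 102 MHz at 40 ms).  The low-NA reference width defaults to
  308 MHz and is configurable.  The subtraction convention is
  implemented as stated; it is not a deconvolution.
* **Precision curve/slope**: sample std of fitted shift and linewidth
  per integration time; unweighted least squares of log₁₀ std against
  log₁₀ time.  −0.5 marks shot-noise-limited operation, 0 a
  time-independent noise floor.
* **Edge response**: offset + scale·Φ((x−x₀)/σ) fit of a peak-amplitude
  profile across a material boundary; FWHM = 2√(2 ln 2)·σ.  Profiles
  without a dominant monotone transition (R² < 0.5) come back flagged.
* **Scan-range study**: bias/std of fitted parameters versus spectral
  span at fixed frequency *step* (point count scales with span, as a
  swept-frequency instrument behaves).  Held at fixed point count the
  comparison would be confounded: σ grows ∝ √span because on-resonance
  sampling is diluted.  With the fixed step, fidelity plateaus beyond
  ~2 GHz.

## Numerical choices and problem sizes

* Optimizer: `scipy.optimize.curve_fit` (trust-region reflective),
  tolerances 1e-12, analytic-free numerical Jacobian; noiseless
  recovery is at machine level (residual rms < 1e-8).
* The brute-force oracles used in the tests (dense-grid
  maximum-likelihood search with amplitude/baseline projected out;
  finite-difference derivative crossing counts) are implemented
  independently of the library paths they validate.
* Monte-Carlo sizes follow the protocols they emulate: 300 repeats per
  integration time for precision curves, 10,000 spectra for the
  water-classification rate, 100 random parameter draws for the
  crossing-count cross-check.  Phantom grids in the tests are kept at
  tens of pixels per side, which exercises every traversal branch
  (serpentine parity, plane flips, line-shift masking) at full fidelity
  since reconstruction is exact permutation logic, independent of scale.

## Known limitations

* The Lorentzian model assumes symmetric lines; instrument-lineshape
  deconvolution is out of scope (the spectral-resolution subtraction is
  post hoc).
* The classifier decides 1-vs-2 components; 3-peak fits are
  user-invoked, and no information-criterion model comparison is
  offered.
* The stage-delay correction is a whole-pixel shift; sub-pixel
  interpolation is deliberately avoided to keep reconstruction a pure
  permutation.
* Phantoms carry no PSF, aberration, or refractive-index-mismatch
  model; resolution figures are validated as parameter recovery, not
  end-to-end imaging physics.
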