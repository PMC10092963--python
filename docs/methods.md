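# Methods

hepaflow implements the signal-processing chain of a combined non-invasive
liver-function sensor: an optical-densitometry channel that estimates the
indocyanine green (ICG) plasma disappearance rate (PDR) from transmitted
light, and a dynamic-light-scattering (DLS) channel that estimates
microcirculatory blood-flow velocity from the temporal autocorrelation of
scattered laser speckle. This note records the models, the parameter
choices, the numerical decisions, and what the synthetic validation does
and does not demonstrate.

## Densitometry channel

### Model

Transmitted intensity through the finger follows the Beer–Lambert law.
Intensity is measured as voltage `u` on the photodiode load resistor;
because the relative deviation of intensity equals the relative deviation
of voltage, the transduction is

    u = u0 · 10^(−ε·c·z),

with `ε` the decadic extinction coefficient (L·mg⁻¹·cm⁻¹), `z` the optical
path (cm), and `u0` the dye-free reference voltage. After the
recirculation transient ends at `t1`, the concentration decays as

    c(t) = c1 · exp(−0.01 · PDR · (t − t1)),

with `t` in minutes and PDR in %/min (the 0.01 converts %/min into the
exponential rate). The double-log transform

    f(t) = −ln[A(t)/A(t1)] · 100 %,   A = log10(u0/u),

is exactly linear in `t − t1` with slope PDR, so PDR is estimated by
ordinary least squares on f. A direct nonlinear exponential fit is
provided as a diagnostic cross-check only; on clean data the two agree,
and on noisy data the OLS estimate on f is the reported one because it is
the estimator the method defines.

### Uncertainty model

Propagating a voltage noise floor `Δu` through both the reference and the
sample measurement gives the closed-form concentration standard deviation

    Δc(c) = ln10·Δu/(ε·z·u0) · sqrt(1 + exp(2·ln10·ε·c·z)).

At zero dye both terms contribute equally (the √2 floor); the error then
grows exponentially with concentration because the transmitted voltage
shrinks exponentially while its noise does not. This is why there is an
optimal concentration window for the clinical test: enough dye to rise
above the background, not so much that the transmitted signal drowns in
electronic noise.

### Trace segmentation

The method itself prescribes only that the pre-injection signal is
averaged to define the zero point and that the slope after the
recirculation end is fitted; the detection rules are this package's own:

* **Baseline / u0** — mean voltage over all samples before the detected
  injection, minus a 5-sample guard.
* **Injection time t0** — first sample whose absorbance exceeds
  `k`·(baseline absorbance SD), with `k = 5` by default, and stays above
  for 5 consecutive samples. The sustain requirement rejects single-sample
  noise spikes; on the simulated traces t0 is recovered within 2 sample
  periods.
* **Recirculation peak** — first prominent maximum of the lightly smoothed
  absorbance after t0.
* **Recirculation end t1** — a line is fitted to the log-absorbance of the
  trailing half of the post-peak record, where the terminal exponential is
  exactly linear, and extended backwards toward the peak; t1 is the
  earliest sample from which every later sample still lies on that line
  within `max(5·σ_local, 10⁻⁹)`, with σ_local a robust (MAD-based)
  estimate of the local log-absorbance noise. This exploits the slope kink
  between the recirculation flank and the elimination exponential. The
  absolute floor keeps the rule exact on noiseless input: there the
  detected t1 lands on the true kink sample and the recovered PDR matches
  the generating value to better than 10⁻⁶ %/min.

Elimination-window samples whose absorbance is not positive (noise at or
below baseline) are excluded and counted, never clipped: clipping would
bias the slope, exclusion only costs points. Fewer than 10 usable points
is an error, mirroring the "ERROR" outcome a clinical analyzer reports on
unusable records.

Units are fixed as minutes, %/min, mg/L and volts. `ε` and `z` are
configuration inputs; the defaults (0.2 L·mg⁻¹·cm⁻¹, 1 cm) give
absorbance ≈ 0.6 at a typical post-distribution concentration of 3 mg/L,
i.e. a transmitted voltage a quarter of the reference — comfortably inside
the measurable window of the uncertainty model above.

## DLS channel

### Model

Speckle intensity scattered by moving red cells decorrelates on a time
scale inversely proportional to the scatterer velocity. The adopted
correlation model is a Gaussian decay of the normalized intensity
autocorrelation,

    G(τ) = exp(−(τ/τc)²),   τc = 1/(K·ϑ),

with the geometry coefficient

    K = [ω² + σ²·Δx²]^(−1/2),   Δx = λ·l/(π·ω),

where `ω` is the beam radius at the sample (mm), `l` the
scattering-volume-to-detector distance, `σ = l/ρ + 1` the dimensionless
wavefront parameter (plane wave: σ = 1), and `λ` the wavelength. Velocity
follows as ϑ = 1/(τc·K).

The estimation chain is: (1) autocorrelation by the Wiener–Khinchin
theorem — mean subtraction, zero-padding to at least twice the record
length so the circular correlation equals the linear one, inverse FFT of
the periodogram, division by N (the biased, positive-semidefinite
estimator), normalization to G(0) = 1; (2) τc read off at the first
downward crossing of the 1/e level, linearly interpolated between the
bracketing lags, with later noise-induced re-crossings ignored; (3)
ϑ = 1/(K·τc). Lags beyond a tenth of the record are discarded — they are
averaged over too few independent correlation patches to be useful.

Ten replicate records are acquired per measurement and the per-replicate
velocities averaged (mean and sample SD), because capillary flow shows
spontaneous 2–4 s accelerations and a single short record aliases them.
Replicates whose correlation time cannot be extracted are dropped and
counted; only if all fail does the estimate fail.

### Geometry scale

With macroscopic bench values (ω = 0.5 mm, l = 7.5 cm, λ = 650 nm) the
coefficient K is ≈ 2 mm⁻¹, which at mm/s velocities would imply
correlation times of seconds. Measured speckle decorrelation in
backscattering instead happens at the optical wavevector scale
1/q = λ/(4π) ≈ 52 nm, which reproduces the microsecond correlation times
such instruments actually observe (τc ≈ 17 µs at 3 mm/s, ≈ 1 ms at
0.05 mm/s). The simulator therefore defaults to an *effective* geometry —
`OpticalGeometry.effective_backscatter()` — with ω_eff = λ/(4π) and a
negligible far-field speckle term, giving K ≈ 1.93 × 10⁴ mm⁻¹ at 650 nm.
The functional form of K is used unchanged; only the default parameter
values are the effective ones. Bench geometries remain fully supported
through configuration.

### Sampling

The sampling rate is a configuration parameter. Simulations default to
2 MHz with 0.2 s records, chosen so the fastest correlation time in the
0.05–3 mm/s band (≈ 17 µs at 3 mm/s) spans more than 20 samples — the
enforced minimum below which τc would be grid-quantized — while the
slowest (≈ 1 ms) still fits ~200 times into a record, which controls the
variance of the ACF estimate. A scenario whose implied τc is
under-resolved raises an error naming the minimum admissible rate.

## Synthetic-signal generator

The generator replaces the hardware so every estimator is testable by
parameter recovery. It is a pure function of its scenario, seed included:
identical scenarios give bit-identical output.

**Clearance traces.** Concentration is zero before t0, a log-normal bump
between t0 and t1 — rising smoothly from zero, peaking at
t0 + 0.4·(t1 − t0) at `peak_height_ratio`·c1 (default 1.5) and passing
through c1 exactly at t1 — then the exponential decay. Only the peak's
existence, height and end are constrained by the physiology (bolus
recirculation before uniform mixing); the log-normal shape itself is a
modelling choice, as real recordings show only a smooth single-peaked
transient. Voltage is the Beer–Lambert transduction plus additive white
Gaussian noise of SD `noise_rel`·u0 (default 10⁻³, a realistic ADC-scale
noise floor relative to reference). Defaults: injection at 1 min,
recirculation over at 2.5 min, 15 min records at 60 samples/min.

**Speckle records.** Each replicate is a stationary Gaussian process with
ACF exactly exp(−(τ/τc)²), generated by circulant spectral synthesis: the
target autocovariance on a power-of-two circular grid of at least twice
the record length, eigenvalues by FFT, a white complex-Gaussian spectrum
shaped by their square root, transformed back, real part taken. White
Gaussian noise is added at a fluctuation-to-noise power ratio `snr`
(default 10). Two deliberate simplifications: the fluctuation statistics
are Gaussian rather than exponential-intensity speckle — the analysis
chain uses only second-order statistics, which the synthesis matches
exactly — and the noise is white, as no measured noise spectrum is
available for either channel.

**Flow sweep.** The in-silico analogue of the microsphere capillary
calibration: a grid of true velocities, ten replicates each through the
full pipeline, reported as per-velocity mean, SD and relative error.
Volumetric pump rates (mL/h) are not converted to linear velocity — the
capillary bore needed for the conversion is not available — so sweeps are
specified directly in mm/s over the 0.05–3 mm/s band of interest.

### What passing the synthetic suites shows — and what it does not

Recovery on these signals demonstrates that the estimation chain is
correct and quantifies its statistical error under the stated noise
model. It does not exercise motion and tremor artifacts, pulse and
respiration interference, the non-Gaussian single-speckle intensity
statistics, detector shot noise, or drift in u0 — all present in real
recordings. The known noise-floor bias discussed below is intrinsic to
the estimator definition and would be present on hardware data too.

## Numerical notes and known biases

* **Noise-floor bias of τc.** White measurement noise adds its power only
  at lag 0, so the normalized ACF of a noisy record is
  (snr/(snr+1))·exp(−(τ/τc)²) at positive lags. The 1/e readout of that
  deflated curve crosses at τ = τc·sqrt(1 + ln(snr/(snr+1))): at snr = 10
  the correlation time is read ≈ 4.9 % low and velocity ≈ 5 % high. This
  is a property of the defined estimator (normalize at lag 0, read at
  1/e), kept as defined; it is the dominant term in the sweep's ~5–9 %
  relative errors, with replicate-to-replicate ACF fluctuation
  contributing the rest.
* **Finite-record variance.** The SD of the estimated ACF near the
  crossing scales as sqrt(τc/T); at the slowest default velocity
  (0.05 mm/s, τc ≈ 1 ms, T = 0.2 s) this gives ≈ 12 % per-replicate
  velocity scatter, reduced ≈ 3–4 % by the 10-replicate mean.
* **Interpolated crossing.** Linear interpolation between the bracketing
  lags roughly halves the grid-quantization error of a nearest-sample
  readout; both are negligible at the default ≥ 20 samples per τc.
* **Circulant eigenvalues.** The Gaussian ACF decays far inside the
  embedding, so the circulant spectrum is non-negative up to rounding;
  tiny negative eigenvalues are clipped to zero.
* **Degenerate inputs.** Constant speckle records, flat clearance traces,
  truncated records ending at the peak, and non-positive voltages all
  raise typed errors rather than returning numbers.

## Problem sizes

The validation suites run at the sizes the protocols define: clearance
traces of 901 samples (15 min at 60 min⁻¹), 100-seed recovery for the
noisy-PDR suite, and flow sweeps of 12 velocities × 10 replicates ×
400 000 samples (0.2 s at 2 MHz). The full test suite completes in about
two minutes on one CPU; the sweep underlying the headline error bounds
takes about 30 s.

## Limitations

* No artifact rejection: records contaminated by motion must be excluded
  upstream.
* The PDR–microcirculation link is deliberately not modelled: the joint
  report juxtaposes the two estimates without computing a combined index.
* Cardiac-output estimation from the recirculation-peak area is out of
  scope; the segmentation exposes the peak should downstream work need it.
* The σ = l/ρ + 1 wavefront parameterization assumes ρ is given as a
  curvature radius in the same length unit as l; σ may be supplied
  directly to bypass it.
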