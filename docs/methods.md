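# Methods

## Demodulator

The lock-in processes one ADC sample at a time. With the modulation locked
to an exact integer fraction of the sample rate, *f₀ = f_s/m*, the
references `cos(2πn/m)`, `sin(2πn/m)` are exactly periodic in *n* and never
drift relative to the LED drive, which toggles every *m*/2 samples (at the
zero crossings of the sine reference). Multiplying the input by both
references shifts the component at *f₀* to DC in the (X, Y) channel pair;
the exponential moving-average cascade then removes everything that is not
(near) DC. Reporting the magnitude `R = √(X²+Y²)` makes the output
independent of the signal phase, which matters because the LED driver's
turn-on lag phase-shifts the optical waveform by an amount that varies with
modulation frequency.

Conventions fixed by this implementation:

* **Reference amplitude.** References have unit amplitude, so a settled
  tone of amplitude *A* at *f₀* reads *A*/2 and a 0-to-*A* square wave
  reads *A*/π. Any constant factor here cancels in every calibrated
  quantity (slopes, LODs, ratios), so the choice is a pure convention.
* **α ↔ cut-off mapping.** `alpha = 1 − exp(−2π·fc/fs)` (exact placement of
  the single discrete pole). At the operating point this equals the
  small-α linearisation `2π·fc/fs` to five significant figures and gives
  α = 7.854×10⁻⁶ for a 0.25-Hz cut-off at 200 kHz.
* **Initial state and settling.** All accumulators start at zero and no
  burn-in is discarded internally; callers wait `settling_samples` (ten
  time constants by default, ≈ 6.4 s ≈ 1.27×10⁶ samples). The two-stage
  step response is `1 − (1+t/τ)e^(−t/τ)`, so the residual at 10 τ is
  `11·e⁻¹⁰ ≈ 5×10⁻⁴` — the package verifies this against the simulated
  filter directly.
* **Output decimation.** The instantaneous magnitude is emitted every
  `round(fs·output_interval)` samples (round-half-up), with no averaging
  across the interval, mirroring how a microcontroller would stream
  readings. Instantaneous decimation means residual demodulation ripple
  (the 2·f₀ product terms attenuated by the filter skirt) appears as
  reading-to-reading scatter if the bandwidth is widened; at the default
  0.25-Hz bandwidth the ripple is ~10⁻⁴ relative and negligible against
  noise.
* **Precision.** Accumulators are float64. With α ≈ 8×10⁻⁶ a float32
  accumulator cannot represent the per-sample increment once the filter
  approaches its asymptote and stalls ≈ 1 % short; the test suite
  demonstrates this failure mode.
* **Vectorised equivalence.** `demodulate` evaluates the identical
  difference equation via `scipy.signal.lfilter`; the per-sample `step`
  function and the vectorised path agree to ~10⁻¹² relative and are
  cross-checked in the tests, as is the settled output against direct
  Fourier quadrature sums over whole periods.

## Instrument simulator

The generator emulates the statistical and spectral structure of the
front end, not its optics. Signal path (all amplitudes in
ADC-count-equivalent arbitrary units, 1 a.u. = 1 count at the converter):

1. emission + leakage amplitude × LED waveform (square wave through a
   first-order turn-on lag, default 50 µs);
2. + ambient DC + mains sine (default 50 Hz, exposed) + white Gaussian
   noise (default sd 2 counts) at the conditioning node;
3. first-order high-pass at 16 Hz (DC compensation) and second-order
   Butterworth low-pass at 94 kHz (anti-aliasing), both as
   bilinear-transform digital filters — corner frequencies and orders are
   the modelled facts, Butterworth alignment is an assumption;
4. + 1.6-V mid-scale offset, then 12-bit quantisation over 0–3.3 V with
   clipping at the rails (round-half-up; a warning is raised if > 1 % of
   samples clip).

Dose–response: `amplitude(c) = sensitivity·c / (1 + c/quench_scale)` — a
one-parameter saturable form chosen because it is monotone, linear at low
concentration, and captures the observed sublinearity from
dimerisation-induced self-quenching without pretending to model its
chemistry. With the 5 %-deviation criterion below, linearity is lost at
`c* = quench_scale/19`.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| sensitivity | 1×10⁵ a.u./M | ON-amplitude per molar; gives assay-like signal levels well inside the ADC range over nM–µM series |
| quench_scale | 7.4×10⁻⁴ M | places the 5 % linearity breakpoint near 39 µM (q/19), the scale observed for resorufin in a flow cell |
| leakage | 71.14 a.u. | ON-amplitude whose demodulated value (÷π) reproduces a blank of ≈ 22.6 a.u., the magnitude typical of filter leak-through |
| led_tau_on | 50 µs | few-percent first-harmonic loss and ~7° phase shift at 410 Hz — a visible but benign driver lag |
| white_sd | 2 counts | yields blank reading noise of a few 10⁻³ a.u. at the 0.25-Hz bandwidth, i.e. detection limits in the 10²-nM range typical of low-cost fluorimeters |
| ambient_dc, mains_amp | 300, 50 counts | strong interferers relative to µM-scale signals; both are rejected by > 60 dB, which is the point |

The emission `sensitivity` is defined at the ON-state square-wave
amplitude; the demodulated calibration slope is therefore `sensitivity/π`
(plus a ≈ 0.9 % loss from the LED lag and the 16-Hz high-pass). Parameter
recovery in the tests compares against `sensitivity/π` and absorbs the
small systematic inside its 2 % tolerance.

What the simulator does **not** model: photon shot noise and 1/f noise
(no spectral data to anchor them), LED/filter spectra, optical geometry,
drift, and enzyme kinetics. Passing tests therefore demonstrate the
correctness of the demodulation and calibration mathematics under
additive-Gaussian, stationary conditions — not performance claims about
any physical instrument.

## Calibration analysis

* Background subtraction `y = R − R_blank` keeps sub-blank values
  (clipping them would bias the blank statistics).
* Through-origin slope `Σcᵢyᵢ/Σcᵢ²`, unweighted by default (inverse-
  variance weighting is available but off, since per-point sds are often
  poorly estimated from 10-s windows of correlated readings). R² is taken
  about the mean of the included corrected means.
* **LOD convention.** `LOD = 2·σ_blank/slope`, uniformly using the
  *blank's* standard deviation. Published practice sometimes uses the
  sample σ instead; the blank-σ form is adopted as the single documented
  convention because the blank is always measured and its noise is what
  limits detection.
* **Linear range.** Scanning upward in concentration, the largest point
  whose corrected mean is within 5 % (relative) of `slope·c`, all lower
  points also passing. A point whose deviation is within twice its own
  reading sd passes regardless: a departure smaller than the noise cannot
  be attributed to nonlinearity, and without this guard a noisy lowest
  point would spuriously truncate the range to zero.
* Degenerate designs (fewer than two distinct non-zero concentrations)
  raise errors rather than returning ill-defined fits.

## Problem sizes

Closed-form demodulation checks run on ~1.5×10⁶-sample streams (12 time
constants). The parameter-recovery experiment uses an 8-point two-fold
dilution series from 5 µM down (~39 nM), each point settled for 10 τ and
then read for 10 s (100 readings), repeated over 20 seeds; the
detection-limit-versus-noise probe uses white-noise sds of 1, 2 and
4 counts with a shared seed so the comparison is paired. These sizes make
the slope estimate's noise floor (~0.1 %) far smaller than its 2 %
recovery tolerance.

## Known limitations

* The attenuation table measures steady-state tone rejection; it does not
  characterise transient or broadband interference.
* `linear_range_max` reports a tested concentration, not an interpolated
  breakpoint; resolution is limited by the series spacing.
* Readings 0.1 s apart are strongly correlated (τ = 0.64 s), so the sd of
  a 10-s window underestimates the sd of independent readings; the LOD is
  defined on the reading noise as measured, matching bench practice.
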