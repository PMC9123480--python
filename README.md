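# fluorlock

Digital lock-in amplification for fluorescence biosensing, in software: a
streaming dual-phase quadrature demodulator, a synthetic photodetector-signal
generator standing in for the instrument hardware, and the calibration
analysis (sensitivity, 2σ limit of detection, linear and dynamic range) used
to characterise fluorimetric detectors.

## The problem

Low-cost fluorescence detectors read a photodiode in a normally lit lab, so
the fluorescence of interest is buried under ambient light, mains
interference and electronic noise. The classic remedy is synchronous
detection: drive the excitation LED with a square wave at a known frequency
*f₀* and extract only the signal component at *f₀*, rejecting everything
else. This package implements that digital lock-in, the analogue front end
around it as a simulator, and the downstream assay calibration.

## The model

Samples *S(n)* arrive from a 12-bit ADC at rate *f_s* (default 200 kHz). The
modulation frequency is an exact integer fraction of the sample rate,
*f₀ = f_s / m* with *m* = 488 (409.84 Hz), and the LED toggles every *m*/2
samples. Each sample is multiplied by unit-amplitude quadrature references

```
Qx(n) = cos(2πn/m),   Qy(n) = sin(2πn/m)
```

and the products pass through a two-stage exponential moving-average filter
with weight α (default 7.85×10⁻⁶, i.e. a 0.25-Hz cut-off, time constant
τ = 1/(2π·f_c) ≈ 0.64 s):

```
X1(n) = X1(n-1) + α [Qx(n)·S(n) − X1(n-1)]
X2(n) = X2(n-1) + α [X1(n) − X2(n-1)]          (likewise Y1, Y2)
R2(n) = √(X2² + Y2²)
```

*R2* is emitted every 0.1 s. For a settled tone of amplitude *A* at *f₀* it
reads *A*/2; for a 0-to-*A* square wave it reads *A*/π (the first harmonic of
the square wave is 2*A*/π). Tones Δf off-frequency are attenuated by the
two-pole skirt (1 + (Δf/f_c)²); at Δf = 25 Hz that is already ≈ 80 dB. After
a step, the two-stage response leaves a relative residual (1 + t/τ)e^(−t/τ),
which motivates waiting ten time constants (6–7 s) before reading.

Calibration of a dilution series with readings *R* and blank *R_b* uses the
corrected signal *y = R − R_b*, the through-origin least-squares slope
(sensitivity) of *y = slope·c*, the detection limit `LOD = 2σ_blank/slope`,
the largest concentration still within 5 % of the fitted line (linear-range
top, beyond which dye self-quenching makes the response sublinear), and the
dynamic range (linear-range top / LOD).

## Worked example

```python
import fluorlock as fl

cfg = fl.DemodConfig()                      # 200 kHz, m=488, fc=0.25 Hz
print(f"f0 = {cfg.f0:.2f} Hz, tau = {cfg.time_constant:.3f} s, "
      f"settle 10 tau = {fl.settling_samples(cfg)/cfg.fs:.1f} s")

synth = fl.SignalSynthesizer()              # default emission/front-end models
concs = [5e-6 / 2**k for k in range(8)]     # 39 nM .. 5 uM dilution series
curve = fl.calibrate_synthetic_series(concs, synth, cfg, seed=7)
print(f"sensitivity = {curve.sensitivity_:.0f} a.u./M  (R^2 = {curve.r_squared_:.4f})")
print(f"blank = {curve.blank_mean_:.3f} +/- {curve.blank_sd_:.4f} a.u.")
print(f"2-sigma LOD = {curve.lod_2sigma_*1e9:.0f} nM, "
      f"dynamic range = {curve.dynamic_range_:.0f}")
```

prints

```
f0 = 409.84 Hz, tau = 0.637 s, settle 10 tau = 6.4 s
sensitivity = 31494 a.u./M  (R^2 = 0.9995)
blank = 22.442 +/- 0.0031 a.u.
2-sigma LOD = 198 nM, dynamic range = 25
```

The generator's emission sensitivity is 1×10⁵ a.u./M expressed as the
ON-state square-wave amplitude, so the demodulated slope is a factor π lower
(1×10⁵/π ≈ 3.18×10⁴); the fit recovers it to about 1 %. The blank level is
the modulated excitation-light leakage (≈ 71 a.u. ON-amplitude → 22.6 a.u.
at the output), and its 0.003-a.u. reading noise sets the ≈ 200 nM detection
limit. The dynamic range is small here only because this series stops at
5 µM, far below the self-quenching region.

The same workflows are available from the shell:

```bash
fluorlock simulate -c 1e-6 --duration 8 --seed 1 -o stream.csv
fluorlock demod -i stream.csv -o trace.csv --blank 22.44
fluorlock calibrate -i dilution.csv -o result.json
fluorlock characterize -f 409.836 -f 434.836 -f 50
```

Estimator-style classes (`LockInDemodulator`, `CalibrationCurve`) expose the
same functionality with scikit-learn `fit`/`transform`/`get_params`
semantics for use in pipelines.

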