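"""Synthetic photodetector-signal generation.

Emulates the signal chain of an LED-modulated fluorescence detector so the
demodulator and calibration analysis can be exercised without hardware:

* a 50 %-duty square-wave LED drive, phase-locked to the lock-in references
  (the LED toggles every ``m/2`` samples) and smoothed by a first-order
  turn-on lag;
* a fluorescence emission proportional to dye concentration with a
  saturable self-quenching roll-off at high concentration, plus a
  concentration-independent modulated background from excitation-light
  leakage through the emission filter;
* ambient (DC) light, mains interference, and additive white Gaussian
  noise at the photodiode/conditioning node;
* the analogue conditioning chain — a first-order DC-compensation
  high-pass (16 Hz corner) and a second-order anti-aliasing low-pass
  (94 kHz corner) — modelled as bilinear-transform Butterworth filters;
* a mid-scale DC offset and 12-bit quantisation over a 0–3.3 V input
  range (0–4095 counts), with clipping at the rails.

Amplitudes are expressed in ADC-count-equivalent arbitrary units (1 a.u. =
1 count at the converter input).  Streams are reproducible: the same seed
and parameters give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, lfilter, lfilter_zi
from sklearn.base import BaseEstimator

from .config import DemodConfig
from .errors import ClippingWarning, InvalidParameterError

__all__ = [
    "EmissionModel",
    "FrontEndModel",
    "SampleStream",
    "modulation_waveform",
    "fluorescence_amplitude",
    "adc_quantize",
    "synthesize",
    "SignalSynthesizer",
]


@dataclass(frozen=True)
class EmissionModel:
    """Dose–response of the fluorescent sample.

    sensitivity : a.u. per molar
        Low-concentration slope of the modulated emission amplitude (the
        ON-state amplitude at the ADC input per molar of dye).
    quench_scale : molar
        Concentration scale of the saturable self-quenching roll-off; the
        response is ``sensitivity*c / (1 + c/quench_scale)``, linear for
        ``c << quench_scale``.
    leakage : a.u.
        Concentration-independent modulated background (excitation light
        leaking through the long-pass emission filter plus filter
        auto-fluorescence); it rides on the same square wave as the
        fluorescence, so it sets the blank level of the instrument.
    """

    sensitivity: float = 1.0e5
    quench_scale: float = 7.4e-4
    leakage: float = 71.14

    def __post_init__(self):
        if self.sensitivity < 0:
            raise InvalidParameterError("sensitivity must be >= 0")
        if self.quench_scale <= 0:
            raise InvalidParameterError("quench_scale must be > 0")
        if self.leakage < 0:
            raise InvalidParameterError("leakage must be >= 0")


@dataclass(frozen=True)
class FrontEndModel:
    """Analogue front end, interference environment and ADC.

    led_tau_on : s
        First-order turn-on/off time constant of the LED and its driver.
    hp_cutoff : Hz
        Corner of the DC-compensation high-pass (treats everything below
        it as DC and removes it).
    lp_cutoff, lp_order
        Anti-aliasing low-pass corner and order (Butterworth).
    dc_offset_v : volts
        Mid-scale offset added after conditioning so the bipolar signal
        fits the unipolar ADC range.
    ambient_dc : a.u.
        Unmodulated ambient-light level at the photodiode.
    mains_freq, mains_amp
        Mains interference frequency (Hz) and amplitude (a.u.).
    white_sd : a.u.
        Standard deviation of additive white Gaussian noise at the
        conditioning-output node.
    adc_bits, vref
        Converter resolution and full-scale input voltage; counts span
        ``0 .. 2**adc_bits - 1``.
    """

    led_tau_on: float = 5e-5
    hp_cutoff: float = 16.0
    lp_cutoff: float = 94_000.0
    lp_order: int = 2
    dc_offset_v: float = 1.6
    ambient_dc: float = 300.0
    mains_freq: float = 50.0
    mains_amp: float = 50.0
    white_sd: float = 2.0
    adc_bits: int = 12
    vref: float = 3.3

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    @property
    def dc_offset_counts(self) -> float:
        return self.dc_offset_v / self.vref * self.adc_max

    def __post_init__(self):
        if self.hp_cutoff < 0 or self.lp_cutoff <= 0:
            raise InvalidParameterError("filter corners must be positive")
        if self.adc_bits < 1:
            raise InvalidParameterError("adc_bits must be >= 1")
        if self.white_sd < 0 or self.mains_amp < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class SampleStream:
    """A finite sequence of ADC samples at a fixed rate.

    ``counts`` are integers in ``[0, 4095]`` for a 12-bit converter;
    ``metadata`` records the generating parameters for provenance.
    """

    counts: np.ndarray
    fs: float
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64).ravel()
        )

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration(self) -> float:
        return len(self.counts) / self.fs


def modulation_waveform(
    n, m: int, led_tau_on: float = 0.0, fs: float = 200_000.0
) -> np.ndarray:
    """Normalised LED drive waveform at sample indices ``n``.

    An ideal 50 %-duty square wave (ON for ``n % m < m/2``, toggling every
    ``m/2`` samples at the zero crossings of the quadrature reference),
    smoothed by a first-order rise/fall of time constant ``led_tau_on``.
    When a lag is requested the waveform is evolved from index 0, so ``n``
    is expected to be a contiguous range starting at 0 (scalar indices are
    handled by evolving up to that index).
    """
    if m < 4 or m % 2 != 0:
        raise InvalidParameterError(f"m must be an even integer >= 4; got {m}")
    scalar = np.isscalar(n)
    n_arr = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if led_tau_on <= 0.0:
        out = ((n_arr % m) < m // 2).astype(np.float64)
    else:
        n_max = int(n_arr.max())
        full = ((np.arange(n_max + 1) % m) < m // 2).astype(np.float64)
        beta = -math.expm1(-1.0 / (led_tau_on * fs))
        lagged = lfilter([beta], [1.0, -(1.0 - beta)], full)
        out = lagged[n_arr]
    return float(out[0]) if scalar else out


def fluorescence_amplitude(c: float, em: EmissionModel):
    """Modulated emission amplitude (a.u.) at dye concentration ``c`` (molar).

    Saturable form ``sensitivity*c / (1 + c/quench_scale)``: linear at low
    concentration, sublinear above ``quench_scale`` where self-quenching
    (dimerisation, inner filtering) reduces the fluorescence yield.
    Strictly increasing in ``c``.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise InvalidParameterError(f"concentration must be >= 0; got {c}")
    out = em.sensitivity * c_arr / (1.0 + c_arr / em.quench_scale)
    return float(out) if np.isscalar(c) else out


def adc_quantize(v, fe: FrontEndModel) -> np.ndarray:
    """Quantise voltages to ADC counts.

    Linear map of ``[0, vref]`` volts to ``[0, 2**bits - 1]`` counts,
    round-half-up to the nearest count, clipped at both rails.
    """
    x = np.asarray(v, dtype=float) / fe.vref * fe.adc_max
    counts = np.clip(np.floor(x + 0.5), 0, fe.adc_max)
    if np.isscalar(v):
        return int(counts)
    return counts.astype(np.int64)


def synthesize(
    c: float,
    em: EmissionModel,
    fe: FrontEndModel,
    cfg: DemodConfig,
    duration: float,
    seed: int | None = None,
) -> SampleStream:
    """Generate the ADC stream for a sample at concentration ``c``.

    Composes the modulated emission-plus-leakage waveform with ambient
    light, mains interference and white noise, passes it through the
    DC-compensation high-pass and anti-aliasing low-pass, adds the
    mid-scale offset and quantises to counts.  Deterministic for a given
    ``seed``.  If more than 1 % of samples clip at the ADC rails a
    :class:`ClippingWarning` is issued.
    """
    if duration <= 0:
        raise InvalidParameterError(f"duration must be positive; got {duration}")
    fs = cfg.fs
    n_samples = int(math.floor(fs * duration + 0.5))
    n = np.arange(n_samples, dtype=np.int64)

    mod = modulation_waveform(n, cfg.m, fe.led_tau_on, fs)
    amplitude = fluorescence_amplitude(float(c), em) + em.leakage
    signal = amplitude * mod + fe.ambient_dc
    if fe.mains_amp > 0:
        signal = signal + fe.mains_amp * np.sin(2.0 * np.pi * fe.mains_freq * n / fs)
    if fe.white_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, fe.white_sd, n_samples)

    if fe.hp_cutoff > 0:
        bh, ah = butter(1, fe.hp_cutoff, btype="highpass", fs=fs)
        signal = lfilter(bh, ah, signal)
    bl, al = butter(fe.lp_order, fe.lp_cutoff, btype="lowpass", fs=fs)
    signal = lfilter(bl, al, signal)

    signal = signal + fe.dc_offset_counts
    volts = signal * fe.vref / fe.adc_max
    counts = adc_quantize(volts, fe)

    clipped = np.count_nonzero((counts == 0) | (counts == fe.adc_max))
    if clipped > 0.01 * n_samples:
        warnings.warn(
            f"{clipped / n_samples:.1%} of samples clipped at the ADC rails",
            ClippingWarning,
            stacklevel=2,
        )
    return SampleStream(
        counts=counts,
        fs=fs,
        seed=seed,
        metadata={
            "concentration_M": float(c),
            "duration_s": float(duration),
            "emission": asdict(em),
            "frontend": asdict(fe),
            "m": cfg.m,
        },
    )


class SignalSynthesizer(BaseEstimator):
    """Parameterised generator of synthetic instrument streams.

    Thin object wrapper over :func:`synthesize` holding the emission model,
    front-end model and demodulator timing, with scikit-learn style
    ``get_params``/``set_params`` for configuration plumbing.
    """

    def __init__(
        self,
        emission: EmissionModel | None = None,
        frontend: FrontEndModel | None = None,
        fs: float = 200_000.0,
        m: int = 488,
    ):
        self.emission = emission
        self.frontend = frontend
        self.fs = fs
        self.m = m

    def _models(self):
        em = self.emission if self.emission is not None else EmissionModel()
        fe = self.frontend if self.frontend is not None else FrontEndModel()
        cfg = DemodConfig(fs=self.fs, m=self.m)
        return em, fe, cfg

    def sample_stream(
        self, c: float, duration: float, seed: int | None = None
    ) -> SampleStream:
        """Stream for one sample at concentration ``c`` (molar)."""
        em, fe, cfg = self._models()
        return synthesize(c, em, fe, cfg, duration, seed)

    def blank_stream(self, duration: float, seed: int | None = None) -> SampleStream:
        """Stream for the blank (solvent only, LED on)."""
        return self.sample_stream(0.0, duration, seed)
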