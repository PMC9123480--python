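"""Demodulator configuration and the relations between the exponential-filter
weight, the filter cut-off frequency and the time constant.

The lock-in runs at a fixed sample rate ``fs`` and demodulates at the
modulation frequency ``f0 = fs / m``, where ``m`` is the (even) number of
samples per modulation period.  Choosing ``f0`` as an exact integer fraction
of ``fs`` keeps the digital references perfectly periodic and free of timing
drift.  The low-pass stage is a cascade of single-pole exponential
moving-average filters ``y[n] = y[n-1] + alpha*(x[n] - y[n-1])`` whose weight
``alpha`` sets the cut-off frequency and therefore the detection bandwidth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import InvalidParameterError, NarrowbandWarning

__all__ = [
    "DemodConfig",
    "modulation_frequency",
    "alpha_from_cutoff",
    "cutoff_from_alpha",
    "time_constant_from_cutoff",
    "time_constant_from_alpha",
    "settling_samples",
]

#: Default sample rate of the instrument front end, Hz.
DEFAULT_FS = 200_000.0
#: Default samples per modulation period (f0 = fs/m ~ 409.84 Hz).
DEFAULT_M = 488
#: Default exponential-filter weight (cut-off ~ 0.25 Hz at 200 kHz).
DEFAULT_ALPHA = 7.85e-6


def alpha_from_cutoff(fc: float, fs: float = DEFAULT_FS) -> float:
    """Exponential-filter weight for a given -3 dB cut-off frequency.

    Uses the exact single-pole match ``alpha = 1 - exp(-2*pi*fc/fs)``; for
    ``fc << fs`` this reduces to the familiar ``2*pi*fc/fs``.

    Parameters
    ----------
    fc : float
        Cut-off frequency in Hz, ``0 < fc < fs/2``.
    fs : float
        Sample rate in Hz.
    """
    if not 0.0 < fc < fs / 2.0:
        raise InvalidParameterError(
            f"cut-off frequency must satisfy 0 < fc < fs/2; got fc={fc}, fs={fs}"
        )
    return -math.expm1(-2.0 * math.pi * fc / fs)


def cutoff_from_alpha(alpha: float, fs: float = DEFAULT_FS) -> float:
    """Inverse of :func:`alpha_from_cutoff`: ``fc = -fs*ln(1-alpha)/(2*pi)``."""
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1); got {alpha}")
    return -fs * math.log1p(-alpha) / (2.0 * math.pi)


def time_constant_from_cutoff(fc: float) -> float:
    """Single-pole time constant ``tau = 1/(2*pi*fc)`` in seconds."""
    if fc <= 0:
        raise InvalidParameterError(f"cut-off frequency must be positive; got {fc}")
    return 1.0 / (2.0 * math.pi * fc)


def time_constant_from_alpha(alpha: float, fs: float = DEFAULT_FS) -> float:
    """Time constant implied by the filter weight at sample rate ``fs``."""
    return time_constant_from_cutoff(cutoff_from_alpha(alpha, fs))


@dataclass(frozen=True)
class DemodConfig:
    """Fixed parameters of the dual-phase digital lock-in.

    Parameters
    ----------
    fs : float
        ADC sample rate in Hz.
    m : int
        Samples per modulation period; must be even and >= 4 so the LED
        toggles (every ``m/2`` samples) land on integer sample indices.
        The modulation frequency is ``f0 = fs / m``.
    alpha : float
        Weight of each exponential-filter stage, in (0, 1).
    n_stages : int
        Number of cascaded identical filter stages per quadrature channel.
        Two stages give steeper skirts than one at the same cut-off.
    output_interval : float
        Spacing of emitted amplitude readings, seconds.
    """

    fs: float = DEFAULT_FS
    m: int = DEFAULT_M
    alpha: float = DEFAULT_ALPHA
    n_stages: int = 2
    output_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive; got {self.fs}")
        if self.m < 4 or self.m % 2 != 0:
            raise InvalidParameterError(
                f"m must be an even integer >= 4; got {self.m}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError(f"alpha must lie in (0, 1); got {self.alpha}")
        if self.n_stages < 1:
            raise InvalidParameterError(
                f"n_stages must be >= 1; got {self.n_stages}"
            )
        if self.output_interval <= 0:
            raise InvalidParameterError(
                f"output_interval must be positive; got {self.output_interval}"
            )
        # Synchronous detection needs the modulation far above the filter
        # passband, otherwise the 2*f0 product terms leak into the output.
        if self.f0 < 100.0 * self.cutoff:
            warnings.warn(
                f"modulation frequency f0={self.f0:.3g} Hz is less than 100x the "
                f"filter cut-off {self.cutoff:.3g} Hz; demodulation ripple will "
                "be significant",
                NarrowbandWarning,
                stacklevel=2,
            )

    @classmethod
    def from_cutoff(cls, fc: float, **kwargs) -> "DemodConfig":
        """Build a config from a cut-off frequency instead of ``alpha``."""
        fs = kwargs.pop("fs", DEFAULT_FS)
        return cls(fs=fs, alpha=alpha_from_cutoff(fc, fs), **kwargs)

    @property
    def f0(self) -> float:
        """Modulation frequency ``fs / m`` in Hz."""
        return self.fs / self.m

    @property
    def cutoff(self) -> float:
        """Filter cut-off frequency implied by ``alpha``, Hz."""
        return cutoff_from_alpha(self.alpha, self.fs)

    @property
    def time_constant(self) -> float:
        """Per-stage filter time constant, seconds."""
        return time_constant_from_cutoff(self.cutoff)

    @property
    def samples_per_output(self) -> int:
        """Samples between emitted readings (round-half-up)."""
        return int(math.floor(self.fs * self.output_interval + 0.5))


def modulation_frequency(cfg: DemodConfig) -> float:
    """Modulation frequency ``f0 = fs/m`` of a configuration, Hz."""
    return cfg.f0


def settling_samples(cfg: DemodConfig, k: float = 10.0) -> int:
    """Number of samples to wait for the output to settle.

    The single-stage step response reaches ``1 - exp(-k)`` after ``k`` time
    constants; waiting ``k = 10`` time constants is a conservative rule that
    also covers the slower two-stage response (residual ``(1+k)exp(-k)``,
    about 5e-4 at k=10).  Returns ``ceil(k * tau * fs)``.
    """
    if k < 0:
        raise InvalidParameterError(f"k must be non-negative; got {k}")
    return math.ceil(k * cfg.time_constant * cfg.fs)
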