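"""Simulated measurement protocols.

Reproduces, on synthetic streams, the bench protocol used to calibrate the
detector: for each sample the lock-in output is left to settle for ten
filter time constants, then the 0.1-s readings are recorded for a fixed
window to obtain a mean and standard deviation; a dilution series of such
records plus a blank feeds the calibration analysis.
"""

from __future__ import annotations

import numpy as np

from .calibrate import CalibrationCurve, MeasurementRecord
from .config import DemodConfig
from .demod import demodulate
from .simulate import SignalSynthesizer, synthesize

__all__ = ["measure_sample", "simulate_dilution_series", "calibrate_synthetic_series"]


def measure_sample(
    c: float,
    synth: SignalSynthesizer,
    cfg: DemodConfig,
    measure_duration: float = 10.0,
    settle_tau: float = 10.0,
    seed: int | None = None,
) -> MeasurementRecord:
    """Settle, then record ``measure_duration`` seconds of 0.1-s readings.

    Returns the mean and standard deviation of the readings taken after
    ``settle_tau`` time constants, as one calibration record.
    """
    em, fe, _ = synth._models()
    settle = settle_tau * cfg.time_constant
    stream = synthesize(c, em, fe, cfg, settle + measure_duration, seed)
    trace = demodulate(stream, cfg)
    readings = trace.values[trace.times > settle]
    return MeasurementRecord(
        concentration=float(c),
        r2_mean=float(np.mean(readings)),
        r2_sd=float(np.std(readings, ddof=1)) if len(readings) > 1 else 0.0,
        n_readings=len(readings),
    )


def simulate_dilution_series(
    concentrations,
    synth: SignalSynthesizer | None = None,
    cfg: DemodConfig | None = None,
    measure_duration: float = 10.0,
    settle_tau: float = 10.0,
    seed: int = 0,
    include_blank: bool = True,
) -> list[MeasurementRecord]:
    """Measure a dilution series (blank first) on synthetic streams.

    Each concentration gets an independent noise realisation derived from
    ``seed``; the blank is concentration zero.
    """
    if synth is None:
        synth = SignalSynthesizer()
    if cfg is None:
        cfg = DemodConfig(fs=synth.fs, m=synth.m)
    ss = np.random.SeedSequence(seed)
    points = ([0.0] if include_blank else []) + list(concentrations)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(points))]
    return [
        measure_sample(c, synth, cfg, measure_duration, settle_tau, s)
        for c, s in zip(points, seeds)
    ]


def calibrate_synthetic_series(
    concentrations,
    synth: SignalSynthesizer | None = None,
    cfg: DemodConfig | None = None,
    measure_duration: float = 10.0,
    seed: int = 0,
    c_max: float | None = None,
) -> CalibrationCurve:
    """Simulate a dilution series and fit the calibration curve to it."""
    records = simulate_dilution_series(
        concentrations, synth, cfg, measure_duration=measure_duration, seed=seed
    )
    return CalibrationCurve(c_max=c_max).fit(records)
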