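"""CSV/JSON/YAML file formats.

All CSV files are comma-separated, UTF-8, ``.`` decimal, with a mandatory
header line (fixed dialect to avoid locale drift):

* sample stream:   ``sample_index,counts``     (rate lives in the config)
* amplitude trace: ``time_s,R2[,R2_corrected]``
* calibration:     ``concentration_M,r2_mean,r2_sd,n_readings`` — a row
  with concentration 0 is the blank.

Configs are flat key-value YAML.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationResult, MeasurementRecord
from .config import DemodConfig, alpha_from_cutoff
from .demod import RTrace
from .errors import DataFormatError
from .simulate import EmissionModel, FrontEndModel, SampleStream

__all__ = [
    "read_stream",
    "write_stream",
    "write_trace",
    "read_trace",
    "read_calibration",
    "write_calibration_result",
    "read_config",
]


def read_stream(path, fs: float = 200_000.0) -> SampleStream:
    """Read a sample stream CSV (``sample_index,counts``).

    Malformed rows are reported with their line number.  A header-only
    file yields an empty stream with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many parser subclasses
        raise DataFormatError(f"{path}: {exc}") from exc
    for col in ("sample_index", "counts"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column '{col}'")
    if df.empty:
        warnings.warn(f"{path}: stream file contains no samples", UserWarning)
        return SampleStream(counts=np.empty(0, dtype=np.int64), fs=fs)
    counts = pd.to_numeric(df["counts"], errors="coerce")
    bad = counts.isna() | (counts != np.floor(counts))
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise DataFormatError(
            f"{path}: non-integer count on line {line}: {df['counts'].iloc[bad.idxmax()]!r}"
        )
    return SampleStream(counts=counts.to_numpy(dtype=np.int64), fs=fs)


def write_stream(path, stream: SampleStream) -> None:
    """Write a sample stream CSV (``sample_index,counts``)."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(stream)), "counts": stream.counts}
    )
    df.to_csv(path, index=False)


def write_trace(path, trace: RTrace, blank: float | None = None) -> None:
    """Write an amplitude trace CSV.

    Columns ``time_s,R2`` and, when a blank level is supplied, a third
    column ``R2_corrected = R2 - blank`` (recorded both with and without
    background subtraction).
    """
    data = {"time_s": trace.times, "R2": trace.values}
    if blank is not None:
        data["R2_corrected"] = trace.values - blank
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace(path) -> RTrace:
    """Read an amplitude trace CSV written by :func:`write_trace`."""
    df = pd.read_csv(path)
    for col in ("time_s", "R2"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column '{col}'")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1:
        interval = float(np.median(np.diff(times)))
    else:
        interval = 0.1
    return RTrace(
        times=times,
        values=df["R2"].to_numpy(dtype=float),
        output_rate=1.0 / interval,
    )


def read_calibration(path) -> list[MeasurementRecord]:
    """Read a calibration table CSV into measurement records."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    for col in ("concentration_M", "r2_mean"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column '{col}'")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                MeasurementRecord(
                    concentration=float(row["concentration_M"]),
                    r2_mean=float(row["r2_mean"]),
                    r2_sd=float(row.get("r2_sd", 0.0) or 0.0),
                    n_readings=int(row.get("n_readings", 1) or 1),
                )
            )
        except (TypeError, ValueError) as exc:
            raise DataFormatError(f"{path}: bad record on line {i + 2}: {exc}") from exc
    return records


def write_calibration_result(path, result: CalibrationResult) -> None:
    """Write a calibration result as JSON."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_config(path):
    """Read a flat key-value YAML config.

    Recognised keys: demodulator ``fs, m, alpha`` (or ``fc``), ``n_stages``,
    ``output_interval``; any field of :class:`EmissionModel` and
    :class:`FrontEndModel`; plus ``seed``.  Returns
    ``(DemodConfig, EmissionModel, FrontEndModel, seed)``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise DataFormatError(f"{path}: config must be a flat key-value mapping")
    fs = float(raw.get("fs", 200_000.0))
    alpha = raw.get("alpha")
    if alpha is None and "fc" in raw:
        alpha = alpha_from_cutoff(float(raw["fc"]), fs)
    cfg = DemodConfig(
        fs=fs,
        m=int(raw.get("m", 488)),
        alpha=float(alpha) if alpha is not None else 7.85e-6,
        n_stages=int(raw.get("n_stages", 2)),
        output_interval=float(raw.get("output_interval", 0.1)),
    )
    em_fields = {f for f in EmissionModel.__dataclass_fields__}
    fe_fields = {f for f in FrontEndModel.__dataclass_fields__}
    em = EmissionModel(**{k: raw[k] for k in raw.keys() & em_fields})
    fe = FrontEndModel(**{k: raw[k] for k in raw.keys() & fe_fields})
    return cfg, em, fe, int(raw.get("seed", 0))
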