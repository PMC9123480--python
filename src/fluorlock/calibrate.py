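"""Calibration-curve analysis for fluorimetric assays.

Given a dilution series of lock-in readings — mean amplitude and standard
deviation per concentration, plus a blank (solvent only) — this module
computes the quantities used to characterise a fluorescence detector:

* the background-corrected signal ``y = R - R_blank``;
* the assay sensitivity, i.e. the slope of the through-origin least-squares
  line ``y = slope * c`` over the linear range, with its goodness of fit;
* the 2-sigma limit of detection ``LOD = 2 * sigma_blank / slope`` — the
  concentration whose corrected signal equals twice the blank's standard
  deviation;
* the upper end of the linear range (where self-quenching makes the
  response sublinear) and the dynamic range ``linear_range_max / LOD``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "MeasurementRecord",
    "CalibrationResult",
    "background_subtract",
    "fit_through_origin",
    "detection_limit",
    "linear_range_max",
    "dynamic_range",
    "CalibrationCurve",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One concentration point of a dilution series.

    ``r2_mean``/``r2_sd`` are the mean and standard deviation of the
    0.1-s lock-in readings recorded after settling; ``n_readings`` is how
    many readings were averaged.  A record with ``concentration == 0`` is
    a blank.
    """

    concentration: float
    r2_mean: float
    r2_sd: float = 0.0
    n_readings: int = 1

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")
        if self.r2_sd < 0:
            raise InvalidParameterError("r2_sd must be >= 0")
        if self.n_readings < 1:
            raise InvalidParameterError("n_readings must be >= 1")


@dataclass(frozen=True)
class CalibrationResult:
    """Summary of a fitted calibration curve.

    ``sensitivity`` is the through-origin slope in a.u. per molar;
    ``lod_2sigma`` and ``linear_range_max`` are molar; ``dynamic_range``
    is their ratio.
    """

    sensitivity: float
    r_squared: float
    lod_2sigma: float
    linear_range_max: float
    dynamic_range: float
    blank_mean: float = 0.0
    blank_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "sensitivity_au_per_M": self.sensitivity,
            "r_squared": self.r_squared,
            "lod_2sigma_M": self.lod_2sigma,
            "linear_range_max_M": self.linear_range_max,
            "dynamic_range": self.dynamic_range,
            "blank_mean_au": self.blank_mean,
            "blank_sd_au": self.blank_sd,
        }


def background_subtract(r2, r2_blank):
    """Background-corrected signal ``r2 - r2_blank``.

    Sub-blank values are preserved (not clipped): a slightly negative
    corrected blank or low-concentration reading is informative noise.
    """
    return r2 - r2_blank


def fit_through_origin(
    records,
    blank: MeasurementRecord | None = None,
    c_max: float | None = None,
    weighted: bool = False,
):
    """Least-squares fit of ``y = slope * c`` to background-corrected means.

    Parameters
    ----------
    records : sequence of MeasurementRecord
        Non-blank calibration points.
    blank : MeasurementRecord, optional
        The blank; its mean is subtracted from every point.  ``None``
        means the means are already corrected.
    c_max : float, optional
        Only points with ``concentration <= c_max`` enter the fit
        (restricts to the linear range).
    weighted : bool
        If true, weight each point by ``1/sd**2`` (points with zero sd
        get the smallest observed variance).  Off by default.

    Returns
    -------
    (slope, r_squared)
        ``slope = sum(w*c*y)/sum(w*c**2)``; ``r_squared = 1 - SSres/SStot``
        with ``SStot`` taken about the mean of the included ``y``.
    """
    recs = [r for r in records if c_max is None or r.concentration <= c_max]
    if len(recs) < 2:
        raise InsufficientDataError(
            f"need at least 2 records with concentration <= {c_max}; got {len(recs)}"
        )
    c = np.array([r.concentration for r in recs], dtype=float)
    blank_mean = blank.r2_mean if blank is not None else 0.0
    y = np.array([r.r2_mean for r in recs], dtype=float) - blank_mean
    if np.all(c == 0):
        raise DegenerateDesignError("all concentrations are zero")
    if np.unique(c).size < 2:
        raise DegenerateDesignError(
            "a single distinct concentration cannot constrain a calibration line"
        )
    if weighted:
        sd = np.array([r.r2_sd for r in recs], dtype=float)
        positive = sd[sd > 0]
        if positive.size == 0:
            w = np.ones_like(c)
        else:
            sd = np.where(sd > 0, sd, positive.min())
            w = 1.0 / sd**2
    else:
        w = np.ones_like(c)
    slope = float(np.sum(w * c * y) / np.sum(w * c**2))
    ss_res = float(np.sum(w * (y - slope * c) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r_squared


def detection_limit(slope: float, sigma_blank: float) -> float:
    """2-sigma limit of detection, ``2 * sigma_blank / slope`` (molar).

    The concentration at which the corrected signal first exceeds twice
    the blank's standard deviation, obtained by extrapolating the
    calibration line down to ``y = 2*sigma_blank``.
    """
    if slope <= 0:
        raise InvalidParameterError(
            f"detection limit requires a positive calibration slope; got {slope}"
        )
    if sigma_blank < 0:
        raise InvalidParameterError("sigma_blank must be >= 0")
    return 2.0 * sigma_blank / slope


def linear_range_max(
    records,
    slope: float,
    blank: MeasurementRecord | None = None,
    tol: float = 0.05,
) -> float:
    """Upper end of the linear range (molar).

    Scanning upward from the lowest concentration, returns the largest
    concentration whose background-corrected mean lies within relative
    deviation ``tol`` of ``slope * c``, requiring every lower concentration
    to pass as well; if every point passes, the highest tested
    concentration is returned.  A point whose absolute deviation is within
    twice its own reading standard deviation also passes, since a
    departure smaller than the noise cannot be attributed to nonlinearity.
    """
    recs = sorted(records, key=lambda r: r.concentration)
    if not recs:
        raise InsufficientDataError("no records to scan for linearity")
    blank_mean = blank.r2_mean if blank is not None else 0.0
    last_ok = 0.0
    for r in recs:
        expected = slope * r.concentration
        dev = abs((r.r2_mean - blank_mean) - expected)
        ok = dev <= tol * abs(expected) or dev <= 2.0 * r.r2_sd
        if not ok:
            break
        last_ok = r.concentration
    return last_ok


def dynamic_range(linear_range_max: float, lod: float) -> float:
    """Ratio of the largest linear concentration to the detection limit."""
    if lod <= 0:
        raise InvalidParameterError(f"detection limit must be positive; got {lod}")
    return linear_range_max / lod


def _records_from_input(X, y=None, sd=None):
    """Coerce fit input into (points, blank) record lists.

    Accepts a DataFrame with columns ``concentration_M, r2_mean[, r2_sd,
    n_readings]``, a sequence of :class:`MeasurementRecord`, or a
    concentration array plus ``y`` (and optional ``sd``) arrays.  Records
    with zero concentration are pooled into the blank.
    """
    if isinstance(X, pd.DataFrame):
        recs = [
            MeasurementRecord(
                concentration=float(row["concentration_M"]),
                r2_mean=float(row["r2_mean"]),
                r2_sd=float(row.get("r2_sd", 0.0)),
                n_readings=int(row.get("n_readings", 1)),
            )
            for _, row in X.iterrows()
        ]
    elif len(X) and isinstance(next(iter(X)), MeasurementRecord):
        recs = list(X)
    else:
        c = np.asarray(X, dtype=float).ravel()
        if y is None:
            raise InsufficientDataError("y (mean readings) required with array input")
        yv = np.asarray(y, dtype=float).ravel()
        sdv = (
            np.zeros_like(c)
            if sd is None
            else np.asarray(sd, dtype=float).ravel()
        )
        recs = [
            MeasurementRecord(concentration=ci, r2_mean=yi, r2_sd=si)
            for ci, yi, si in zip(c, yv, sdv)
        ]
    blanks = [r for r in recs if r.concentration == 0.0]
    points = [r for r in recs if r.concentration > 0.0]
    blank = None
    if blanks:
        blank = MeasurementRecord(
            concentration=0.0,
            r2_mean=float(np.mean([b.r2_mean for b in blanks])),
            r2_sd=float(np.sqrt(np.mean([b.r2_sd**2 for b in blanks]))),
            n_readings=sum(b.n_readings for b in blanks),
        )
    return points, blank


class CalibrationCurve(RegressorMixin, BaseEstimator):
    """Through-origin calibration fit with LOD and dynamic-range analysis.

    Fits ``R_corrected = sensitivity * c`` to a dilution series, estimating
    the sensitivity, its goodness of fit, the 2-sigma detection limit from
    the blank's noise, the end of the linear range, and the dynamic range.

    Parameters
    ----------
    c_max : float or None
        Restrict the slope fit to concentrations at or below this value
        (the known linear range); ``None`` fits all points.
    tol : float
        Relative-deviation threshold of the linear-range scan.
    weighted : bool
        Weight the slope fit by inverse reading variance.

    Attributes
    ----------
    sensitivity_ : float
        Fitted slope, a.u. per molar.
    r_squared_ : float
    lod_2sigma_ : float
    linear_range_max_ : float
    dynamic_range_ : float
    blank_mean_, blank_sd_ : float
    result_ : CalibrationResult
    """

    def __init__(self, c_max: float | None = None, tol: float = 0.05,
                 weighted: bool = False):
        self.c_max = c_max
        self.tol = tol
        self.weighted = weighted

    def fit(self, X, y=None, sd=None):
        points, blank = _records_from_input(X, y, sd)
        if blank is None:
            blank = MeasurementRecord(concentration=0.0, r2_mean=0.0, r2_sd=0.0)
        slope, r2 = fit_through_origin(
            points, blank=blank, c_max=self.c_max, weighted=self.weighted
        )
        if slope <= 0:
            raise DegenerateDesignError(
                f"fitted sensitivity is non-positive ({slope}); not a valid assay"
            )
        lod = detection_limit(slope, blank.r2_sd)
        lrm = linear_range_max(points, slope, blank=blank, tol=self.tol)
        self.sensitivity_ = slope
        self.r_squared_ = r2
        self.lod_2sigma_ = lod
        self.linear_range_max_ = lrm
        self.dynamic_range_ = lrm / lod if lod > 0 else float("inf")
        self.blank_mean_ = blank.r2_mean
        self.blank_sd_ = blank.r2_sd
        self.result_ = CalibrationResult(
            sensitivity=slope,
            r_squared=r2,
            lod_2sigma=lod,
            linear_range_max=lrm,
            dynamic_range=self.dynamic_range_,
            blank_mean=blank.r2_mean,
            blank_sd=blank.r2_sd,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted background-corrected signal at concentrations ``X``."""
        c = np.asarray(X, dtype=float).ravel()
        return self.sensitivity_ * c
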