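"""Figures of merit for calibration and validation.

R^2, RMSE (used for RMSEC/RMSECV/RMSEP depending on which predictions
are fed in), relative standard deviation (RSD%), the 3.3sigma/s and
10sigma/s detection/quantification limits, and the predicted-vs-
reference calibration line.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .preprocess import PreprocessConfig, apply_chain
from .spectra import SpectrumSet


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding (report style), e.g. 0.51095 -> 0.5110."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length vectors with at least 2 points")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant reference vector")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error sqrt(sum (y_i - yhat_i)^2 / n)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("need non-empty, equal-length vectors")
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def rsd(predictions: np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * SD(n-1) / mean."""
    p = np.asarray(predictions, dtype=float)
    if p.size < 2:
        raise ValueError("RSD needs at least 2 predictions")
    mean = p.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero-mean predictions")
    return float(100.0 * p.std(ddof=1) / mean)


@dataclass(frozen=True)
class DetectionLimits:
    """3.3sigma/s and 10sigma/s limits; sigma is the SD of predicted
    contents (w/w%) and s the calibration-curve slope."""

    sigma: float
    slope: float
    lod: float
    loq: float


def detection_limits(sigma: float, slope: float) -> DetectionLimits:
    if slope == 0:
        raise ValueError("zero calibration slope")
    if sigma < 0:
        raise ValueError("negative sigma")
    return DetectionLimits(
        sigma=float(sigma),
        slope=float(slope),
        lod=3.3 * sigma / abs(slope),
        loq=10.0 * sigma / abs(slope),
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line yhat = intercept + slope * y_ref with its R^2."""

    slope: float
    intercept: float
    r_squared: float


def fit_calibration_curve(reference: np.ndarray, predicted: np.ndarray) -> CalibrationCurve:
    """Ordinary least squares of predicted content on reference content."""
    x = np.asarray(reference, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if x.size < 3 or x.shape != yp.shape:
        raise ValueError("need at least 3 (reference, predicted) pairs")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("degenerate reference values")
    slope = float(xc @ (yp - yp.mean())) / denom
    intercept = float(yp.mean() - slope * x.mean())
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared(yp, intercept + slope * x),
    )


@dataclass(frozen=True)
class ValidationReport:
    """Independent-validation outcome of one calibrated model."""

    reference: np.ndarray
    predicted: np.ndarray
    rmsep: float
    r_squared: float
    rsd_precision: float | None
    rsd_repeatability: float | None
    rsd_stability: float | None

    @property
    def n(self) -> int:
        return int(self.reference.size)

    @property
    def y_bar(self) -> float:
        return float(self.reference.mean())

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.tolist(),
            "predicted": self.predicted.tolist(),
            "rmsep": self.rmsep,
            "r_squared": self.r_squared,
            "rsd_precision": self.rsd_precision,
            "rsd_repeatability": self.rsd_repeatability,
            "rsd_stability": self.rsd_stability,
            "n": self.n,
            "y_bar": self.y_bar,
        }


def predict_set(model, chain: PreprocessConfig, sset: SpectrumSet) -> np.ndarray:
    """Apply a fitted pretreatment chain, then the PLS model, to a set."""
    from . import pls as _pls

    return _pls.predict(model, apply_chain(chain, sset).intensities)


def validate_model(
    model,
    chain: PreprocessConfig,
    validation: SpectrumSet,
    precision_set: SpectrumSet | None = None,
    repeatability_set: SpectrumSet | None = None,
    stability_set: SpectrumSet | None = None,
) -> ValidationReport:
    """Predict the validation samples and the 45%-level replicate sets.

    RMSEP and R^2 come from the validation pairs; each replicate set
    (>= 2 spectra of the same sample) yields one RSD%.  Replicate sets
    are optional; their RSDs are None when absent.
    """
    if not validation.has_known_fractions:
        raise ValueError("validation set must have known fractions")
    predicted = predict_set(model, chain, validation)
    reference = validation.fractions

    def _rsd(s: SpectrumSet | None) -> float | None:
        if s is None:
            return None
        return rsd(predict_set(model, chain, s))

    return ValidationReport(
        reference=reference.copy(),
        predicted=predicted,
        rmsep=rmse(reference, predicted),
        r_squared=r_squared(reference, predicted),
        rsd_precision=_rsd(precision_set),
        rsd_repeatability=_rsd(repeatability_set),
        rsd_stability=_rsd(stability_set),
    )
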