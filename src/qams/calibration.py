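"""Log-log (power-law) calibration of a nonlinear ELSD response.

An evaporative light scattering detector responds to mass, not absorbance,
and its peak area follows a power law in concentration,

    A = 10**b * C**F,

which is linear in log-log coordinates: lg A = F * lg C + b (``lg`` is the
base-10 logarithm throughout). This module fits that line per analyte by
ordinary least squares, inverts it to read concentrations off measured
areas, and derives signal-to-noise detection limits.

The estimator :class:`PowerLawCalibrator` is the sklearn-style surface;
:func:`fit_loglog_calibration` and friends are thin functional wrappers
operating on the frozen :class:`CalibrationCurve` record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    CalibrationRangeWarning,
    DegenerateCurveError,
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "Analyte",
    "CalibrationLevel",
    "CalibrationSeries",
    "CalibrationCurve",
    "SensitivityLimits",
    "PowerLawCalibrator",
    "fit_loglog_calibration",
    "predict_concentration",
    "predict_area",
    "estimate_lod_loq",
]


@dataclass(frozen=True)
class Analyte:
    """One compound in the panel, e.g. a fructooligosaccharide GF1..GF8.

    ``is_marker`` flags the single reference standard (the marker) whose
    physical standard anchors all single-marker quantification.
    """

    id: str
    name: str = ""
    is_marker: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("analyte id must be nonempty")


@dataclass(frozen=True)
class CalibrationLevel:
    """One dilution level: a known concentration and the measured peak area."""

    level_index: int
    concentration: float  # µg/mL
    area: float  # arbitrary detector units

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DomainError(
                f"level {self.level_index}: concentration must be > 0, "
                f"got {self.concentration}"
            )
        if self.area <= 0:
            raise DomainError(
                f"level {self.level_index}: area must be > 0, got {self.area}"
            )


@dataclass(frozen=True)
class CalibrationSeries:
    """An analyte's dilution series of :class:`CalibrationLevel` records.

    Concentrations must be strictly monotone across levels and level indices
    unique. A series may hold a single level (some relative-correction
    formulas are defined per level); fitting a curve requires at least three.
    """

    analyte: Analyte
    levels: tuple[CalibrationLevel, ...]

    def __post_init__(self) -> None:
        if isinstance(self.levels, list):
            object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 1:
            raise InsufficientDataError("a calibration series needs >= 1 level")
        idx = [lv.level_index for lv in self.levels]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate level_index in series {self.analyte.id}")
        conc = [lv.concentration for lv in self.levels]
        diffs = np.diff(conc)
        if len(conc) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(
                f"concentrations not strictly monotone in series {self.analyte.id}"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([lv.concentration for lv in self.levels], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([lv.area for lv in self.levels], dtype=float)

    def level_map(self) -> dict[int, CalibrationLevel]:
        return {lv.level_index: lv for lv in self.levels}


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted log-log response line lg A = slope * lg C + intercept.

    ``range_low``/``range_high`` bound the calibrated concentration range;
    ``None`` means unknown (hand-built curves), in which case inverse
    prediction never warns about extrapolation.
    """

    analyte: Analyte
    slope: float
    intercept: float
    r_squared: float | None = None
    range_low: float | None = None
    range_high: float | None = None
    n_levels: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")
        if (
            self.range_low is not None
            and self.range_high is not None
            and not self.range_low < self.range_high
        ):
            raise ValueError("range_low must be < range_high")


@dataclass(frozen=True)
class SensitivityLimits:
    """Limit of detection and limit of quantification, in µg/mL."""

    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not 0 < self.lod < self.loq:
            raise ValueError(f"need 0 < lod < loq, got lod={self.lod}, loq={self.loq}")


class PowerLawCalibrator(RegressorMixin, BaseEstimator):
    """Power-law detector calibration fitted by OLS in log-log space.

    Parameters
    ----------
    min_levels : int, default=3
        Minimum number of calibration levels required to fit.

    Attributes
    ----------
    slope_ : float
        Fitted exponent F of ``A = 10**b * C**F``.
    intercept_ : float
        Fitted base-10 log intercept b.
    r_squared_ : float
        Coefficient of determination of the log-log fit.
    range_low_, range_high_ : float
        Smallest and largest calibrated concentration.
    n_levels_ : int
        Number of levels used in the fit.

    Examples
    --------
    >>> cal = PowerLawCalibrator().fit([10, 100, 1000], [10.0, 1000.0, 100000.0])
    >>> round(cal.slope_, 10), round(cal.intercept_, 10)
    (2.0, -1.0)
    >>> float(cal.inverse_predict([10.0])[0])
    10.0
    """

    def __init__(self, min_levels: int = 3):
        self.min_levels = min_levels

    def fit(self, X, y):
        """Fit the log-log line to concentrations ``X`` and areas ``y``."""
        C = np.asarray(X, dtype=float).reshape(-1)
        A = np.asarray(y, dtype=float).reshape(-1)
        if C.shape != A.shape:
            raise ValueError("concentration and area arrays differ in length")
        if C.size < self.min_levels:
            raise InsufficientDataError(
                f"need >= {self.min_levels} levels to fit, got {C.size}"
            )
        if np.any(C <= 0) or np.any(A <= 0):
            raise DomainError("concentrations and areas must be > 0 (log domain)")
        if np.ptp(C) == 0:
            raise DegenerateDesignError("all concentrations identical; cannot fit")
        res = stats.linregress(np.log10(C), np.log10(A))
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.range_low_ = float(C.min())
        self.range_high_ = float(C.max())
        self.n_levels_ = int(C.size)
        return self

    def predict(self, X):
        """Forward model: peak areas expected at concentrations ``X``."""
        self._check_fitted()
        C = np.asarray(X, dtype=float).reshape(-1)
        if np.any(C <= 0):
            raise DomainError("concentration must be > 0")
        return 10.0 ** (self.slope_ * np.log10(C) + self.intercept_)

    def inverse_predict(self, y, warn_out_of_range: bool = True):
        """Concentrations read off measured areas ``y`` (inverse calibration)."""
        self._check_fitted()
        A = np.asarray(y, dtype=float).reshape(-1)
        if np.any(A <= 0):
            raise DomainError("area must be > 0")
        if self.slope_ == 0:
            raise DegenerateCurveError("slope is zero; curve not invertible")
        C = 10.0 ** ((np.log10(A) - self.intercept_) / self.slope_)
        if warn_out_of_range and np.any(
            (C < self.range_low_) | (C > self.range_high_)
        ):
            warnings.warn(
                "predicted concentration outside calibrated range "
                f"[{self.range_low_:g}, {self.range_high_:g}]",
                CalibrationRangeWarning,
                stacklevel=2,
            )
        return C

    def lod_loq(self, noise_sd: float) -> SensitivityLimits:
        """Detection limits at signal-to-noise 3 (LOD) and 10 (LOQ)."""
        self._check_fitted()
        curve = self.to_curve()
        return estimate_lod_loq(curve, noise_sd)

    def to_curve(self, analyte: Analyte | None = None) -> CalibrationCurve:
        """Freeze the fitted state into a :class:`CalibrationCurve` record."""
        self._check_fitted()
        return CalibrationCurve(
            analyte=analyte or Analyte("unnamed"),
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=min(self.r_squared_, 1.0),
            range_low=self.range_low_,
            range_high=self.range_high_,
            n_levels=self.n_levels_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise RuntimeError(
                "PowerLawCalibrator instance is not fitted yet; call fit first"
            )


def fit_loglog_calibration(series: CalibrationSeries) -> CalibrationCurve:
    """OLS fit of lg(area) on lg(concentration) for one analyte's series."""
    cal = PowerLawCalibrator().fit(series.concentrations, series.areas)
    return cal.to_curve(series.analyte)


def predict_concentration(
    curve: CalibrationCurve, area: float, warn_out_of_range: bool = True
) -> float:
    """Invert a curve: the concentration whose predicted area equals ``area``.

    Emits :class:`CalibrationRangeWarning` (never an error) when the result
    falls outside the curve's calibrated range, since unknowns may legitimately
    be diluted into range afterwards.
    """
    if area <= 0:
        raise DomainError(f"area must be > 0, got {area}")
    if curve.slope == 0:
        raise DegenerateCurveError("slope is zero; curve not invertible")
    conc = 10.0 ** ((math.log10(area) - curve.intercept) / curve.slope)
    if (
        warn_out_of_range
        and curve.range_low is not None
        and curve.range_high is not None
        and not (curve.range_low <= conc <= curve.range_high)
    ):
        warnings.warn(
            f"{curve.analyte.id}: concentration {conc:g} outside calibrated "
            f"range [{curve.range_low:g}, {curve.range_high:g}]",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return conc


def predict_area(curve: CalibrationCurve, concentration: float) -> float:
    """Forward model: expected peak area at a concentration."""
    if concentration <= 0:
        raise DomainError(f"concentration must be > 0, got {concentration}")
    return 10.0 ** (curve.slope * math.log10(concentration) + curve.intercept)


def estimate_lod_loq(curve: CalibrationCurve, noise_sd: float) -> SensitivityLimits:
    """LOD/LOQ as the concentrations whose predicted areas hit 3 and 10 times
    the baseline noise SD (the signal-to-noise convention)."""
    if noise_sd <= 0:
        raise DomainError(f"noise_sd must be > 0, got {noise_sd}")
    if curve.slope == 0:
        raise DegenerateCurveError("slope is zero; limits undefined")
    lod = 10.0 ** ((math.log10(3.0 * noise_sd) - curve.intercept) / curve.slope)
    loq = 10.0 ** ((math.log10(10.0 * noise_sd) - curve.intercept) / curve.slope)
    return SensitivityLimits(lod=lod, loq=loq)
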