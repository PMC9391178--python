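"""Relative correction factors (RCFs) of each analyte against a single marker.

With a nonlinear (power-law) ELSD response there is no single agreed way to
define the factor relating the marker's response to another analyte's. Six
conventions circulate in the single-marker (QAMS) literature:

========  ==================================================================
method    definition
========  ==================================================================
A         read every analyte level off the *marker's* log-log curve
          (C_detected = 10**((lg A - b_s)/F_s)); RCF = C_detected / C,
          averaged over levels
B         ratio of fitted log-log slopes, F_k / F_s
C         per level, (C_s / lg A_s) / (C_k / lg A_k), averaged
D         per level, (lg C_k / lg A_k) / (lg C_s / lg A_s), averaged
E         per level, (A_s / C_s) / (A_k / C_k) — the linear-detector
          response-factor ratio — averaged
F         RCF = 1.00 for every analyte (no correction)
========  ==================================================================

Subscript ``s`` is the single marker, ``k`` any analyte. Methods A, C, D, E
average level-wise values arithmetically; B and F have no per-level detail.
Only method A uses the marker curve's intercept, which is why it alone can
absorb an intercept shift between analytes whose slopes agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import (
    Analyte,
    CalibrationCurve,
    CalibrationSeries,
    fit_loglog_calibration,
)
from .exceptions import (
    DegenerateCurveError,
    DegenerateLevelWarning,
    DomainError,
    LogDomainWarning,
    PairingError,
    PanelLookupError,
)

__all__ = [
    "RCF_METHODS",
    "RCFEntry",
    "RCFTable",
    "rcf_method_a",
    "rcf_method_b",
    "rcf_method_c",
    "rcf_method_d",
    "rcf_method_e",
    "rcf_method_f",
    "build_rcf_table",
]

RCF_METHODS = ("A", "B", "C", "D", "E", "F")

#: Methods whose RCF is an arithmetic mean over concentration levels.
LEVEL_AVERAGED = frozenset({"A", "C", "D", "E"})


@dataclass(frozen=True)
class RCFEntry:
    """One analyte's RCF under one method.

    ``per_level`` holds ``(level_index, level_rcf)`` pairs for the
    level-averaged methods (A, C, D, E) and is empty for B and F.
    """

    analyte: Analyte
    method: str
    value: float
    per_level: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method not in RCF_METHODS:
            raise ValueError(f"unknown RCF method {self.method!r}")
        if not self.value > 0:
            raise DomainError(f"RCF must be > 0, got {self.value}")


@dataclass(frozen=True)
class RCFTable:
    """Per-analyte RCFs against one marker under one method."""

    marker: Analyte
    method: str
    entries: Mapping[str, RCFEntry]

    def __getitem__(self, analyte_id: str) -> RCFEntry:
        try:
            return self.entries[analyte_id]
        except KeyError:
            raise PanelLookupError(
                f"no RCF entry for analyte {analyte_id!r} (method {self.method})"
            ) from None

    def values(self, rounding: int | None = None) -> dict[str, float]:
        out = {aid: e.value for aid, e in self.entries.items()}
        if rounding is not None:
            out = {aid: round(v, rounding) for aid, v in out.items()}
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-level audit table (one row per analyte-level)."""
        rows = []
        for aid, e in self.entries.items():
            if e.per_level:
                for idx, v in e.per_level:
                    rows.append(
                        {"method": self.method, "analyte_id": aid,
                         "level_index": idx, "level_rcf": v, "rcf": e.value}
                    )
            else:
                rows.append(
                    {"method": self.method, "analyte_id": aid,
                     "level_index": pd.NA, "level_rcf": np.nan, "rcf": e.value}
                )
        return pd.DataFrame(rows)


def _as_entry(analyte, method, per_level):
    per_level = tuple(per_level)
    value = float(np.mean([v for _, v in per_level]))
    return RCFEntry(analyte=analyte, method=method, value=value, per_level=per_level)


def rcf_method_a(
    marker_curve: CalibrationCurve, analyte_series: CalibrationSeries
) -> RCFEntry:
    """Apparent-over-true concentration ratio on the marker's curve.

    Each analyte level's area is read off the marker's fitted curve to give
    an apparent concentration C_detected; the level RCF is C_detected / C and
    the entry value is the mean over levels.
    """
    if marker_curve.slope == 0:
        raise DegenerateCurveError("marker slope is zero")
    per_level = []
    for lv in analyte_series.levels:
        c_det = 10.0 ** (
            (np.log10(lv.area) - marker_curve.intercept) / marker_curve.slope
        )
        per_level.append((lv.level_index, c_det / lv.concentration))
    return _as_entry(analyte_series.analyte, "A", per_level)


def rcf_method_b(
    marker_curve: CalibrationCurve, analyte_curve: CalibrationCurve
) -> RCFEntry:
    """Ratio of fitted log-log slopes, F_k / F_s."""
    if marker_curve.slope == 0:
        raise DegenerateCurveError("marker slope is zero")
    return RCFEntry(
        analyte=analyte_curve.analyte,
        method="B",
        value=analyte_curve.slope / marker_curve.slope,
    )


def _paired_levels(marker_series, analyte_series):
    ms, ks = marker_series.level_map(), analyte_series.level_map()
    if set(ms) != set(ks):
        raise PairingError(
            f"level indices differ: marker {sorted(ms)} vs "
            f"analyte {sorted(ks)} ({analyte_series.analyte.id})"
        )
    return [(i, ms[i], ks[i]) for i in sorted(ms)]


def _warn_small_areas(*series):
    for s in series:
        if np.any(s.areas < 1.0):
            warnings.warn(
                f"{s.analyte.id}: areas below 1 give negative lg(area); "
                "the per-level formula changes sign there",
                LogDomainWarning,
                stacklevel=3,
            )


def rcf_method_c(
    marker_series: CalibrationSeries, analyte_series: CalibrationSeries
) -> RCFEntry:
    """Per level, (C_s / lg A_s) / (C_k / lg A_k), averaged over paired levels."""
    _warn_small_areas(marker_series, analyte_series)
    per_level = []
    for i, m, k in _paired_levels(marker_series, analyte_series):
        lga_s, lga_k = np.log10(m.area), np.log10(k.area)
        if lga_s == 0 or lga_k == 0:
            raise DomainError(
                f"level {i}: area of exactly 1 makes lg(area) zero; "
                "method C divides by it"
            )
        per_level.append((i, (m.concentration / lga_s) / (k.concentration / lga_k)))
    return _as_entry(analyte_series.analyte, "C", per_level)


def rcf_method_d(
    marker_series: CalibrationSeries, analyte_series: CalibrationSeries
) -> RCFEntry:
    """Per level, (lg C_k / lg A_k) / (lg C_s / lg A_s), averaged."""
    _warn_small_areas(marker_series, analyte_series)
    per_level = []
    for i, m, k in _paired_levels(marker_series, analyte_series):
        lgc_s, lgc_k = np.log10(m.concentration), np.log10(k.concentration)
        lga_s, lga_k = np.log10(m.area), np.log10(k.area)
        if lgc_s == 0 or lgc_k == 0:
            warnings.warn(
                f"level {i}: concentration of exactly 1 makes lg(C) zero; "
                "method D is degenerate there",
                DegenerateLevelWarning,
                stacklevel=2,
            )
        if lga_s == 0 or lga_k == 0 or lgc_s == 0:
            raise DomainError(
                f"level {i}: zero log term makes method D undefined"
            )
        per_level.append((i, (lgc_k / lga_k) / (lgc_s / lga_s)))
    return _as_entry(analyte_series.analyte, "D", per_level)


def rcf_method_e(
    marker_series: CalibrationSeries, analyte_series: CalibrationSeries
) -> RCFEntry:
    """Per level, the linear response-factor ratio (A_s/C_s)/(A_k/C_k), averaged."""
    per_level = []
    for i, m, k in _paired_levels(marker_series, analyte_series):
        per_level.append(
            (i, (m.area / m.concentration) / (k.area / k.concentration))
        )
    return _as_entry(analyte_series.analyte, "E", per_level)


def rcf_method_f(analyte: Analyte) -> RCFEntry:
    """No correction: RCF = 1.00 (quantify everything as if it were the marker)."""
    return RCFEntry(analyte=analyte, method="F", value=1.0)


def build_rcf_table(
    panel: Mapping[str, CalibrationSeries],
    marker_id: str,
    method: str,
    rounding: int | None = None,
) -> RCFTable:
    """Assemble one method's RCF table for a whole calibration panel.

    Parameters
    ----------
    panel : mapping of analyte id to CalibrationSeries
        Must include the marker. Methods A and B fit log-log curves from the
        series; C, D, E pair levels by ``level_index``.
    marker_id : str
        The single marker (e.g. ``"GF3"``).
    method : {"A", "B", "C", "D", "E", "F"}
    rounding : int, optional
        Decimal places applied to the *reported* values; ``None`` keeps full
        precision. Per-level detail is never rounded.
    """
    if method not in RCF_METHODS:
        raise PanelLookupError(f"unknown RCF method {method!r}")
    if marker_id not in panel:
        raise PanelLookupError(f"marker {marker_id!r} not present in panel")
    marker_series = panel[marker_id]
    marker_curve = None
    if method in ("A", "B"):
        marker_curve = fit_loglog_calibration(marker_series)

    entries: dict[str, RCFEntry] = {}
    for aid, series in panel.items():
        if method == "A":
            e = rcf_method_a(marker_curve, series)
        elif method == "B":
            e = rcf_method_b(marker_curve, fit_loglog_calibration(series))
        elif method == "C":
            e = rcf_method_c(marker_series, series)
        elif method == "D":
            e = rcf_method_d(marker_series, series)
        elif method == "E":
            e = rcf_method_e(marker_series, series)
        else:
            e = rcf_method_f(series.analyte)
        if rounding is not None:
            e = RCFEntry(
                analyte=e.analyte,
                method=e.method,
                value=round(e.value, rounding),
                per_level=e.per_level,
            )
        entries[aid] = e
    return RCFTable(marker=marker_series.analyte, method=method, entries=entries)
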