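"""External-standard and single-marker (QAMS) quantification of samples.

Two routes from a sample's peak areas to per-analyte content (% w/w):

* **ESM** (external standard method): each analyte is read off its own
  calibration curve — the reference route, needing a physical standard for
  every analyte.
* **QAMS**: every area is read off the single marker's curve to give an
  apparent concentration, then divided by the analyte's relative correction
  factor: C_k = C_k_detected / RCF_k. One physical standard quantifies the
  whole panel.

The signed relative error RE% = (QAMS - ESM) / ESM * 100 per analyte and
sample is the criterion that ranks the six RCF conventions: the one whose
RE distribution sits closest to zero wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calibration import (
    CalibrationCurve,
    CalibrationSeries,
    fit_loglog_calibration,
    predict_concentration,
)
from .exceptions import (
    DomainError,
    InsufficientDataError,
    PairingError,
    PanelLookupError,
)
from .rcf import RCF_METHODS, RCFTable, build_rcf_table

__all__ = [
    "SampleMeasurement",
    "ContentResult",
    "QAMSQuantifier",
    "esm_quantify",
    "qams_quantify",
    "content_percent",
    "relative_error",
    "quantify_batch",
    "rank_rcf_methods",
    "ratio_to_raw",
]


@dataclass(frozen=True)
class SampleMeasurement:
    """One extracted sample: peak areas plus the weighing/dilution metadata
    needed to turn solution concentrations into content of the dry material."""

    sample_id: str
    group: str  # e.g. Raw, St, S, L
    mass_g: float
    volume_ml: float
    dilution: float
    areas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.mass_g <= 0 or self.volume_ml <= 0:
            raise DomainError(
                f"{self.sample_id}: mass and volume must be > 0"
            )
        if self.dilution < 1:
            raise DomainError(f"{self.sample_id}: dilution must be >= 1")


@dataclass(frozen=True)
class ContentResult:
    """Per-sample per-analyte contents under both routes, with relative error."""

    sample_id: str
    analyte_id: str
    conc_esm: float
    conc_qams: float
    content_esm_pct: float
    content_qams_pct: float
    re_pct: float


def esm_quantify(
    sample: SampleMeasurement, curves: Mapping[str, CalibrationCurve]
) -> dict[str, float]:
    """Each analyte's solution concentration off its own calibration curve."""
    out = {}
    for aid, area in sample.areas.items():
        if aid not in curves:
            raise PanelLookupError(f"no calibration curve for analyte {aid!r}")
        out[aid] = predict_concentration(curves[aid], area)
    return out


def qams_quantify(
    sample: SampleMeasurement,
    marker_curve: CalibrationCurve,
    rcf_table: RCFTable,
) -> dict[str, float]:
    """Every analyte off the *marker's* curve, corrected by its RCF.

    The apparent concentration C_detected is divided by the analyte's RCF,
    inverting the defining ratio RCF = C_detected / C. The same inversion is
    applied whichever method produced the table, so all six conventions run
    through an identical content pipeline (method F, RCF = 1, then means
    "quantify everything as if it were the marker").
    """
    out = {}
    for aid, area in sample.areas.items():
        rcf = rcf_table[aid].value
        if rcf <= 0:
            raise DomainError(f"RCF for {aid!r} must be > 0, got {rcf}")
        c_det = predict_concentration(marker_curve, area)
        out[aid] = c_det / rcf
    return out


def content_percent(conc: float, sample: SampleMeasurement) -> float:
    """Content (% w/w) of the weighed material from a solution concentration.

    content = conc[µg/mL] * volume[mL] * dilution / (mass[g] * 1e6 µg/g) * 100
    """
    if conc < 0:
        raise DomainError(f"concentration must be >= 0, got {conc}")
    return conc * sample.volume_ml * sample.dilution / (sample.mass_g * 1e6) * 100.0


def relative_error(qams: float, esm: float) -> float:
    """Signed relative error RE% = (qams - esm) / esm * 100."""
    if esm <= 0:
        raise DomainError(f"ESM content must be > 0, got {esm}")
    return (qams - esm) / esm * 100.0


class QAMSQuantifier(BaseEstimator):
    """Single-marker quantifier fitted on a calibration panel.

    Fitting fits every analyte's log-log curve and the marker RCF table for
    the chosen method; prediction turns sample measurements into an ESM/QAMS
    content table with per-row relative errors.

    Parameters
    ----------
    marker : str, default="GF3"
        Analyte id of the single marker.
    method : {"A", ..., "F"}, default="A"
        RCF convention used for the QAMS route.
    rounding : int or None, default=None
        Decimal places for *reported* RCFs; computation keeps full precision.

    Attributes
    ----------
    curves_ : dict of analyte id -> CalibrationCurve
    marker_curve_ : CalibrationCurve
    rcf_table_ : RCFTable
    analyte_ids_ : list of str
    """

    def __init__(self, marker: str = "GF3", method: str = "A",
                 rounding: int | None = None):
        self.marker = marker
        self.method = method
        self.rounding = rounding

    def fit(self, panel: Mapping[str, CalibrationSeries], y=None):
        if self.method not in RCF_METHODS:
            raise PanelLookupError(f"unknown RCF method {self.method!r}")
        if self.marker not in panel:
            raise PanelLookupError(f"marker {self.marker!r} not in panel")
        self.curves_ = {aid: fit_loglog_calibration(s) for aid, s in panel.items()}
        self.marker_curve_ = self.curves_[self.marker]
        self.rcf_table_ = build_rcf_table(
            panel, self.marker, self.method, rounding=self.rounding
        )
        self.analyte_ids_ = list(panel)
        return self

    def predict(self, samples: Iterable[SampleMeasurement]) -> pd.DataFrame:
        """Content table (one row per sample-analyte) for a sample batch."""
        if not hasattr(self, "curves_"):
            raise RuntimeError("QAMSQuantifier is not fitted yet; call fit first")
        rows = []
        for sample in samples:
            esm = esm_quantify(sample, self.curves_)
            qams = qams_quantify(sample, self.marker_curve_, self.rcf_table_)
            for aid in sample.areas:
                c_esm = content_percent(esm[aid], sample)
                c_qams = content_percent(qams[aid], sample)
                rows.append(
                    ContentResult(
                        sample_id=sample.sample_id,
                        analyte_id=aid,
                        conc_esm=esm[aid],
                        conc_qams=qams[aid],
                        content_esm_pct=c_esm,
                        content_qams_pct=c_qams,
                        re_pct=relative_error(c_qams, c_esm)
                        if c_esm > 0
                        else np.nan,
                    )
                )
        return pd.DataFrame([r.__dict__ for r in rows])


def quantify_batch(
    samples: Iterable[SampleMeasurement],
    panel: Mapping[str, CalibrationSeries],
    marker_id: str = "GF3",
    method: str = "A",
) -> pd.DataFrame:
    """One-shot wrapper: fit a :class:`QAMSQuantifier` and predict the batch."""
    return QAMSQuantifier(marker=marker_id, method=method).fit(panel).predict(samples)


def rank_rcf_methods(
    samples: Iterable[SampleMeasurement],
    panel: Mapping[str, CalibrationSeries],
    marker_id: str = "GF3",
) -> pd.DataFrame:
    """Run all six RCF conventions over a batch and rank them by accuracy.

    For each method the QAMS-vs-ESM relative error is pooled across analytes
    and samples; methods are ordered by mean \\|RE\\| ascending, so the first
    row is the selected (most accurate) method.

    Returns a DataFrame indexed 0..5 with columns ``method``, ``mean_abs_re``,
    ``median_abs_re``, ``max_abs_re``, ``n``; ``df.attrs["selected"]`` holds
    the winning method code.
    """
    samples = list(samples)
    if not samples:
        raise InsufficientDataError("empty sample batch")
    rows = []
    for method in RCF_METHODS:
        res = quantify_batch(samples, panel, marker_id, method)
        re = res["re_pct"].dropna().abs()
        if re.empty:
            raise InsufficientDataError(f"no finite RE values for method {method}")
        rows.append(
            {
                "method": method,
                "mean_abs_re": float(re.mean()),
                "median_abs_re": float(re.median()),
                "max_abs_re": float(re.max()),
                "n": int(re.size),
            }
        )
    out = (
        pd.DataFrame(rows)
        .sort_values("mean_abs_re", kind="stable")
        .reset_index(drop=True)
    )
    out.attrs["selected"] = out.loc[0, "method"]
    return out


def ratio_to_raw(
    results: pd.DataFrame,
    pairing: Mapping[str, str],
    content_col: str = "content_qams_pct",
) -> pd.DataFrame:
    """Per-analyte content ratio of each processed sample to its raw sample.

    ``pairing`` maps processed sample ids to raw sample ids; both must exist
    in ``results`` (a content table with ``sample_id``, ``analyte_id`` and
    ``content_col`` columns). A raw content of zero leaves that ratio NaN.
    """
    table = results.pivot_table(
        index="sample_id", columns="analyte_id", values=content_col
    )
    rows = []
    for proc, raw in pairing.items():
        if proc not in table.index:
            raise PairingError(f"processed sample {proc!r} not in results")
        if raw not in table.index:
            raise PairingError(f"raw sample {raw!r} not in results")
        num, den = table.loc[proc], table.loc[raw]
        ratio = num / den.where(den > 0)
        for aid, r in ratio.items():
            rows.append(
                {"sample_id": proc, "raw_id": raw, "analyte_id": aid,
                 "ratio": float(r) if pd.notna(r) else np.nan}
            )
    return pd.DataFrame(rows)
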