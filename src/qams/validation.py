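"""Method-validation statistics: RSD, spike recovery, replicate summaries,
and cross-instrument RCF system suitability.

Conventions follow routine pharmacopoeial practice: the relative standard
deviation uses the n-1 (sample) standard deviation, and recovery is the
spiked-sample mass balance (detected - origin) / spiked * 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, DomainError, InsufficientDataError
from .rcf import RCFTable

__all__ = [
    "RecoveryExperiment",
    "rsd",
    "recovery_rate",
    "summarize_validation",
    "system_suitability_rcf",
]

VALIDATION_METRICS = (
    "precision",
    "repeatability",
    "stability_sample",
    "stability_standard",
    "recovery",
)


@dataclass(frozen=True)
class RecoveryExperiment:
    """One spiked-recovery run: analyte already present (origin), analyte
    added (spike), and total found (detected), all in mg."""

    sample_mass_g: float
    origin_mg: float
    spike_mg: float
    detected_mg: float
    level_label: str = ""  # Low / Medium / High

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0 or self.origin_mg <= 0 or self.spike_mg <= 0:
            raise DomainError("mass, origin and spike must all be > 0")
        if self.detected_mg < 0:
            raise DomainError("detected amount must be >= 0")


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: sample SD (n-1) / mean * 100."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"RSD needs >= 2 values, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise DomainError("RSD undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


def recovery_rate(exp: RecoveryExperiment) -> float:
    """Spike recovery in percent: (detected - origin) / spiked * 100."""
    return (exp.detected_mg - exp.origin_mg) / exp.spike_mg * 100.0


def summarize_validation(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-(metric, analyte) replicate summaries.

    Parameters
    ----------
    runs : DataFrame with columns ``metric``, ``analyte_id``, ``replicate_id``,
        ``value``. Precision replicates are peak areas of repeated injections;
        stability replicates are areas over the storage time points;
        repeatability replicates are contents (%) across the three-mass
        design, pooled after content normalisation so differing weighed
        masses do not inflate the spread.

    Returns
    -------
    DataFrame with columns ``metric``, ``analyte_id``, ``n``, ``mean``,
    ``rsd_pct``, one row per group.
    """
    required = {"metric", "analyte_id", "replicate_id", "value"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    rows = []
    for (metric, aid), grp in runs.groupby(["metric", "analyte_id"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise InsufficientDataError(
                f"group ({metric}, {aid}) has {vals.size} replicate(s); need >= 2"
            )
        rows.append(
            {
                "metric": metric,
                "analyte_id": aid,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "rsd_pct": rsd(vals),
            }
        )
    return pd.DataFrame(rows)


def system_suitability_rcf(rcf_tables: Iterable[RCFTable]) -> pd.DataFrame:
    """Mean RCF and its RSD per analyte across instruments.

    All tables must share method and marker (same convention on every
    instrument); at least two instruments are required.
    """
    tables = list(rcf_tables)
    if len(tables) < 2:
        raise InsufficientDataError("system suitability needs >= 2 instruments")
    methods = {t.method for t in tables}
    markers = {t.marker.id for t in tables}
    if len(methods) > 1 or len(markers) > 1:
        raise ConsistencyError(
            f"tables disagree: methods {sorted(methods)}, markers {sorted(markers)}"
        )
    ids = list(tables[0].entries)
    if any(set(t.entries) != set(ids) for t in tables):
        raise ConsistencyError("tables cover different analyte panels")
    rows = []
    for aid in ids:
        vals = np.array([t[aid].value for t in tables], dtype=float)
        rows.append(
            {
                "analyte_id": aid,
                "mean_rcf": float(vals.mean()),
                "rsd_pct": rsd(vals) if vals.std(ddof=1) > 0 else 0.0,
                "n": len(tables),
            }
        )
    return pd.DataFrame(rows)
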