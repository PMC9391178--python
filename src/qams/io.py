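"""Delimited-table readers/writers, run configuration, and the pipeline driver.

All interchange is comma-separated UTF-8 text with a header row. Numeric
values are written with locale-independent decimal points; rounding (e.g.
2-dp RCFs) happens only at serialization — computation keeps full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import (
    Analyte,
    CalibrationCurve,
    CalibrationLevel,
    CalibrationSeries,
    estimate_lod_loq,
    fit_loglog_calibration,
)
from .exceptions import PanelLookupError, QAMSError, SchemaError
from .quantify import SampleMeasurement, quantify_batch, rank_rcf_methods
from .rcf import RCF_METHODS, RCFTable, build_rcf_table

__all__ = [
    "RunConfig",
    "read_config",
    "read_calibration_table",
    "write_calibration_table",
    "write_curve_table",
    "read_sample_table",
    "write_sample_table",
    "write_rcf_tables",
    "run_pipeline",
]

logger = logging.getLogger("qams")

CALIBRATION_COLUMNS = ("analyte_id", "level_index", "concentration_ug_per_ml", "area")
SAMPLE_COLUMNS = (
    "sample_id", "group", "mass_g", "volume_ml", "dilution", "analyte_id", "area"
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any() or df[col].isna().any():
        row = int((out.isna()).idxmax())
        raise SchemaError(f"{path}: non-numeric or empty value in column "
                          f"{col!r} at row {row}")
    return out


def read_calibration_table(path) -> dict[str, CalibrationSeries]:
    """Read per-analyte calibration series from a long-format CSV.

    Columns: ``analyte_id``, ``concentration_ug_per_ml``, ``area`` and
    optionally ``level_index`` (row order within each analyte is used when
    the column is absent).
    """
    df = pd.read_csv(path)
    _require_columns(
        df, ("analyte_id", "concentration_ug_per_ml", "area"), path
    )
    conc = _numeric(df, "concentration_ug_per_ml", path)
    area = _numeric(df, "area", path)
    for col, vals in (("concentration_ug_per_ml", conc), ("area", area)):
        if (vals <= 0).any():
            row = int((vals <= 0).idxmax())
            raise SchemaError(
                f"{path}: nonpositive value in column {col!r} at row {row}"
            )
    df = df.assign(concentration_ug_per_ml=conc, area=area)
    panel: dict[str, CalibrationSeries] = {}
    for aid, grp in df.groupby("analyte_id", sort=False):
        if "level_index" in grp.columns:
            idx = _numeric(grp, "level_index", path).astype(int).tolist()
        else:
            idx = list(range(1, len(grp) + 1))
        levels = tuple(
            CalibrationLevel(level_index=i, concentration=c, area=a)
            for i, c, a in zip(
                idx, grp["concentration_ug_per_ml"], grp["area"]
            )
        )
        try:
            panel[str(aid)] = CalibrationSeries(Analyte(str(aid)), levels)
        except (QAMSError, ValueError) as exc:
            raise SchemaError(f"{path}: invalid series for {aid!r}: {exc}") from exc
    return panel


def write_calibration_table(panel: Mapping[str, CalibrationSeries], path) -> None:
    rows = [
        {
            "analyte_id": aid,
            "level_index": lv.level_index,
            "concentration_ug_per_ml": lv.concentration,
            "area": lv.area,
        }
        for aid, series in panel.items()
        for lv in series.levels
    ]
    pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS)).to_csv(path, index=False)


def write_curve_table(
    curves: Mapping[str, CalibrationCurve],
    path,
    noise_sd: float | None = None,
) -> None:
    """Write fitted curves (and LOD/LOQ when a baseline noise SD is given)."""
    rows = []
    for aid, c in curves.items():
        row = {
            "analyte": aid,
            "slope": c.slope,
            "intercept": c.intercept,
            "r_squared": round(c.r_squared, 4) if c.r_squared is not None else "",
            "range_low": c.range_low,
            "range_high": c.range_high,
        }
        if noise_sd is not None:
            lim = estimate_lod_loq(c, noise_sd)
            row["lod"], row["loq"] = lim.lod, lim.loq
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_table(path) -> list[SampleMeasurement]:
    """Read sample measurements from a long-format CSV (one row per
    sample-analyte area, metadata repeated)."""
    df = pd.read_csv(path)
    _require_columns(df, SAMPLE_COLUMNS, path)
    for col in ("mass_g", "volume_ml", "dilution", "area"):
        df[col] = _numeric(df, col, path)
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        meta = grp.iloc[0]
        if grp[["group", "mass_g", "volume_ml", "dilution"]].nunique().max() > 1:
            raise SchemaError(f"{path}: inconsistent metadata for sample {sid!r}")
        samples.append(
            SampleMeasurement(
                sample_id=str(sid),
                group=str(meta["group"]),
                mass_g=float(meta["mass_g"]),
                volume_ml=float(meta["volume_ml"]),
                dilution=float(meta["dilution"]),
                areas=dict(zip(grp["analyte_id"].astype(str), grp["area"])),
            )
        )
    return samples


def write_sample_table(samples: Iterable[SampleMeasurement], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "mass_g": s.mass_g,
            "volume_ml": s.volume_ml,
            "dilution": s.dilution,
            "analyte_id": aid,
            "area": area,
        }
        for s in samples
        for aid, area in s.areas.items()
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(path, index=False)


def write_rcf_tables(
    tables: Iterable[RCFTable], wide_path, levels_path=None, rounding: int | None = 2
) -> None:
    """Write RCF tables wide (rows = methods, columns = analytes) and, when
    ``levels_path`` is given, a long per-level audit file."""
    tables = list(tables)
    wide = pd.DataFrame(
        [
            {"method": t.method, **t.values(rounding=rounding)}
            for t in tables
        ]
    )
    wide.to_csv(wide_path, index=False)
    if levels_path is not None:
        pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
            levels_path, index=False
        )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (calibrate -> RCF -> quantify -> rank)."""

    calibration_path: str
    sample_path: str
    out_dir: str
    marker_id: str = "GF3"
    rcf_method: str = "A"
    rounding: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rcf_method not in RCF_METHODS:
            raise PanelLookupError(f"unknown RCF method {self.rcf_method!r}")


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a :class:`RunConfig`."""
    values: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: line {i + 1} is not 'key = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    kwargs: dict = {}
    for key in ("calibration_path", "sample_path", "out_dir", "marker_id",
                "rcf_method", "log_level"):
        if key in values:
            kwargs[key] = values[key]
    for key in ("rounding", "seed"):
        if key in values:
            kwargs[key] = int(values[key])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Calibrate, build all six RCF tables, quantify, and rank the methods.

    Writes ``curves.csv``, ``rcf_table.csv``, ``rcf_levels.csv``,
    ``content.csv`` and ``re_summary.csv`` under ``config.out_dir`` and
    returns their paths. Fails before any computation if the marker is
    missing from the calibration panel.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = read_calibration_table(config.calibration_path)
    if config.marker_id not in panel:
        raise PanelLookupError(
            f"marker {config.marker_id!r} not in calibration panel "
            f"{sorted(panel)}"
        )
    samples = read_sample_table(config.sample_path)
    logger.info("calibration: %d analytes; samples: %d", len(panel), len(samples))

    curves = {aid: fit_loglog_calibration(s) for aid, s in panel.items()}
    paths = {"curves": out / "curves.csv"}
    write_curve_table(curves, paths["curves"])

    tables = [
        build_rcf_table(panel, config.marker_id, m) for m in RCF_METHODS
    ]
    paths["rcf_table"] = out / "rcf_table.csv"
    paths["rcf_levels"] = out / "rcf_levels.csv"
    write_rcf_tables(
        tables, paths["rcf_table"], paths["rcf_levels"], rounding=config.rounding
    )
    logger.info("RCF tables built for methods %s", ",".join(RCF_METHODS))

    content = quantify_batch(samples, panel, config.marker_id, config.rcf_method)
    paths["content"] = out / "content.csv"
    content.to_csv(paths["content"], index=False)

    summary = rank_rcf_methods(samples, panel, config.marker_id)
    paths["re_summary"] = out / "re_summary.csv"
    summary.assign(selected=summary["method"] == summary.attrs["selected"]).to_csv(
        paths["re_summary"], index=False
    )
    logger.info(
        "content rows: %d; selected RCF method: %s",
        len(content),
        summary.attrs["selected"],
    )
    return paths
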