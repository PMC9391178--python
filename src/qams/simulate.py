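"""Synthetic ELSD detector responses with known ground truth.

Everything downstream (calibration, RCFs, QAMS-vs-ESM ranking, validation)
is testable without an instrument because this module generates peak areas
from an explicit power-law detector model,

    area = 10**(F * lg C + b) * exp(eps_mult) + eps_add,

with multiplicative lognormal noise (ELSD noise scales with signal;
``eps_mult ~ Normal(0, ln(1 + noise_cv))``) and an optional additive
baseline term feeding LOD/LOQ work. With both noise terms zero the forward
model is deterministic, so round-trips through the fitting code are exact.

The batch generator emulates a medicinal-herb processing study: a few raw
lots, each processed several ways in replicate, with per-group content
multipliers (e.g. long-chain fructans degraded and short ones enriched by
steaming) and lognormal lot-to-lot jitter. It returns both the observable
samples and the hidden truth table so recovery of the configured effects can
be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import Analyte, CalibrationLevel, CalibrationSeries
from .exceptions import DesignError, DomainError, PanelLookupError
from .quantify import SampleMeasurement

__all__ = [
    "DetectorModel",
    "BatchDesign",
    "simulate_area",
    "make_calibration_series",
    "make_sample_batch",
    "dilute",
    "default_panel",
    "default_top_concentrations",
    "DEFAULT_DILUTION_FACTORS",
]

#: Co-dilution factors of the mixed standard stock (1x is the stock itself).
DEFAULT_DILUTION_FACTORS = (1.0, 1.5, 2.2, 4.0, 10.0)


@dataclass(frozen=True)
class DetectorModel:
    """Ground-truth power-law response of one analyte on one detector."""

    analyte_id: str
    true_slope: float  # F, typically 1.8-1.95 for oligosaccharides on ELSD
    true_intercept: float  # b, typically -1.9 .. -1.55
    noise_cv: float = 0.0  # relative SD of multiplicative area noise
    baseline_noise_sd: float = 0.0  # additive area noise SD

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValueError("true_slope must be > 0")
        if self.noise_cv < 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class BatchDesign:
    """Design of a raw + processed sample batch.

    ``groups`` maps each processed-group code to its replicate count per raw
    lot; raw lots themselves appear once each. ``group_multipliers`` scales
    each analyte's raw content per group (missing entries default to 1).
    """

    n_raw: int = 3
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"St": 3, "L": 3, "S": 3}
    )
    base_content_pct: Mapping[str, float] = field(default_factory=dict)
    group_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    mass_g: float = 0.25
    volume_ml: float = 25.0
    dilution: float = 1.0
    batch_jitter_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raw < 1 or any(n < 1 for n in self.groups.values()):
            raise DesignError("replicate counts must be >= 1")
        if any(v <= 0 for v in self.base_content_pct.values()):
            raise DesignError("base contents must be > 0")
        for g, mult in self.group_multipliers.items():
            if any(m <= 0 for m in mult.values()):
                raise DesignError(f"group {g}: multipliers must be > 0")


def simulate_area(
    model: DetectorModel, concentration: float, rng: np.random.Generator | None = None
) -> float:
    """Draw one peak area from the detector model at a concentration."""
    if concentration <= 0:
        raise DomainError(f"concentration must be > 0, got {concentration}")
    area = 10.0 ** (
        model.true_slope * np.log10(concentration) + model.true_intercept
    )
    if model.noise_cv > 0 or model.baseline_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when the model is noisy")
        if model.noise_cv > 0:
            area *= np.exp(rng.normal(0.0, np.log1p(model.noise_cv)))
        if model.baseline_noise_sd > 0:
            area += rng.normal(0.0, model.baseline_noise_sd)
    return float(area)


def make_calibration_series(
    model: DetectorModel,
    top_concentration: float | None = None,
    dilution_factors: Sequence[float] = DEFAULT_DILUTION_FACTORS,
    concentrations: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    analyte: Analyte | None = None,
) -> CalibrationSeries:
    """Simulate a dilution series and its areas for one analyte.

    Either give ``top_concentration`` (levels at top/f for each dilution
    factor, the co-diluted mixed-standard design) or an explicit
    ``concentrations`` list (separately prepared standards). Level index 1 is
    the most dilute level.
    """
    if concentrations is None:
        if top_concentration is None:
            raise DesignError("give top_concentration or concentrations")
        if top_concentration <= 0:
            raise DomainError("top_concentration must be > 0")
        factors = [float(f) for f in dilution_factors]
        if any(f < 1 for f in factors):
            raise DesignError("dilution factors must be >= 1")
        if len(set(factors)) != len(factors):
            raise DesignError(f"duplicate dilution factors: {factors}")
        concs = sorted(top_concentration / f for f in factors)
    else:
        concs = sorted(float(c) for c in concentrations)
    levels = tuple(
        CalibrationLevel(
            level_index=i + 1,
            concentration=c,
            area=simulate_area(model, c, rng),
        )
        for i, c in enumerate(concs)
    )
    return CalibrationSeries(
        analyte=analyte or Analyte(model.analyte_id), levels=levels
    )


def make_sample_batch(
    design: BatchDesign, models: Mapping[str, DetectorModel]
) -> tuple[list[SampleMeasurement], "pd.DataFrame"]:
    """Generate a raw + processed sample batch and its hidden truth table.

    Returns ``(samples, truth)`` where ``truth`` has one row per
    sample-analyte with the true content (%), true solution concentration
    (µg/mL), group and raw-lot pairing — the oracle for parameter-recovery
    tests.
    """
    import pandas as pd

    for aid in design.base_content_pct:
        if aid not in models:
            raise PanelLookupError(f"no detector model for analyte {aid!r}")
    rng = np.random.default_rng(design.seed)
    sigma = np.log1p(design.batch_jitter_cv)
    analytes = list(design.base_content_pct)

    samples: list[SampleMeasurement] = []
    truth_rows = []

    def emit(sample_id: str, group: str, contents: dict[str, float], raw_id: str):
        areas = {}
        for aid, content in contents.items():
            conc = (
                content / 100.0 * design.mass_g * 1e6
                / (design.volume_ml * design.dilution)
            )
            areas[aid] = simulate_area(models[aid], conc, rng)
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "raw_id": raw_id,
                    "analyte_id": aid,
                    "true_content_pct": content,
                    "true_conc_ug_per_ml": conc,
                }
            )
        samples.append(
            SampleMeasurement(
                sample_id=sample_id,
                group=group,
                mass_g=design.mass_g,
                volume_ml=design.volume_ml,
                dilution=design.dilution,
                areas=areas,
            )
        )

    for i in range(1, design.n_raw + 1):
        raw_id = f"Raw_{i:02d}"
        jitter = (
            np.exp(rng.normal(0.0, sigma, size=len(analytes)))
            if design.batch_jitter_cv > 0
            else np.ones(len(analytes))
        )
        raw_contents = {
            aid: design.base_content_pct[aid] * jitter[j]
            for j, aid in enumerate(analytes)
        }
        emit(raw_id, "Raw", raw_contents, raw_id)
        for group, n_rep in design.groups.items():
            mult = design.group_multipliers.get(group, {})
            proc_contents = {
                aid: raw_contents[aid] * mult.get(aid, 1.0) for aid in analytes
            }
            for r in range(1, n_rep + 1):
                emit(f"{group}_{i:02d}-{r}", group, proc_contents, raw_id)

    return samples, pd.DataFrame(truth_rows)


def dilute(concentration: float, aliquot_ml: float, final_ml: float) -> float:
    """Concentration after drawing ``aliquot_ml`` into ``final_ml`` total volume.

    >>> dilute(1043.46, 3.5, 5.0)
    730.422
    """
    if concentration <= 0 or aliquot_ml <= 0 or final_ml <= 0:
        raise DomainError("concentration and volumes must be > 0")
    if aliquot_ml > final_ml:
        raise DesignError("aliquot cannot exceed final volume")
    return concentration * aliquot_ml / final_ml


# Published-scale reference panel: slopes/intercepts typical of the eight
# Morinda officinalis fructooligosaccharides (GF1 sucrose .. GF8) on a
# HILIC-HPLC-ELSD system, with each standard's stock concentration.
_REFERENCE_PARAMS = {
    "GF1": (1.88, -1.70, 934.128),
    "GF2": (1.94, -1.90, 730.422),
    "GF3": (1.82, -1.67, 1180.400),
    "GF4": (1.80, -1.56, 950.400),
    "GF5": (1.81, -1.66, 1130.920),
    "GF6": (1.81, -1.76, 1212.154),
    "GF7": (1.83, -1.77, 1162.394),
    "GF8": (1.86, -1.91, 1035.752),
}


def default_panel(
    noise_cv: float = 0.0, baseline_noise_sd: float = 0.0
) -> dict[str, DetectorModel]:
    """Detector models for the eight-fructan reference panel (marker GF3)."""
    return {
        aid: DetectorModel(aid, F, b, noise_cv, baseline_noise_sd)
        for aid, (F, b, _top) in _REFERENCE_PARAMS.items()
    }


def default_top_concentrations() -> dict[str, float]:
    """Stock (1x) concentration in µg/mL per analyte of the reference panel."""
    return {aid: top for aid, (_F, _b, top) in _REFERENCE_PARAMS.items()}
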