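"""Ligand-efficiency metrics and their threshold classification.

Six size/lipophilicity-normalised potency metrics derived from a docking
binding energy BE (kcal/mol, negative = favourable), a heavy-atom count HA
and an octanol/water logP:

    Ki       = exp(BE / RT)                      (molar)
    LE       = -BE / HA                          (kcal/mol per heavy atom)
    LLE      = -log10(Ki) - logP
    LE_Scale = 0.873 * exp(-0.026 * HA) - 0.064  (empirical maximal-LE curve)
    FQ       = LE / LE_Scale                     (fit quality)
    LELP     = logP / LE                         ("lipophilic price" of LE)

The conventional hit thresholds are LE >= 0.3 kcal/mol/HA, LLE >= 3,
FQ >= 0.8 and LELP within [-10, +10]; comparisons are inclusive.  All
internal arithmetic is full precision; rounding is for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError

__all__ = [
    "ThermoConfig",
    "EfficiencyInputs",
    "MetricThresholds",
    "EfficiencyReport",
    "inhibition_constant",
    "ligand_efficiency",
    "le_scale",
    "lipophilic_efficiency",
    "fit_quality",
    "lelp",
    "evaluate_metrics",
    "evaluate_table",
]

#: kcal/(mol K); CODATA molar gas constant in thermochemical calories.
GAS_CONSTANT_KCAL = 1.98720425e-3
#: K; standard ambient temperature.  The temperature behind a published Ki
#: column is often unstated, so Ki-based comparisons should allow a few
#: percent of slack.
STANDARD_TEMPERATURE = 298.15


@dataclass(frozen=True)
class ThermoConfig:
    gas_constant: float = GAS_CONSTANT_KCAL  # kcal/(mol K)
    temperature: float = STANDARD_TEMPERATURE  # K

    def __post_init__(self):
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise ContractError("temperature and gas constant must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class EfficiencyInputs:
    binding_energy: float  # kcal/mol
    heavy_atoms: int
    logp: float
    ki_override: float | None = None  # molar

    def __post_init__(self):
        if self.heavy_atoms < 1:
            raise ContractError("heavy_atoms must be >= 1")
        if self.ki_override is not None and self.ki_override <= 0:
            raise ContractError("ki_override must be positive")


@dataclass(frozen=True)
class MetricThresholds:
    le_min: float = 0.3  # kcal/mol per heavy atom
    lle_min: float = 3.0
    fq_min: float = 0.8
    lelp_range: tuple[float, float] = (-10.0, 10.0)
    ki_max: float | None = None  # molar, optional extra gate

    def __post_init__(self):
        lo, hi = self.lelp_range
        if lo > hi:
            raise ContractError("lelp_range must be ordered")
        if min(self.le_min, self.lle_min, self.fq_min) <= 0:
            raise ContractError("le_min, lle_min, fq_min must be positive")


@dataclass
class EfficiencyReport:
    ki: float  # molar
    le: float
    lle: float
    le_scale: float
    fq: float
    lelp: float
    flags: dict[str, bool] = field(default_factory=dict)
    ki_provenance: str = "computed"  # "computed" | "override"

    @property
    def ki_uM(self) -> float:
        return self.ki * 1e6

    @property
    def passes(self) -> bool:
        return all(self.flags.values())

    def failed_metrics(self) -> list[str]:
        return [k for k, ok in self.flags.items() if not ok]


def inhibition_constant(binding_energy: float, thermo: ThermoConfig = ThermoConfig()) -> float:
    """Ki = exp(BE / RT), in molar; monotonically increasing in BE."""
    if not math.isfinite(binding_energy):
        raise ContractError("binding energy must be finite")
    return math.exp(binding_energy / thermo.rt)


def ligand_efficiency(binding_energy: float, heavy_atoms: int) -> float:
    """LE = -BE / HA, kcal/mol per heavy atom."""
    if heavy_atoms < 1:
        raise ContractError("heavy_atoms must be >= 1")
    return -binding_energy / heavy_atoms


def le_scale(heavy_atoms: int) -> float:
    """Empirical maximal-LE scaling curve; strictly decreasing in HA."""
    if heavy_atoms < 1:
        raise ContractError("heavy_atoms must be >= 1")
    return _le_scale_form(heavy_atoms)


def _le_scale_form(ha: float) -> float:
    return 0.873 * math.exp(-0.026 * ha) - 0.064


def lipophilic_efficiency(ki: float, logp: float) -> float:
    """LLE = -log10(Ki) - logP, with Ki in molar."""
    if ki <= 0:
        raise ContractError("Ki must be positive")
    return -math.log10(ki) - logp


def fit_quality(le: float, le_scale_value: float) -> float:
    """FQ = LE / LE_Scale."""
    if le_scale_value == 0:
        raise ContractError("LE_Scale must be nonzero")
    return le / le_scale_value


def lelp(logp: float, le: float) -> float:
    """LELP = logP / LE."""
    if le == 0:
        raise ContractError("LE must be nonzero")
    return logp / le


def evaluate_metrics(
    inputs: EfficiencyInputs,
    thermo: ThermoConfig = ThermoConfig(),
    thresholds: MetricThresholds = MetricThresholds(),
) -> EfficiencyReport:
    """Compute all six metrics and classify against the thresholds.

    Ki comes from ``inputs.ki_override`` when present (e.g. a published Ki
    column), otherwise from the thermodynamic relation; the provenance is
    recorded on the report.  Pass/fail comparisons are inclusive.
    """
    if inputs.ki_override is not None:
        ki = inputs.ki_override
        provenance = "override"
    else:
        ki = inhibition_constant(inputs.binding_energy, thermo)
        provenance = "computed"
    le = ligand_efficiency(inputs.binding_energy, inputs.heavy_atoms)
    scale = le_scale(inputs.heavy_atoms)
    report = EfficiencyReport(
        ki=ki,
        le=le,
        lle=lipophilic_efficiency(ki, inputs.logp),
        le_scale=scale,
        fq=fit_quality(le, scale),
        lelp=lelp(inputs.logp, le),
        ki_provenance=provenance,
    )
    lo, hi = thresholds.lelp_range
    report.flags = {
        "LE": report.le >= thresholds.le_min,
        "LLE": report.lle >= thresholds.lle_min,
        "FQ": report.fq >= thresholds.fq_min,
        "LELP": lo <= report.lelp <= hi,
    }
    if thresholds.ki_max is not None:
        report.flags["Ki"] = report.ki <= thresholds.ki_max
    return report


def evaluate_table(
    df: pd.DataFrame,
    thermo: ThermoConfig = ThermoConfig(),
    thresholds: MetricThresholds = MetricThresholds(),
) -> pd.DataFrame:
    """Vector convenience over :func:`evaluate_metrics`.

    ``df`` needs columns id, binding_energy, heavy_atoms, logp and may carry
    ki_uM (used as override).  Returns one report row per input row.
    """
    out = []
    for _, row in df.iterrows():
        ki_override = None
        if "ki_uM" in df.columns and pd.notna(row["ki_uM"]):
            ki_override = float(row["ki_uM"]) * 1e-6
        rep = evaluate_metrics(
            EfficiencyInputs(
                binding_energy=float(row["binding_energy"]),
                heavy_atoms=int(row["heavy_atoms"]),
                logp=float(row["logp"]),
                ki_override=ki_override,
            ),
            thermo,
            thresholds,
        )
        out.append(
            {
                "id": row["id"],
                "ki_uM": rep.ki_uM,
                "le": rep.le,
                "lle": rep.lle,
                "le_scale": rep.le_scale,
                "fq": rep.fq,
                "lelp": rep.lelp,
                "passes": rep.passes,
                "failed": ";".join(rep.failed_metrics()),
                "ki_provenance": rep.ki_provenance,
            }
        )
    return pd.DataFrame(out)
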