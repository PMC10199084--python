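"""Drug-likeness rule engines and permissible-range screening.

Two named oral-drug-likeness rules plus a data-driven range screen over
arbitrary ADMET profile fields:

* Lipinski rule: MW <= 500 Da, logP <= 5, H-bond acceptors <= 10, H-bond
  donors <= 5; a compound is Accepted with fewer than two violations.
* Pfizer (3/75) rule: the combination logP > 3 AND TPSA < 75 A^2 marks an
  elevated toxicity-risk region; compounds inside it are Rejected, all
  others Accepted.  Both inequalities are strict.

Permissible ranges are declared as small spec strings ("> -5.15",
"<= 0.90", "100 ~ 600", "-5 to 5", or three-band scales like
"0-0.3 excellent; 0.3-0.7 medium; 0.7-1.0 poor") so the screen stays
data-driven; the shipped :data:`TABLE3_RANGES` covers the standard
absorption/distribution/metabolism/excretion/toxicology panel.  For banded
fields the outcome carries the band label and only the first band counts as
Accepted.  Closed bounds are inclusive (a value exactly on "<= 0.90"
passes).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError, ContractError

__all__ = [
    "PhyschemProfile",
    "RuleStatus",
    "RuleOutcome",
    "RangeSpec",
    "parse_range",
    "lipinski_rule",
    "pfizer_rule",
    "range_screen",
    "TABLE3_RANGES",
    "profile_from_smiles",
]


class RuleStatus(str, enum.Enum):
    ACCEPTED = "Accepted"
    REJECTED = "Rejected"


@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical/ADMET descriptors for one compound.

    Core fields are those every named rule consumes; everything else
    (permeabilities, clearance, toxicity scores, ...) rides in
    ``extra_fields`` and is screened against declared ranges only.
    """

    mw: float | None = None  # Da
    heavy_atoms: int | None = None
    n_hba: int | None = None
    n_hbd: int | None = None
    tpsa: float | None = None  # A^2
    logp: float | None = None
    extra_fields: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mw is not None and self.mw <= 0:
            raise ContractError("mw must be positive")
        if self.tpsa is not None and self.tpsa < 0:
            raise ContractError("tpsa must be non-negative")
        for name in ("heavy_atoms", "n_hba", "n_hbd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ContractError(f"{name} must be non-negative")


@dataclass
class RuleOutcome:
    rule_id: str
    status: RuleStatus
    violations: list[tuple[str, float, str]] = field(default_factory=list)
    band: str | None = None

    @property
    def accepted(self) -> bool:
        return self.status is RuleStatus.ACCEPTED


def _require(profile: PhyschemProfile, *names: str) -> None:
    missing = [n for n in names if getattr(profile, n) is None]
    if missing:
        raise ContractError(f"profile missing required field(s): {missing}")


def lipinski_rule(profile: PhyschemProfile) -> RuleOutcome:
    """Rule-of-five screen; Accepted iff fewer than two bound violations."""
    _require(profile, "mw", "logp", "n_hba", "n_hbd")
    bounds = [
        ("mw", profile.mw, 500.0, "MW <= 500"),
        ("logp", profile.logp, 5.0, "logP <= 5"),
        ("n_hba", profile.n_hba, 10, "nHA <= 10"),
        ("n_hbd", profile.n_hbd, 5, "nHD <= 5"),
    ]
    violations = [(f, float(v), b) for f, v, lim, b in bounds if v > lim]
    status = RuleStatus.ACCEPTED if len(violations) < 2 else RuleStatus.REJECTED
    return RuleOutcome("Lipinski", status, violations)


def pfizer_rule(profile: PhyschemProfile) -> RuleOutcome:
    """3/75 toxicity-risk screen; Rejected iff logP > 3 and TPSA < 75."""
    _require(profile, "logp", "tpsa")
    in_risk_region = profile.logp > 3.0 and profile.tpsa < 75.0
    violations = (
        [("logp", profile.logp, "logP > 3"), ("tpsa", profile.tpsa, "TPSA < 75")]
        if in_risk_region
        else []
    )
    status = RuleStatus.REJECTED if in_risk_region else RuleStatus.ACCEPTED
    return RuleOutcome("Pfizer", status, violations)


# --- permissible-range grammar -------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?"


class RangeSpec:
    """A parsed permissible range; see :func:`parse_range`."""

    def __init__(self, kind: str, payload):
        self.kind = kind  # "bound" | "interval" | "bands"
        self.payload = payload

    def contains(self, value: float) -> bool:
        if self.kind == "bound":
            op, x = self.payload
            return {
                ">": value > x,
                ">=": value >= x,
                "<": value < x,
                "<=": value <= x,
            }[op]
        if self.kind == "interval":
            lo, hi = self.payload
            return lo <= value <= hi
        # bands: accepted iff in the first declared band
        return self.band(value) == self.payload[0][2]

    def band(self, value: float) -> str | None:
        if self.kind != "bands":
            return None
        for lo, hi, label in self.payload:
            if lo <= value <= hi:
                return label
        return None


def _norm(spec: str) -> str:
    s = spec.replace("−", "-").replace("–", "-").replace("—", "-")
    return s.replace("≤", "<=").replace("≥", ">=").strip()


def parse_range(spec: str) -> RangeSpec:
    """Parse a permissible-range spec string.

    Supported forms: one-sided bounds ("> -5.15", ">= 0.05", "<= 0.90",
    "< 38"), closed intervals ("100 ~ 600", "0-12", "-5 to 5", "0 to 1"),
    and semicolon/space separated three-band scales whose bands are closed
    intervals or one-sided bounds with trailing labels.
    """
    s = _norm(spec)
    m = re.fullmatch(rf"(<=|>=|<|>)\s*({_NUM})", s)
    if m:
        return RangeSpec("bound", (m.group(1), float(m.group(2))))
    m = re.fullmatch(rf"({_NUM})\s*(?:~|-|to)\s*({_NUM})", s) or re.fullmatch(
        rf"({_NUM})\s+to\s+({_NUM})", s
    )
    if m:
        lo, hi = sorted((float(m.group(1)), float(m.group(2))))
        return RangeSpec("interval", (lo, hi))
    bands = _parse_bands(s)
    if bands:
        return RangeSpec("bands", bands)
    raise ConfigurationError(f"unparseable range spec {spec!r}")


def _parse_bands(s: str):
    # e.g. "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor"
    #      "> 15 high clearance; 5-15 moderate clearance; < 5 low clearance"
    pattern = re.compile(
        rf"(?:({_NUM})\s*-\s*({_NUM})|(<=|>=|<|>)\s*({_NUM}))\s+([A-Za-z][A-Za-z ]*?)(?=(?:\s*;\s*|\s+)(?:{_NUM}\s*-|[<>])|$)"
    )
    bands = []
    big = 1e30
    for m in pattern.finditer(s):
        label = m.group(5).strip()
        if m.group(1) is not None:
            lo, hi = float(m.group(1)), float(m.group(2))
        else:
            op, x = m.group(3), float(m.group(4))
            lo, hi = (x, big) if op in (">", ">=") else (-big, x)
        bands.append((lo, hi, label))
    return bands if len(bands) >= 2 else None


#: Permissible ranges for the standard ADMET panel, keyed by profile field.
TABLE3_RANGES: dict[str, str] = {
    "mw": "100 ~ 600",
    "ha": "< 38",
    "n_hba": "0-12",
    "n_hbd": "0-7",
    "tpsa": "0-140",
    "logp": "0-3",
    "npscore": "-5 to 5",
    "caco2": "> -5.15",
    "pgp_inhibitor": "0-0.3",
    "hia": "0-0.3",
    "f30": "0-0.3",
    "ppb": "<= 0.90",
    "vd": "0.04-20",
    "bbb": "0 to 1",
    "fu": ">= 0.05",
    "cyp_inhibitor": "0-1",
    "cyp_substrate": "0-1",
    "cl": "> 15 high clearance; 5-15 moderate clearance; < 5 low clearance",
    "t_half": "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor",
    "herg": "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor",
    "h_ht": "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor",
    "ames": "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor",
    "skin_sens": "0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor",
}


def range_screen(
    profile: PhyschemProfile,
    ranges: Mapping[str, str | RangeSpec] | None = None,
) -> list[RuleOutcome]:
    """Screen every declared field of a profile against its range.

    Core fields are read from the profile attributes (mw, tpsa, ...);
    everything else from ``extra_fields``.  Fields without a declared range
    or without a value are skipped.
    """
    ranges = TABLE3_RANGES if ranges is None else ranges
    core = {
        "mw": profile.mw,
        "ha": profile.heavy_atoms,
        "n_hba": profile.n_hba,
        "n_hbd": profile.n_hbd,
        "tpsa": profile.tpsa,
        "logp": profile.logp,
    }
    outcomes = []
    for name, spec in ranges.items():
        value = core.get(name, profile.extra_fields.get(name))
        if value is None:
            continue
        rng = spec if isinstance(spec, RangeSpec) else parse_range(spec)
        ok = rng.contains(float(value))
        outcomes.append(
            RuleOutcome(
                rule_id=f"range:{name}",
                status=RuleStatus.ACCEPTED if ok else RuleStatus.REJECTED,
                violations=[] if ok else [(name, float(value), str(spec))],
                band=rng.band(float(value)),
            )
        )
    return outcomes


def profile_from_smiles(smiles: str) -> PhyschemProfile:
    """Derive the core descriptors from a SMILES via RDKit (optional extra).

    Predicted ADMET panel values are inputs, not derivable; this fills only
    MW, heavy atoms, H-bond acceptor/donor counts, TPSA and Crippen logP.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover
        raise ContractError("RDKit is required for profile_from_smiles") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ContractError(f"invalid SMILES {smiles!r}")
    return PhyschemProfile(
        mw=Descriptors.ExactMolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        n_hba=rdMolDescriptors.CalcNumHBA(mol),
        n_hbd=rdMolDescriptors.CalcNumHBD(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        logp=Crippen.MolLogP(mol),
    )


def profiles_from_table(df) -> dict[str, PhyschemProfile]:
    """Build profiles from a wide descriptor table indexed by label."""
    core_cols = {"mw", "ha", "n_hba", "n_hbd", "tpsa", "logp"}
    skip = {"label", "lipinski", "pfizer", "pubchem_id"}
    profiles: dict[str, PhyschemProfile] = {}
    for label, row in df.iterrows():
        extras = {
            c: float(row[c])
            for c in df.columns
            if c not in core_cols | skip and _is_number(row[c])
        }
        profiles[str(label)] = PhyschemProfile(
            mw=float(row["mw"]),
            heavy_atoms=int(row["ha"]),
            n_hba=int(row["n_hba"]),
            n_hbd=int(row["n_hbd"]),
            tpsa=float(row["tpsa"]),
            logp=float(row["logp"]),
            extra_fields=extras,
        )
    return profiles


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False
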