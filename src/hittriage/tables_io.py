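"""Tabular and structural I/O for the hit-triage pipeline.

All tables travel as comma-separated values with a mandatory header row and
"." decimals.  Numeric cells transcribed from typeset tables may carry the
Unicode minus sign (U+2212) and spaces between the sign and the digits; every
reader in this module normalises both to plain ASCII before parsing.

The main-text reference tables of the source screen (compound identities and
docking energies; physicochemical/ADMET profiles; ligand-efficiency metrics;
orbital and electrostatic-potential energies) ship with the package as
versioned CSV fixtures and are loaded through :func:`load_fixture`.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    AmbiguityError,
    ContractError,
    FixtureLookupError,
    FormatError,
    RowParseError,
    SchemaError,
)

__all__ = [
    "Role",
    "ScoreSource",
    "CompoundRecord",
    "ScoreEntry",
    "ScoreTable",
    "read_compound_table",
    "parse_docking_log",
    "load_fixture",
    "write_report_table",
    "normalize_numeric_text",
    "FIXTURE_NAMES",
]


class Role(str, enum.Enum):
    """Position of a compound within the screen."""

    ANALOG = "analog"
    PARENT = "parent"
    CONTROL = "control"


class ScoreSource(str, enum.Enum):
    VINA = "vina"
    AUTODOCK = "autodock"
    MMGBSA = "mmgbsa"
    OTHER = "other"


@dataclass(frozen=True)
class CompoundRecord:
    """One screened chemical entity.

    ``compound_id`` is the stable identifier used for joins (e.g. a PubChem
    CID such as "132210409"); ``label`` is the human-facing name ("A3",
    "AGP", "Rofecoxib").
    """

    compound_id: str
    label: str
    role: Role = Role.ANALOG
    smiles: str | None = None
    structure_ref: str | None = None

    def __post_init__(self):
        if not self.compound_id:
            raise ContractError("compound_id must be non-empty")


@dataclass(frozen=True)
class ScoreEntry:
    compound_id: str
    binding_energy: float  # kcal/mol, negative = favourable
    source: ScoreSource = ScoreSource.OTHER

    def __post_init__(self):
        if not math.isfinite(self.binding_energy):
            raise ContractError(
                f"binding energy for {self.compound_id!r} is not finite"
            )


@dataclass
class ScoreTable:
    """Per-compound docking/rescoring energies in kcal/mol."""

    entries: list[ScoreEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def energy_of(self, compound_id: str) -> float:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e.binding_energy
        raise KeyError(compound_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [e.compound_id for e in self.entries],
                "binding_energy": [e.binding_energy for e in self.entries],
                "source": [e.source.value for e in self.entries],
            }
        )


_MINUS_VARIANTS = re.compile("[−–—]")


def normalize_numeric_text(text: str) -> str:
    """Map typeset minus variants to '-' and drop sign-digit whitespace."""
    cleaned = _MINUS_VARIANTS.sub("-", text.strip())
    cleaned = re.sub(r"^-\s+", "-", cleaned)
    return cleaned


def _parse_float(cell, row_index: int, column: str) -> float:
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        return float(cell)
    try:
        return float(normalize_numeric_text(str(cell)))
    except (TypeError, ValueError):
        raise RowParseError(
            f"cannot parse {column!r} value {cell!r} as a number", row_index
        ) from None


DEFAULT_SCHEMA: Mapping[str, str] = {
    "compound_id": "pubchem_id",
    "label": "label",
    "role": "role",
    "binding_energy": "binding_energy_kcal_mol",
}


def read_compound_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    source: ScoreSource = ScoreSource.OTHER,
) -> tuple[list[CompoundRecord], ScoreTable]:
    """Read a compound table, returning identity records joined with scores.

    ``schema`` maps logical fields (compound_id, label, binding_energy and
    optionally role, smiles) to column names in the file header.  Row order
    is preserved; unknown extra columns are ignored here (they remain
    available through plain :func:`pandas.read_csv` passthrough).
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    # keep_default_na=False: "N/A" etc. must surface as row-level parse
    # errors, not silently become missing values
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, keep_default_na=False)
    for logical in ("compound_id", "label", "binding_energy"):
        col = schema.get(logical)
        if col is None or col not in df.columns:
            raise SchemaError(
                f"column for {logical!r} ({col!r}) missing from header "
                f"{list(df.columns)}"
            )
    records: list[CompoundRecord] = []
    entries: list[ScoreEntry] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        cid = str(row[schema["compound_id"]]).strip()
        if cid in seen:
            raise ContractError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        role = Role(str(row[schema["role"]]).strip()) if schema.get("role") in df.columns else Role.ANALOG
        smiles_col = schema.get("smiles")
        records.append(
            CompoundRecord(
                compound_id=cid,
                label=str(row[schema["label"]]).strip(),
                role=role,
                smiles=str(row[smiles_col]) if smiles_col in df.columns else None,
            )
        )
        be = _parse_float(row[schema["binding_energy"]], int(i), schema["binding_energy"])
        entries.append(ScoreEntry(cid, be, source))
    return records, ScoreTable(entries)


# --- docking log dialects -------------------------------------------------

_VINA_MODE_ROW = re.compile(
    r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+\d+(?:\.\d+)?\s+\d+(?:\.\d+)?\s*$"
)
_VINA_LIGAND = re.compile(r"^(?:Ligand|Receptor-ligand|##\s*Ligand):?\s*(\S+)", re.I)
_AD4_ENERGY = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*(-?\d+(?:\.\d+)?)\s*kcal/mol"
)
_AD4_LIGAND = re.compile(r"^\s*Ligand(?:\s+PDBQT)?\s*file:?\s*(\S+)", re.I | re.M)


def parse_docking_log(path: str | Path, dialect: str = "vina") -> ScoreTable:
    """Extract per-ligand best binding energies from a docking log.

    vina dialect: the mode-1 affinity of each result block (the score table
    printed under the ``mode | affinity`` header).  autodock4 dialect: the
    lowest estimated free energy of binding over all reported conformers,
    i.e. the top cluster after ranking.
    """
    text = Path(path).read_text()
    if dialect == "vina":
        blocks: list[tuple[str | None, float]] = []
        current_ligand: str | None = None
        lines = text.splitlines()
        i = 0
        while i < len(lines):
            m = _VINA_LIGAND.match(lines[i])
            if m:
                current_ligand = m.group(1)
            elif lines[i].lstrip().startswith("mode |"):
                # first numeric row after the separator is mode 1
                j = i + 1
                best = None
                while j < len(lines):
                    row = _VINA_MODE_ROW.match(lines[j])
                    if row:
                        affinity = float(row.group(2))
                        if best is None or affinity < best:
                            best = affinity
                        j += 1
                    elif "|" in lines[j] or set(lines[j].strip()) <= {"-", "+", " "} and lines[j].strip():
                        j += 1  # header continuation / separator rows
                    else:
                        break
                if best is None:
                    raise FormatError(f"no mode rows under result header in {path}")
                blocks.append((current_ligand, best))
                current_ligand = None
                i = j
                continue
            i += 1
        if not blocks:
            raise FormatError(f"no vina result block found in {path}")
        if len(blocks) > 1 and any(name is None for name, _ in blocks):
            raise AmbiguityError(
                f"{path}: multiple result blocks but not all carry ligand ids"
            )
        return ScoreTable(
            [
                ScoreEntry(name or "ligand", energy, ScoreSource.VINA)
                for name, energy in blocks
            ]
        )
    if dialect == "autodock4":
        energies = [float(v) for v in _AD4_ENERGY.findall(text)]
        if not energies:
            raise FormatError(f"no AutoDock4 binding-energy lines found in {path}")
        names = _AD4_LIGAND.findall(text)
        if len(set(names)) > 1:
            raise AmbiguityError(
                f"{path}: multiple ligand files in one log; split per ligand"
            )
        name = names[0] if names else "ligand"
        return ScoreTable([ScoreEntry(name, min(energies), ScoreSource.AUTODOCK)])
    raise ContractError(f"unknown docking-log dialect {dialect!r}")


# --- shipped fixtures -----------------------------------------------------

FIXTURE_NAMES = ("table1", "table3", "table4", "table5")


def _fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        )
    return Path(resources.files("hittriage.fixtures") / f"{name}.csv")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a shipped reference table, indexed by compound label.

    table1: compound identities, roles and docking binding energies
    (kcal/mol).  table3: physicochemical/ADMET profile fields.  table4:
    ligand-efficiency metrics (Ki in uM).  table5: HOMO/LUMO/HLG (eV) and
    electrostatic potential energies of compound, adduct, and the derived
    adduct binding energy (kcal/mol); the peptide row has no adduct columns.
    """
    df = pd.read_csv(
        _fixture_path(name), dtype=str, skipinitialspace=True, keep_default_na=False
    )
    for col in df.columns:
        if col in ("label", "role", "lipinski", "pfizer", "pubchem_id"):
            continue
        df[col] = [
            _parse_float(v, i, col) if v.strip() else float("nan")
            for i, v in enumerate(df[col])
        ]
    return df.set_index("label", drop=False)


def write_report_table(
    rows: Iterable, path: str | Path, columns: Sequence[str] | None = None
) -> Path:
    """Write homogeneous report rows (dicts or dataclass-likes) as CSV.

    Column order is the field order of the first row (or ``columns`` when
    given, which also enables a header-only file for an empty row list); a
    round-trip read returns equal values to the written precision.
    """
    materialised: list[dict] = []
    for r in rows:
        if isinstance(r, Mapping):
            materialised.append(dict(r))
        elif hasattr(r, "__dataclass_fields__"):
            materialised.append({k: getattr(r, k) for k in r.__dataclass_fields__})
        elif isinstance(r, pd.Series):
            materialised.append(r.to_dict())
        else:
            raise ContractError(f"unsupported row type {type(r).__name__}")
    path = Path(path)
    if not materialised:
        path.write_text(",".join(columns) + "\n" if columns else "")
        return path
    columns = list(columns) if columns is not None else list(materialised[0])
    for i, r in enumerate(materialised):
        if list(r) != columns:
            raise ContractError(
                f"heterogeneous rows: row {i} fields {list(r)} != {columns}"
            )
    pd.DataFrame(materialised, columns=columns).to_csv(path, index=False)
    return path


def records_from_fixture() -> tuple[list[CompoundRecord], ScoreTable]:
    """The shipped compound table as typed records + scores."""
    df = load_fixture("table1")
    records = [
        CompoundRecord(str(r.pubchem_id), str(r.label), Role(r.role))
        for r in df.itertuples()
    ]
    entries = [
        ScoreEntry(str(r.pubchem_id), float(r.binding_energy_kcal_mol), ScoreSource.AUTODOCK)
        for r in df.itertuples()
    ]
    return records, ScoreTable(entries)
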