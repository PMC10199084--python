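"""Derivations over ingested quantum-chemistry outputs.

Three small but load-bearing computations sit on top of externally computed
(DFT) energy tables:

* the frontier-orbital gap HLG = LUMO - HOMO (eV), a chemical-reactivity
  proxy (smaller gap, easier electron flow, higher reactivity);
* the adduct stabilization energy from electrostatic potential energies,
  delta = E(adduct) - [E(compound) + E(peptide)] (kcal/mol).  Published
  tables sometimes print the magnitude with a favourable (negative) sign
  even when the component energies make the literal difference positive, so
  both the literal ``delta`` and the sign-convention value -|delta| are
  exposed and magnitudes are used for comparisons;
* direction-aware stable rankings over (id, energy) lists with mean-rank
  ties.

No electronic-structure computation happens here; energies are data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError

__all__ = [
    "OrbitalEnergies",
    "AdductEnergetics",
    "EpeValue",
    "homo_lumo_gap",
    "adduct_stabilization",
    "rank_by_energy",
]


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO energies in eV.

    A HOMO above the LUMO is physically suspect but not rejected; callers
    can check :attr:`inverted`.
    """

    homo: float
    lumo: float

    def __post_init__(self):
        if not (math.isfinite(self.homo) and math.isfinite(self.lumo)):
            raise ContractError("orbital energies must be finite")

    @property
    def inverted(self) -> bool:
        return self.homo > self.lumo


@dataclass(frozen=True)
class AdductEnergetics:
    """Component/adduct energies (kcal/mol) and the stabilization term."""

    e_adduct: float
    e_compound: float
    e_peptide: float

    @property
    def delta(self) -> float:
        """Literal stabilization energy E(adduct) - [E(compound)+E(peptide)]."""
        return self.e_adduct - (self.e_compound + self.e_peptide)

    @property
    def paper_convention_value(self) -> float:
        """The stabilization magnitude signed favourable (always <= 0)."""
        return -abs(self.delta)

    @property
    def magnitude(self) -> float:
        return abs(self.delta)


@dataclass(frozen=True)
class EpeValue:
    """An electrostatic potential energy with its potential-sign class."""

    value: float  # kcal/mol

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ContractError("EPE must be finite")

    @property
    def sign_class(self) -> str:
        return "positive_potential" if self.value >= 0 else "negative_potential"


def homo_lumo_gap(orbitals: OrbitalEnergies) -> float:
    """HLG = LUMO - HOMO, in eV."""
    return orbitals.lumo - orbitals.homo


def adduct_stabilization(
    e_adduct: float, e_compound: float, e_peptide: float
) -> AdductEnergetics:
    """Stabilization energy of a peptide-ligand adduct from component EPEs."""
    for name, v in (
        ("e_adduct", e_adduct),
        ("e_compound", e_compound),
        ("e_peptide", e_peptide),
    ):
        if not math.isfinite(v):
            raise ContractError(f"{name} must be finite")
    return AdductEnergetics(e_adduct, e_compound, e_peptide)


def rank_by_energy(
    values: list[tuple[str, float]], direction: str = "ascending"
) -> list[tuple[str, float, float]]:
    """Stable, tie-aware ranking of (id, energy) pairs.

    ``ascending`` ranks the most negative energy first (rank 1), the usual
    convention for favourable binding; ``descending`` the reverse.  Tied
    values share the mean of the ranks they span.  Returns (id, value,
    rank) sorted by rank then input order.
    """
    if direction not in ("ascending", "descending"):
        raise ContractError(f"unknown direction {direction!r}")
    ids = [i for i, _ in values]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ContractError(f"duplicate ids in ranking input: {dupes}")
    arr = np.asarray([v for _, v in values], dtype=float)
    ranks = rankdata(arr if direction == "ascending" else -arr, method="average")
    order = sorted(range(len(ids)), key=lambda k: (ranks[k], k))
    return [(ids[k], float(arr[k]), float(ranks[k])) for k in order]
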