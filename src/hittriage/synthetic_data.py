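"""Seeded synthetic inputs with the statistical structure the funnel assumes.

Every generator is a pure function of its spec (root seed included); the
root seed is split into independent stage streams with
:class:`numpy.random.SeedSequence`, so identical specs give bitwise
identical outputs and different stages never share draws.

What is emulated — and what is not.  The library generator mimics the
statistics of a docking screen (Gaussian binding energies, uniform heavy
atom counts, Gaussian logP, a controllable fraction of rule-failing
descriptor pairs and an optionally planted dominant hit); the trajectory
generator produces a reference geometry plus optional rigid-body motion
and isotropic Gaussian jitter.  No real chemistry (valence,
synthesizability) or force-field dynamics is imitated: passing tests on
these inputs validate the pipeline's arithmetic and bookkeeping, not any
claim about real screening data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .druglikeness import PhyschemProfile
from .errors import ContractError
from .ligand_efficiency import EfficiencyInputs
from .md_summaries import StructureFrame, Trajectory
from .tables_io import CompoundRecord, Role, ScoreEntry, ScoreTable, ScoreSource

__all__ = [
    "LibrarySpec",
    "TrajectorySpec",
    "SyntheticLibrary",
    "generate_library",
    "generate_trajectory",
    "generate_adduct_energies",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Study conditions for a synthetic screening library.

    Defaults emulate a 237-compound docking screen whose energies scatter
    as Normal(-7, 1) kcal/mol, with drug-sized molecules (15-35 heavy
    atoms) and a tenth of the library placed in the high-logP/low-TPSA
    toxicity-risk region.
    """

    n_compounds: int = 237
    be_mean: float = -7.0  # kcal/mol
    be_sd: float = 1.0
    ha_range: tuple[int, int] = (15, 35)
    logp_mean: float = 2.5
    logp_sd: float = 0.8
    fraction_rule_failures: float = 0.1
    planted_hit: tuple[str, float] | None = None  # (id, be_margin kcal/mol)
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ContractError("n_compounds must be >= 1")
        if self.be_sd < 0 or self.logp_sd < 0:
            raise ContractError("standard deviations must be >= 0")
        lo, hi = self.ha_range
        if not (1 <= lo <= hi <= 200):
            raise ContractError("ha_range must lie within [1, 200]")
        if not (0 <= self.fraction_rule_failures <= 1):
            raise ContractError("fraction_rule_failures must be in [0, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    """Study conditions for a synthetic trajectory.

    ``fluctuation_sd`` is the per-coordinate Gaussian jitter in nm;
    ``rigid_motion`` optionally superimposes a rotation (deg/ps about z)
    and translation (nm/ps along x) that optimal superposition must remove.
    """

    n_atoms: int = 50
    n_frames: int = 200
    dt: float = 10.0  # ps
    fluctuation_sd: float = 0.05  # nm
    rigid_motion: tuple[float, float] | None = None  # (deg/ps, nm/ps)
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 3:
            raise ContractError("n_atoms must be >= 3")
        if self.n_frames < 2:
            raise ContractError("n_frames must be >= 2")
        if self.fluctuation_sd < 0:
            raise ContractError("fluctuation_sd must be >= 0")
        if self.dt <= 0:
            raise ContractError("dt must be positive")


@dataclass
class SyntheticLibrary:
    records: list[CompoundRecord]
    scores: ScoreTable
    profiles: dict[str, PhyschemProfile]
    efficiency_inputs: dict[str, EfficiencyInputs]
    metadata: dict = field(default_factory=dict)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_library(spec: LibrarySpec) -> SyntheticLibrary:
    """Draw a compound library with scores, profiles and metric inputs.

    Binding energies ~ Normal(be_mean, be_sd); heavy atoms uniform over
    ha_range; logP ~ Normal(logp_mean, logp_sd).  A
    ``fraction_rule_failures`` subset receives a descriptor pair inside the
    logP>3 / TPSA<75 risk region; everyone else gets TPSA above 75 so the
    rule stage passes them regardless of logP.  The planted hit (if any)
    gets a binding energy ``be_margin`` below the library minimum and
    all-rule-passing descriptors.
    """
    rng_be, rng_ha, rng_logp, rng_fail = _streams(spec.seed, 4)
    n = spec.n_compounds
    be = rng_be.normal(spec.be_mean, spec.be_sd, size=n)
    ha = rng_ha.integers(spec.ha_range[0], spec.ha_range[1] + 1, size=n)
    logp = rng_logp.normal(spec.logp_mean, spec.logp_sd, size=n)

    n_fail = int(round(spec.fraction_rule_failures * n))
    fail_idx = set(rng_fail.choice(n, size=n_fail, replace=False).tolist())
    tpsa = np.where(
        [i in fail_idx for i in range(n)],
        rng_fail.uniform(40.0, 74.0, size=n),
        rng_fail.uniform(76.0, 140.0, size=n),
    )
    logp = np.where([i in fail_idx for i in range(n)], rng_fail.uniform(3.1, 5.0, size=n), logp)

    ids = [f"SYN{i:05d}" for i in range(n)]
    roles = [Role.ANALOG] * n
    if spec.planted_hit is not None:
        hit_id, margin = spec.planted_hit
        ids.append(hit_id)
        roles.append(Role.ANALOG)
        be = np.append(be, be.min() - margin)
        ha = np.append(ha, int(np.median(ha)))
        logp = np.append(logp, 2.0)
        tpsa = np.append(tpsa, 90.0)

    records, entries = [], []
    profiles: dict[str, PhyschemProfile] = {}
    eff: dict[str, EfficiencyInputs] = {}
    for i, cid in enumerate(ids):
        records.append(CompoundRecord(cid, cid, roles[i]))
        entries.append(ScoreEntry(cid, float(be[i]), ScoreSource.VINA))
        profiles[cid] = PhyschemProfile(
            mw=float(12.5 * ha[i]),  # crude organic-molecule mass proxy
            heavy_atoms=int(ha[i]),
            n_hba=4,
            n_hbd=2,
            tpsa=float(tpsa[i]),
            logp=float(logp[i]),
        )
        eff[cid] = EfficiencyInputs(float(be[i]), int(ha[i]), float(logp[i]))
    return SyntheticLibrary(
        records,
        ScoreTable(entries),
        profiles,
        eff,
        metadata={"spec": spec, "seed": spec.seed},
    )


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Reference geometry + optional rigid motion + i.i.d. Gaussian jitter."""
    rng_ref, rng_noise = _streams(spec.seed, 2)
    reference = rng_ref.normal(0.0, 1.0, size=(spec.n_atoms, 3))
    frames, times = [], []
    for k in range(spec.n_frames):
        t = k * spec.dt
        coords = reference
        if spec.rigid_motion is not None:
            rot_rate, trans_rate = spec.rigid_motion
            coords = coords @ _rotation_z(rot_rate * t).T
            coords = coords + np.array([trans_rate * t, 0.0, 0.0])
        coords = coords + rng_noise.normal(0.0, spec.fluctuation_sd, size=coords.shape)
        frames.append(StructureFrame(coords))
        times.append(t)
    return Trajectory(frames, np.asarray(times))


def generate_adduct_energies(
    n: int,
    stabilization_mean: float = -50.0,
    stabilization_sd: float = 5.0,
    seed: int = 0,
) -> list[tuple[str, float, float, float]]:
    """Component/adduct energy triples with an additive stabilization term.

    Returns (id, e_adduct, e_compound, e_peptide) rows where
    e_adduct = e_compound + e_peptide + delta, delta ~ Normal(mean, sd),
    so the stabilization operation recovers delta exactly.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if stabilization_sd < 0:
        raise ContractError("stabilization_sd must be >= 0")
    rng_comp, rng_pep, rng_delta = _streams(seed, 3)
    e_comp = rng_comp.normal(-46.0, 2.0, size=n)
    e_pep = rng_pep.normal(-62.0, 1.0, size=n)
    delta = rng_delta.normal(stabilization_mean, stabilization_sd, size=n)
    return [
        (f"ADD{i:04d}", float(e_comp[i] + e_pep[i] + delta[i]), float(e_comp[i]), float(e_pep[i]))
        for i in range(n)
    ]
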