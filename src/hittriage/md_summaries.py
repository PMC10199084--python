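"""Scalar summary statistics over molecular-dynamics trajectories.

Implements the trajectory-level observables commonly reported for
protein-ligand complex stability — RMSD after optimal (Kabsch)
superposition, per-atom RMSF, radius of gyration, geometric hydrogen-bond
counts — plus mean +/- sd summaries of arbitrary per-frame scalar series
(solvent-accessible surface area/volume/density, H-bond counts, ...)
ingested from simulation-package output.

Units: coordinates and distances in nm, times in ps, masses in amu.
Solvent-accessible surface quantities are never recomputed from
coordinates here; they arrive as precomputed series and are summarised.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractError, FormatError

__all__ = [
    "StructureFrame",
    "Trajectory",
    "FrameSeries",
    "SummaryStat",
    "HBondCriterion",
    "KabschResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_atom",
    "radius_of_gyration",
    "count_hbonds",
    "series_summary",
    "parse_xvg",
    "write_xvg",
    "read_xyz",
    "write_xyz",
    "OBSERVABLE_UNITS",
]

#: Units for the recognised per-frame observables.
OBSERVABLE_UNITS = {
    "rmsd_nm": "nm",
    "rg_nm": "nm",
    "sasa_nm2": "nm^2",
    "sas_volume_nm3": "nm^3",
    "sas_density": "g/L",
    "hbonds_protein": "count",
    "hbonds_protein_ligand": "count",
    "other": "",
}


@dataclass
class StructureFrame:
    """A single structure: N x 3 coordinates (nm) with per-atom masses."""

    coordinates: np.ndarray
    masses: np.ndarray | None = None
    atom_labels: list[str] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ContractError("coordinates must be an N x 3 array")
        if self.coordinates.shape[0] < 1:
            raise ContractError("a frame needs at least one atom")
        if not np.all(np.isfinite(self.coordinates)):
            raise ContractError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.ones(len(self.coordinates))
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.coordinates),):
                raise ContractError("masses must be one value per atom")
            if np.any(self.masses <= 0):
                raise ContractError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


@dataclass
class Trajectory:
    """An ordered, congruent sequence of frames with strictly increasing times."""

    frames: list[StructureFrame]
    times: np.ndarray  # ps

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ContractError("one time per frame required")
        if len(self.frames) == 0:
            raise ContractError("trajectory must have at least one frame")
        n = self.frames[0].n_atoms
        if any(f.n_atoms != n for f in self.frames):
            raise ContractError("all frames must have the same atom count")
        if np.any(np.diff(self.times) <= 0):
            raise ContractError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms


@dataclass
class FrameSeries:
    """Per-frame scalar observable with units fixed by the observable name."""

    observable: str
    times: np.ndarray  # ps
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ContractError("times and values must have equal length")
        if self.observable not in OBSERVABLE_UNITS:
            self.observable = "other"

    @property
    def units(self) -> str:
        return OBSERVABLE_UNITS[self.observable]


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float  # population standard deviation
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (GROMACS-style defaults)."""

    max_da_distance: float = 0.35  # nm, donor-acceptor
    max_angle: float = 30.0  # degrees, hydrogen-donor-acceptor

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_angle <= 0:
            raise ContractError("criterion parameters must be positive")


@dataclass(frozen=True)
class KabschResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation about centroids
    rmsd: float  # nm, mass-weighted
    degenerate: bool = False


def _weighted_centroid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w[:, None] * x).sum(axis=0) / w.sum()


def kabsch_superpose(mobile: StructureFrame, reference: StructureFrame) -> KabschResult:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Minimises the mass-weighted RMSD over all rotations and translations;
    the returned rotation always has determinant +1 (reflections are
    corrected).  Degenerate geometries (fewer than three atoms, or all
    atoms collinear) do not determine a unique rotation; they are flagged
    and fitted by translation only.
    """
    if mobile.n_atoms != reference.n_atoms:
        raise ContractError(
            f"atom-count mismatch: {mobile.n_atoms} vs {reference.n_atoms}"
        )
    if not np.allclose(mobile.masses, reference.masses):
        raise ContractError("mass vectors must agree between frames")
    w = mobile.masses
    x = mobile.coordinates - _weighted_centroid(mobile.coordinates, w)
    y = reference.coordinates - _weighted_centroid(reference.coordinates, w)

    degenerate = mobile.n_atoms < 3 or _collinear(x) or _collinear(y)
    if degenerate:
        rotation = np.eye(3)
    else:
        h = (w[:, None] * x).T @ y  # covariance
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = x @ rotation.T - y
    rmsd = math.sqrt(float((w * (diff**2).sum(axis=1)).sum() / w.sum()))
    translation = _weighted_centroid(reference.coordinates, w) - rotation @ _weighted_centroid(
        mobile.coordinates, w
    )
    return KabschResult(rotation, translation, rmsd, degenerate)


def _collinear(centered: np.ndarray, tol: float = 1e-10) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return bool((s > tol * max(1.0, s[0])).sum() < 2)


def _subframe(frame: StructureFrame, selection: Sequence[int] | None) -> StructureFrame:
    if selection is None:
        return frame
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= frame.n_atoms:
        raise ContractError("selection indices out of range")
    return StructureFrame(frame.coordinates[idx], frame.masses[idx])


def rmsd_series(
    traj: Trajectory,
    reference: StructureFrame,
    selection: Sequence[int] | None = None,
) -> FrameSeries:
    """Per-frame Kabsch RMSD against a fixed reference on selected atoms."""
    ref = _subframe(reference, selection)
    values = [
        kabsch_superpose(_subframe(f, selection), ref).rmsd for f in traj.frames
    ]
    return FrameSeries("rmsd_nm", traj.times, np.asarray(values))


def rmsf_per_atom(
    traj: Trajectory, selection: Sequence[int] | None = None
) -> np.ndarray:
    """Root-mean-square fluctuation of each atom about its mean position.

    Every frame is superposed (one round) onto the unweighted mean
    structure of the raw frames; fluctuations are then measured about the
    per-atom mean of the superposed coordinates.
    """
    if traj.n_frames < 2:
        raise ContractError("RMSF needs at least two frames")
    frames = [_subframe(f, selection) for f in traj.frames]
    coords = np.stack([f.coordinates for f in frames])
    mean0 = StructureFrame(coords.mean(axis=0), frames[0].masses)
    aligned = []
    for f in frames:
        fit = kabsch_superpose(f, mean0)
        aligned.append(f.coordinates @ fit.rotation.T + fit.translation)
    aligned = np.stack(aligned)
    mean1 = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean1) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(frame: StructureFrame) -> float:
    """Mass-weighted radius of gyration, nm."""
    com = _weighted_centroid(frame.coordinates, frame.masses)
    sq = ((frame.coordinates - com) ** 2).sum(axis=1)
    return math.sqrt(float((frame.masses * sq).sum() / frame.masses.sum()))


def count_hbonds(
    frame: StructureFrame,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
) -> int:
    """Count geometric hydrogen bonds in one frame.

    A (donor D, hydrogen H, acceptor A) triple bonds when the D-A distance
    is at most the cutoff and the H-D-A angle at most the angular cutoff.
    Each (D, A) pair contributes at most one bond even if the donor carries
    several hydrogens.
    """
    n = frame.n_atoms
    for d, h in donors:
        if d == h:
            raise ContractError("donor and hydrogen indices must differ")
        if not (0 <= d < n and 0 <= h < n):
            raise ContractError("donor/hydrogen index out of range")
    for a in acceptors:
        if not (0 <= a < n):
            raise ContractError("acceptor index out of range")
    xyz = frame.coordinates
    bonded: set[tuple[int, int]] = set()
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h or (d, a) in bonded:
                continue
            da = xyz[a] - xyz[d]
            dist = np.linalg.norm(da)
            if dist > criterion.max_da_distance or dist == 0:
                continue
            dh = xyz[h] - xyz[d]
            nh = np.linalg.norm(dh)
            if nh == 0:
                continue
            cosang = float(np.clip(np.dot(dh, da) / (nh * dist), -1.0, 1.0))
            if math.degrees(math.acos(cosang)) <= criterion.max_angle:
                bonded.add((d, a))
    return len(bonded)


def series_summary(series: FrameSeries, equilibration_skip: float = 0.0) -> SummaryStat:
    """Mean/sd (population) of a series after discarding early frames.

    ``equilibration_skip`` is in ps; frames with time >= skip are kept.
    """
    keep = series.values[series.times >= equilibration_skip]
    if keep.size == 0:
        raise ContractError("no frames remain after the equilibration skip")
    return SummaryStat(
        mean=float(keep.mean()),
        sd=float(keep.std(ddof=0)),
        min=float(keep.min()),
        max=float(keep.max()),
        n=int(keep.size),
    )


# --- text formats ---------------------------------------------------------


def parse_xvg(path: str | Path, observable: str = "other") -> FrameSeries:
    """Parse a two-column XVG-style series (comments start '#' or '@')."""
    times, values = [], []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.split()
        if len(parts) < 2:
            raise FormatError(f"bad data line in {path}: {line!r}")
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    if not times:
        raise FormatError(f"no data lines in {path}")
    return FrameSeries(observable, np.asarray(times), np.asarray(values))


def write_xvg(series: FrameSeries, path: str | Path, title: str = "") -> Path:
    path = Path(path)
    lines = [f"# {title}".rstrip(), f'@    yaxis  label "{series.units}"']
    lines += [f"{t:.6f} {v:.8f}" for t, v in zip(series.times, series.values)]
    path.write_text("\n".join(lines) + "\n")
    return path


_XYZ_TIME = re.compile(r"t\s*=\s*(-?\d+(?:\.\d+)?)")


def read_xyz(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file with coordinates in nm.

    The comment line may carry the frame time as ``t= <ps>``; otherwise
    frames are numbered 0, 1, 2, ... ps.
    """
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"expected atom count at line {i + 1} of {path}")
        if i + 2 + n > len(lines):
            raise FormatError(f"truncated frame at line {i + 1} of {path}")
        m = _XYZ_TIME.search(lines[i + 1])
        times.append(float(m.group(1)) if m else float(len(frames)))
        labels, coords = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"bad atom line {row!r} in {path}")
            labels.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        frames.append(StructureFrame(np.asarray(coords), atom_labels=labels))
        i += 2 + n
    if not frames:
        raise FormatError(f"no frames in {path}")
    return Trajectory(frames, np.asarray(times))


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    out = []
    for t, frame in zip(traj.times, traj.frames):
        labels = frame.atom_labels or ["X"] * frame.n_atoms
        out.append(str(frame.n_atoms))
        out.append(f"t= {t:g} ps; coordinates in nm")
        for lab, (x, y, z) in zip(labels, frame.coordinates):
            out.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")
    return path
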