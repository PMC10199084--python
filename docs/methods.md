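# Methods

This note documents the models, conventions and numerical choices behind
`hittriage`, and what the synthetic-data generators do and do not emulate.

## Ligand-efficiency metrics

The thermodynamic bridge from a docking score to a concentration scale is
Ki = exp(BE/RT). The gas constant is fixed at R = 1.98720425e-3
kcal/(mol·K) and the default temperature at T = 298.15 K, both
configurable through `ThermoConfig`. Published Ki columns rarely state the
temperature actually used; back-solving the shipped reference table gives
an implied RT ≈ 0.591 kcal/mol (T ≈ 297.5 K), about 0.3% below the
default. Consequently Ki values recomputed at the default agree with the
reference column to within ~4% relative, and any comparison against a
published Ki should budget ~5% slack. When a measured or published Ki is
available it can be passed as `ki_override`; the report records the
provenance (`computed` vs `override`), and LLE is then exactly
reproducible from the published column.

Threshold comparisons are inclusive (≥, and a closed LELP interval).
"Surpasses the threshold" is ambiguous about the boundary; inclusive
comparisons reproduce the reference pass/fail partition and make the
boundary case well-defined. All internal arithmetic is full precision;
3-decimal rounding is applied only when formatting reports.

Reproduction note: the reference metric table's LELP column was evidently
computed from its own printed 3-decimal LE values, which mix rounding and
truncation from row to row (one row truncates 0.38958 to 0.389, another
rounds 0.38783 to 0.388). Full-precision LELP therefore deviates from the
printed column by up to ~0.012 on one row, while dividing logP by the
printed LE reproduces every row within 0.01. The golden tests check
LE/LE_Scale/FQ/LLE at full precision (±0.002) and LELP through the
printed-LE procedure (±0.01).

## Drug-likeness rules

The Pfizer 3/75 rule names a *rejection* region: a compound is Rejected
precisely when logP > 3 **and** TPSA < 75 Å² (both strict). The printed
Accepted/Rejected outcomes of the reference descriptor table fix this
polarity. The Lipinski rule counts violations of its four bounds and
accepts below two.

Permissible ranges for the wider ADMET panel are data, not code: a small
grammar covers one-sided bounds (`> -5.15`, `<= 0.90`), closed intervals
(`100 ~ 600`, `-5 to 5`) and three-band label scales
(`0-0.3 excellent 0.3-0.7 medium; 0.7-1.0 poor`). Bounds written with
≤/≥ are inclusive; banded fields report their band label and only the
first declared band counts as Accepted. That convention is applied
uniformly, including to the clearance scale whose first band is the
high-clearance region — a screen that wants a different polarity there
should declare its own range set; the engine is deliberately data-driven.
Predicted ADMET panel values (permeability, hERG, AMES, ...) are always
ingested as data; only the six core descriptors can optionally be derived
from SMILES via RDKit.

## QM energetics

The module derives quantities from externally computed (DFT) energy
tables; it never runs electronic structure. The adduct stabilization
energy is the literal difference ΔE = E(adduct) − [E(compound) +
E(peptide)]. Published tables sometimes print the magnitude with a
favourable negative sign even where the component electrostatic potential
energies make the literal difference positive; rather than guess which
convention is an erratum, the result object exposes both `delta` (literal)
and `paper_convention_value` (= −|Δ|), and comparisons use the magnitude.

Two internal inconsistencies of the shipped reference energy table are
handled explicitly rather than smoothed over: the peptide row prints a
HOMO–LUMO gap of 3.33 eV where its own orbital energies give 4.66 eV, and
one analog row's printed stabilization energy (−50.61 kcal/mol) differs by
0.55 kcal/mol from the value its own components imply (−50.06). The
package always reports the recomputed value; the unit tests assert the
discrepancies so they remain visible.

## MD summary statistics

RMSD uses Kabsch superposition: the mass-weighted covariance matrix is
decomposed by SVD and the reflection corrected so the rotation determinant
is +1, which gives the global minimum RMSD over proper rigid motions.
Geometries that do not determine a unique rotation (fewer than three
atoms, or collinear configurations, detected by a singular-value rank
test at 1e-10 relative tolerance) are flagged and fitted by translation
only. The test suite cross-checks the implementation against an
independent quaternion eigenvalue oracle to 1e-9 nm.

RMSF superposes every frame onto the unweighted mean structure once (no
iteration to convergence) and measures fluctuations about the per-atom
mean of the aligned coordinates — deterministic and standard; iterating
changes results by far less than the statistical noise of any real
trajectory. The hydrogen-bond criterion defaults to a donor–acceptor
distance ≤ 0.35 nm and an H–D–A angle ≤ 30°, the common simulation-package
convention, and counts each donor–acceptor pair once. Series summaries
use the population standard deviation; with thousands of frames the
sample/population distinction is negligible, and the choice is stated in
the output schema.

Solvent-accessible surface area/volume/density are *not* recomputed from
coordinates — a SASA algorithm is a separate project — they are ingested
as per-frame series (XVG or CSV) and summarised. Coordinate trajectories
travel as multi-frame XYZ with coordinates in nm and the frame time on the
comment line (`t= <ps>`).

## Screening funnel

The dock-energy cutoff is a strict `<`: at the default −8.00 kcal/mol a
compound at exactly −8.00 is eliminated, one at −8.10 survives. Stages run
in the configured order (energy → rules → metrics); the ledger enforces
that every stage's entrants equal the previous stage's survivors and that
survivors plus eliminations exactly partition the entrants. Only
compounds with role `analog` enter the funnel by default — parent
scaffolds and control drugs are comparators, which is why a control that
happens to clear the energy cutoff is not counted among the survivors.

Consensus ranking is mean-rank (Borda-like) aggregation: per-criterion
ranks with mean-shared ties, direction-aware, optionally weighted, final
ties broken lexicographically by compound id for reproducibility. The
reference study's final single-candidate nomination integrates MD, EPE
and rescoring evidence narratively without a stated weighting, so no test
asserts a particular multi-criterion winner; published orderings are used
as fixtures for single-criterion rankings only.

## Synthetic data

The library generator draws binding energies Normal(−7, 1) kcal/mol by
default (237 compounds — the scale of the reference screen, whose reported
score range is consistent with that spread), heavy atoms uniform on
[15, 35], logP Normal(2.5, 0.8), and places a configurable fraction
(default 10%) of compounds in the 3/75 rejection region (logP 3.1–5, TPSA
40–74) while everyone else receives TPSA above 75. A planted hit gets a
binding energy a stated margin below the library minimum and
all-rule-passing descriptors, making it the deterministic top-ranked
survivor — the basis of the recovery checks. Molecular weight is a crude
12.5 Da/heavy-atom proxy; no valence, synthesizability or correlation
structure of real chemistry is imitated. Passing tests on this material
validates arithmetic, bookkeeping and statistical behaviour of the
pipeline, not performance on real screening data.

The trajectory generator emits a Gaussian reference cloud plus optional
rigid-body motion (rotation about z, translation along x) and i.i.d.
Gaussian jitter per coordinate — enough structure to verify that
superposition removes rigid motion exactly and that RMSF/RMSD statistics
match closed forms, nothing like real force-field dynamics. All
generators derive independent per-stage streams from one root seed via
`numpy.random.SeedSequence`, so identical specs are bitwise reproducible.

Desk-scale problem sizes used in the test suite (chosen so the whole
suite runs in seconds): libraries of 60–5000 compounds, 100-replicate
recovery experiments, trajectories up to 100 atoms × 2000 frames. The
published MD observables (e.g. an RMSD of 0.37 ± 0.03 nm for the best
complex), MM/GBSA values and DFT orbital energies depend on 100 ns
GROMACS runs, Amber rescoring and B3LYP/6-31G* calculations on systems
that are not redistributable; those numbers enter the package only as
fixture inputs for ranking, never as recomputation targets, and the
components that consume them are validated against independent oracles
(quaternion RMSD, brute-force H-bond scans, closed-form Rg/RMSF cases,
Normal-tail survivor fractions) instead.

## Known limitations

- Docking-log parsing covers the two common result-block dialects
  (score-table and per-conformer energy lines) but not exotic variants;
  multi-ligand logs must carry ligand identifiers.
- The permissible-range grammar is intentionally small; ranges with units
  in the label or open intervals are not parsed.
- No pose geometry, PDB/PDBQT writing, SASA computation, per-residue
  mapping, or network retrieval of structures.
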