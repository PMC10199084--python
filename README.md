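# hittriage

Hit-triage analytics for structure-based virtual screening campaigns.

A docking screen produces a pile of binding energies; turning that pile into
a defensible shortlist takes a chain of small, well-defined computations:
ligand-efficiency metrics, drug-likeness rule screens, derivations over
quantum-chemistry output tables, molecular-dynamics summary statistics, and
a staged elimination funnel with an auditable ledger. `hittriage`
implements that chain as a tested Python library with a thin CLI, using as
its worked reference the published triage of andrographolide (AGP) analogs
against the inflammation target cyclooxygenase-2 (COX-2), whose main-text
tables ship with the package as fixtures.

## What it computes

**Ligand-efficiency metrics.** From a docking binding energy BE (kcal/mol),
heavy-atom count HA and logP:

    Ki       = exp(BE / RT)                       inhibition constant (M)
    LE       = -BE / HA                           ligand efficiency
    LLE      = -log10(Ki) - logP                  lipophilic efficiency
    LE_Scale = 0.873 e^(-0.026 HA) - 0.064        size-dependent maximal LE
    FQ       = LE / LE_Scale                      fit quality
    LELP     = logP / LE                          lipophilic price of LE

with the conventional hit thresholds LE >= 0.3 kcal/mol/HA, LLE >= 3,
FQ >= 0.8, LELP in [-10, +10] (inclusive).

**Drug-likeness rules.** The Lipinski rule of five (Accepted below two
violations of MW <= 500, logP <= 5, HBA <= 10, HBD <= 5) and the Pfizer 3/75
rule (Rejected when logP > 3 and TPSA < 75 Å², both strict), plus a
data-driven screen of arbitrary ADMET fields against declared permissible
ranges, including three-band (excellent/medium/poor) scales.

**QM energetics.** HOMO–LUMO gaps, adduct stabilization energies
ΔE = E(adduct) − [E(compound) + E(peptide)] from electrostatic potential
energies, and tie-aware energy rankings. Energies are ingested from DFT
output tables; no electronic structure is computed here.

**MD summaries.** Kabsch (optimal proper-rotation) RMSD, per-atom RMSF,
radius of gyration, geometric hydrogen-bond counts (0.35 nm / 30°
defaults), and mean ± sd summaries of per-frame scalar series (XVG or CSV).

**Screening funnel.** Dock-energy cutoff (strict `<`), rule stage, metric
stage — each stage recording survivors and per-compound elimination
reasons — followed by a Borda-style consensus ranking of the finalists.

**Synthetic data.** Seeded generators for compound libraries, trajectories
and adduct energy tables with known statistical structure, so every stage
is testable end to end without any external engine.

## Worked example

```python
import hittriage as ht

# the shipped reference tables: docking energies, ADMET profiles,
# published metrics, orbital/EPE energies
records, scores = ht.tables_io.records_from_fixture()
t3, t4 = ht.load_fixture("table3"), ht.load_fixture("table4")

rep = ht.evaluate_metrics(ht.EfficiencyInputs(
    binding_energy=scores.energy_of("132210508"),   # analog A1, -9.35 kcal/mol
    heavy_atoms=24, logp=2.763,
))
print(f"LE={rep.le:.3f}  FQ={rep.fq:.3f}  LELP={rep.lelp:.3f}  pass={rep.passes}")
# LE=0.390  FQ=0.965  LELP=7.092  pass=True
```

`LE=0.390` means A1 gains 0.39 kcal/mol of predicted binding free energy
per heavy atom — comfortably above the 0.3 hit threshold; `FQ` close to 1
says that efficiency is near the empirical maximum for a 24-heavy-atom
molecule, and `LELP` ≈ 7 stays inside the acceptable lipophilicity price
band, so the compound passes every metric flag.

Run the whole funnel on the reference tables from the shell:

```
$ hittriage triage --outdir out/
screening funnel
  dock_cutoff: 7 -> 7
  rules: 7 -> 6
  metrics: 6 -> 6
  final survivors: A1, A2, A3, A4, A6, A7
```

Seven analogs clear the −8.00 kcal/mol docking cutoff; the rule stage
removes A5 (logP 3.229 with TPSA 66.76 places it in the 3/75 toxicity-risk
region); no further analog falls at the metric stage. `out/ledger.csv`
records every elimination with its reason, `out/ranking.csv` the final
energy-ranked shortlist.

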