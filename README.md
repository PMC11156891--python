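# protrefine

Post-prediction refinement of AI-generated protein structure models.

Structure predictors such as AlphaFold 2, OpenFold and ESMFold emit
single-chain, ligand-free models in which every residue carries a pLDDT
confidence score (0–100, written into the PDB B-factor column). For many
downstream uses — docking, cavity analysis, comparative studies — two
refinements are needed: removing the low-confidence regions that would
otherwise pollute the geometry, and restoring the biologically relevant
small molecules (cofactors, substrates) that homology models of the same
protein often contain. `protrefine` implements both, plus the sequence
filtering/routing logic that decides which predictor can fold which
sequence, and the quality-statistics layer used to characterize the
resulting model collections.

## Methods at a glance

**Confidence trimming.** For residue *i* with per-residue confidence
pLDDT(*i*), the smoothed score is the mean of pLDDT over the window
*i* ± 3 (truncated at chain termini). Residues with smoothed score < 70
are removed. The surviving runs of consecutive residues are screened
geometrically: with the largest run taken as the protein core, a detached
run is kept only if it lies within 10 Å of the core, or within 5 Å of a
run that itself lies within 10 Å of the core. Models with fewer than 10
surviving residues are dropped; ligands left more than 5 Å from any
protein atom are discarded.

**Ligand transplantation.** Given an AI model and a homology model of the
same protein, the best-matching donor chain is selected by global sequence
alignment (ties broken by ligand count). For each small-molecule ligand in
contact with the donor (≤ 5 Å), the binding-site residues within radius
*r* ∈ {5, 10, 15} Å of the ligand are superposed onto the AI model with
two correspondence strategies (sequence-guided and structure-guided), each
solved by the Kabsch least-squares rigid fit with iterative outlier
rejection. The lowest-RMSD fit wins; if that RMSD ≤ 7 Å the ligand is
copied through the transform, then screened for steric clashes
(< 2 Å heavy-atom contacts), optionally after an external
energy-minimization hook.

**QC statistics.** Per-model pLDDT quartiles and the strict percentages of
residues above 90 / above 70, backbone φ/ψ dihedrals, dihedral-region
secondary-structure fractions, pairwise inter-model RMSD, and a one-row-
per-protein CSV report.

## Worked example

```python
import numpy as np
from protrefine import fixtures, transplant, trim

# a 40-residue helix plus a homology donor carrying one bound ligand
ai, donor, expected = fixtures.make_donor_pair(n_residues=40)
out, report = transplant.transplant_all(ai, donor)
print(report.outcomes())                # {'transplanted': 1}
print(round(report.entries[0].best_rmsd, 6))   # 0.0
placed = out.ligands[0].coords_array(heavy_only=False)
print(np.abs(placed - expected[0]).max() < 1e-9)  # True

# trim a model with a low-confidence linker between two confident lobes
model = fixtures.make_trim_fixture(fixtures.FixtureSpec(
    n_residues=60, plddt_profile=fixtures.profile_two_lobe_low_linker()))
trimmed, rep = trim.trim_model(model)
print(sorted(k[1] for k in rep.removed_by_plddt))  # [27, ..., 34]
```

The self-transplant lands the ligand exactly on its donor coordinates
(site RMSD 0), and the windowed-average criterion removes exactly the
eight linker residues whose ±3-window mean falls below 70.

The same operations are available from the shell:

```bash
protrefine fixtures --out demo/
protrefine pipeline --in demo/ --out refined/
protrefine trim --in model.pdb --out refined.pdb --report report.json
protrefine transplant --ai model.pdb --donor HM_model.pdb --out out.pdb
protrefine stats --in refined/ --out stats.csv
protrefine plan --fasta proteome.fasta --out plan.csv
```

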