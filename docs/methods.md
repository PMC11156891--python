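# Methods

## Scope and data model

The package operates on PDB-format protein structure models. AI-predicted
models (AlphaFold 2 / OpenFold / ESMFold style) are single-chain monomers
whose B-factor column carries the per-residue pLDDT confidence score;
homology models may have several chains and HETATM ligand groups. The
in-memory container (`StructureModel`) keeps chains of residues (ordered
as in the file, 1-based PDB numbering authoritative), a flat list of
ligand groups keyed by (het code, chain, residue number), and an opaque
metadata map (template id, z-score, oligomeric state are carried but never
computed). Waters are dropped on read; only the first MODEL of a
multi-model file is used; insertion codes are preserved. AI models with
more than one protein chain are rejected, matching the predictors'
single-chain output.

pLDDT scale harmonization: some services report the score as a fraction
(e.g. 0.953), others as a percentage (e.g. 95.32). If every B-factor in a
model is ≤ 1.0 the profile is treated as fractional and multiplied by 100,
then clipped to [0, 100]. A genuine percent-scale model whose scores are
all ≤ 1 would be misread, but such a model is practically impossible. The
transformation is idempotent.

## Sequence filtering and routing

Modeling eligibility requires protein-level evidence (existence level 1)
and a non-fragment sequence. AI eligibility further requires length in
[10, 2700] (both ends inclusive; the sources state the range without
marking openness) and no ambiguous residue letter (U, O, X, J, B, Z).
Routing by tool limits: AlphaFold 2 accepts every AI-eligible sequence;
OpenFold up to 2,000 residues; ESMFold through the public API for 10–400
residues and through BioNeMo for 401–1,024; beyond 1,024 no ESMFold model
is produced. Homology modeling is always attempted (template availability
is decided elsewhere and out of scope).

The accounting helpers are plain integer arithmetic: newly folded
AlphaFold 2 models = all AF2 models − database retrievals; the AI total is
that number plus the OpenFold and ESMFold counts; the collection total
adds homology models. Coverage percentages are rounded half-up to two
decimals to match the printed style of the source counts.

## Confidence trimming

For each residue the pLDDT profile is averaged over a ±3-residue window,
truncated at chain termini (so terminal windows are shorter, never
padded). Residues with windowed average strictly below 70 are flagged; an
average of exactly 70 survives. Window averages are computed once on the
intact chain and never recomputed after removal — this prevents cascade
erosion at freshly created termini and makes trimming idempotent on the
retained set.

Geometric pruning operates on segments — maximal runs of consecutive
retained residues within one chain. The protein core is defined as the
segment with the most residues (ties: earliest start); the term is not
defined more precisely anywhere authoritative, and the largest confident
segment is the natural reading. A non-core segment is kept iff its minimum
heavy-atom distance to the core is ≤ 10 Å, or ≤ 5 Å to a segment that is
itself within 10 Å of the core. The bridging rule is applied for exactly
one hop, not iterated to a fixpoint — the literal reading of the rule.
Distances default to all heavy atoms (`distance_atoms="ca"` switches to
Cα-only; the original procedure does not say which was used).

After pruning, models with fewer than 10 surviving residues are dropped
(the filter counts residues after all removals), and ligands without any
atom within 5 Å of a protein atom are discarded. Trimming is pure
deletion: retained coordinates are bit-identical to the input.

## Superposition

`kabsch_fit` is the closed-form least-squares rigid fit (SVD of the
cross-covariance with the determinant correction, so reflections are never
returned). Degenerate inputs — fewer than 3 points or collinear
configurations (centered rank < 2 at tolerance 1e-8) — raise a fit error.

Two correspondence builders emulate the alternating alignment modes of
interactive structure-alignment tools:

- **sequence-guided**: global pairwise alignment (BLOSUM62, gap open 10,
  extend 0.5) of the chains' one-letter sequences; aligned non-gap
  positions with Cα on both sides become pairs.
- **structure-guided**: residue identities are ignored. A coarse search
  over Cα fragments (length 8, stride 4) seeds a rigid fit; residues are
  then paired by mutual-nearest-neighbour Cα proximity under a 5 Å cap and
  the pairing is re-grown over up to 3 fit/re-pair cycles.

`refine_fit` iterates Kabsch fits with outlier rejection (drop pairs
deviating more than 2 SD above the mean deviation, refit, at most 5
cycles, stop when converged below 1e-6 Å or fewer than 3 pairs would
remain) and returns the lowest-RMSD fit seen, so refinement never worsens
the reported RMSD. RMSD is computed over Cα pairs — robust to side-chain
rebuild differences between modeling tools; the choice of atoms is a knob
because the original gate does not state it.

## Ligand transplantation

Donor chain selection ranks homology-model chains by global alignment
score against the AI model's sequence; exact ties break by the number of
ligands assigned to the chain (a ligand belongs to the chain owning its
nearest protein atom), then by chain id. Eligible ligands are
small molecules only — nucleotide groups and HETATM-recorded amino acids
are excluded — and must touch the donor (≤ 5 Å to some protein atom).

Each ligand is transplanted independently with its own best local fit:
all combinations of radius {5, 10, 15} Å and both correspondence
strategies are tried; the binding site is the set of reference residues
with an atom within the radius of the ligand, and at least 3 paired site
residues are required (otherwise that combination is skipped). The
lowest-RMSD success wins. If the best RMSD exceeds 7 Å the ligand is
rejected (`rmsd_gate_failed`); if no combination yields a fit at all the
outcome is `no_valid_fit`, a distinct code so the two failure modes are
distinguishable in reports. Accepted ligands are mapped through the
inverse of the winning transform (the fit maps acceptor → donor frame;
ligand atoms travel donor → acceptor).

Clash screening deletes any ligand with a heavy atom closer than 2.0 Å to
a protein heavy atom — a documented package decision, chosen well inside
the shortest plausible non-bonded contact, and exposed as `--clash-dist`.
Energy minimization is strictly an external hook (a command template
receiving input/output PDB paths, run before the clash screen); the
package never computes force-field energies. Acceptor protein coordinates
are never modified; transplantation is pure addition of HETATM groups,
which makes placement equivariant under rigid motions of the acceptor.

## Quality statistics

pLDDT summaries report min, quartiles (linear interpolation between order
statistics — the common default; the convention is recorded here because
the source does not state one) and max, plus the percentages of residues
with pLDDT strictly above 90 and strictly above 70. φ/ψ dihedrals follow
the standard backbone definitions; chain-terminal residues lack the
respective angle and residues with missing backbone atoms are skipped with
a warning. Secondary structure is assigned from dihedral regions (helix:
φ ∈ (−100, −30), ψ ∈ (−80, −5); strand: φ ∈ (−180, −100),
ψ ∈ (90, 180) ∪ (−180, −170); else coil; φ = +180° is folded onto −180°),
with helix/strand runs shorter than 3 residues reassigned to coil. This is
deliberately simple and approximate — it is not DSSP — but needs only
backbone atoms. Pairwise model RMSD corresponds residues by (chain id,
residue number) shared between two models, so partial-coverage homology
models compare over their common positions, and fits Cα coordinates with
the Kabsch solver. The CSV report has one row per accession with field
groups per model type; homology z-scores are opaque pass-through metadata,
never computed.

## Synthetic structures

Chains are built atom-by-atom with the NeRF construction from canonical
backbone internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
trans peptide), so requested torsions hold exactly: the ideal helix uses
(φ, ψ) = (−57°, −47°), giving the canonical ~1.5 Å rise and ~100°/residue
right-handed twist with consecutive Cα–Cα ≈ 3.8 Å; the extended fixture
uses (−135°, 135°). Pseudo-ligands are rigid 1–10 atom carbon clusters
(het code LIG) — chemistry is irrelevant to a purely geometric pipeline.
Donor/acceptor pairs place ligands in the acceptor frame and carry their
rigid-transform image in the donor, so the expected post-transplant
coordinates are known by construction, computed by direct geometry and
never by the modules under test. Fixture generation is fully
deterministic; the only randomness (random rigid transforms, randomized
pruning clusters) flows through an explicitly seeded generator.

What the fixtures do not emulate: real side chains, chemically meaningful
ligand poses, realistic pLDDT noise, and the long disordered tails typical
of real low-confidence regions. Passing tests therefore demonstrate
algorithmic correctness of the trimming/transplantation geometry and
bookkeeping, not predictive quality on real proteomes.

## Problem sizes and numerics

Tests and the acceptance script use chains of 9–100 residues, 1,000
randomized pruning fixtures for the brute-force oracle comparison and
10,000 random rigid transforms for the Monte-Carlo optimality baseline —
small enough to run in seconds while exercising every code path.
Tolerances: rotations orthonormal to 1e-10; exact-recovery fits to 1e-8 Å;
transplant coordinate fidelity to 1e-6 Å; fit convergence threshold
1e-6 Å. Tie-breaks are deterministic everywhere (core selection by size
then start index; chain selection by score, ligand count, then id), so
identical inputs give byte-identical outputs.

## Known limitations

- Single-model, single-conformer PDB input; no mmCIF, no PAE.
- The structure-guided correspondence is a light-weight stand-in for full
  structural aligners: adequate for homologous chains, not for remote
  fold matching.
- The dihedral secondary-structure assignment disagrees with DSSP near
  region boundaries.
- The 2.0 Å clash threshold and the one-hop bridging rule are documented
  package decisions where the original procedure is silent or literal,
  respectively; both are configurable.
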