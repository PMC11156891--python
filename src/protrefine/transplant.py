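"""Ligand transplantation from homology models into AI-predicted models.

AI predictors emit apo structures.  When a homology model of the same
protein carries bound small molecules, each ligand is moved into the AI
model by superposing the binding-site region locally (several radii, two
correspondence strategies), picking the lowest-RMSD fit, and copying the
ligand through that transform if the RMSD passes the 7 A gate.  Placed
ligands are then screened for steric clashes (optionally after an external
energy-minimization hook).  Protein atoms of the acceptor are never moved.
"""

from __future__ import annotations

import copy
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import PipelineError, ProtrefineError, ValidationError
from .model_io import Ligand, StructureModel, read_model, write_model
from .superpose import alignment_score, local_site_superpose

OUTCOMES = (
    "transplanted",
    "excluded_category",
    "no_donor_contact",
    "rmsd_gate_failed",
    "no_valid_fit",
    "clash_after_minimization",
    "dropped_after_trim",
)


@dataclass
class TransplantPolicy:
    """Thresholds of the transplantation procedure (defaults as published)."""

    radii: tuple[float, ...] = (5.0, 10.0, 15.0)   # A, site-selection radii
    strategies: tuple[str, ...] = ("sequence", "structure")
    rmsd_max: float = 7.0                          # A, site-RMSD gate
    donor_contact_distance: float = 5.0            # A, ligand must touch donor
    clash_distance: float = 2.0                    # A, heavy-atom clash limit
    retention_distance: float = 5.0                # A, post-trim retention

    def __post_init__(self):
        if not self.radii or any(r <= 0 for r in self.radii):
            raise ValidationError("radii must be positive")
        if list(self.radii) != sorted(self.radii):
            raise ValidationError("radii must be ascending")
        if self.rmsd_max <= 0:
            raise ValidationError("rmsd_max must be positive")


@dataclass
class TransplantEntry:
    het_id: str
    chain_id: str
    seq_number: int
    outcome: str
    best_rmsd: float | None = None
    winning_strategy: str | None = None
    chain_selected: str | None = None

    def to_dict(self) -> dict:
        return {
            "het_id": self.het_id,
            "chain_id": self.chain_id,
            "seq_number": self.seq_number,
            "outcome": self.outcome,
            "best_rmsd": self.best_rmsd,
            "winning_strategy": self.winning_strategy,
            "chain_selected": self.chain_selected,
        }


@dataclass
class TransplantReport:
    entries: list[TransplantEntry] = field(default_factory=list)
    chain_selected: str | None = None

    def outcomes(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.outcome] = counts.get(e.outcome, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "chain_selected": self.chain_selected,
            "entries": [e.to_dict() for e in self.entries],
            "outcomes": self.outcomes(),
        }


# ---------------------------------------------------------------------------
# Chain selection and ligand eligibility


def _ligand_chain_assignment(model: StructureModel) -> dict[int, str]:
    """Assign each ligand to the chain owning its nearest protein atom."""
    chain_xyz = {
        cid: np.vstack([r.coords_array() for r in chain])
        for cid, chain in model.chains.items()
        if chain
    }
    out: dict[int, str] = {}
    for lig in model.ligands:
        lx = lig.coords_array()
        best_cid, best_d = lig.chain_id, np.inf
        for cid, xyz in chain_xyz.items():
            d = float(cdist(lx, xyz).min())
            if d < best_d:
                best_cid, best_d = cid, d
        out[id(lig)] = best_cid
    return out


def select_best_chain(ai_model: StructureModel, homology_model: StructureModel) -> str:
    """Chain of the homology model best matching the AI model's sequence.

    Ranked by global alignment score; exact score ties are broken by the
    number of ligands assigned to the chain (more wins), then by chain id.
    """
    if not homology_model.chains:
        raise ValidationError("homology model has no chains")
    ai_seq = ai_model.sequence()
    assignment = _ligand_chain_assignment(homology_model)
    lig_counts = {cid: 0 for cid in homology_model.chains}
    for lig in homology_model.ligands:
        cid = assignment[id(lig)]
        if cid in lig_counts:
            lig_counts[cid] += 1
    ranked = sorted(
        homology_model.chains,
        key=lambda cid: (
            -alignment_score(ai_seq, homology_model.sequence(cid)),
            -lig_counts[cid],
            cid,
        ),
    )
    return ranked[0]


def eligible_ligands(
    homology_model: StructureModel,
    chain: str,
    policy: TransplantPolicy | None = None,
) -> list[Ligand]:
    """Transplantable ligands of the selected chain.

    Nucleic acids and HETATM-recorded amino acids are excluded, as are
    ligands with no atom within ``donor_contact_distance`` of any protein
    atom of the donor (no physical interaction possible).
    """
    policy = policy or TransplantPolicy()
    if chain not in homology_model.chains:
        raise ValidationError(f"no chain {chain!r} in homology model")
    eligible = []
    protein = homology_model.protein_coords()
    assignment = _ligand_chain_assignment(homology_model)
    for lig in homology_model.ligands:
        if assignment[id(lig)] != chain:
            continue
        if lig.category != "small_molecule":
            continue
        if float(cdist(lig.coords_array(), protein).min()) > policy.donor_contact_distance:
            continue
        eligible.append(lig)
    return eligible


# ---------------------------------------------------------------------------
# Transplantation


def transplant_ligand(
    ai_model: StructureModel,
    homology_model: StructureModel,
    chain: str,
    ligand: Ligand,
    policy: TransplantPolicy | None = None,
) -> tuple[Ligand | None, TransplantEntry]:
    """Place one donor ligand into the AI model via its best local fit.

    All (radius, strategy) combinations are tried with
    :func:`local_site_superpose`; the lowest-RMSD success wins.  If that
    RMSD is within ``rmsd_max`` the ligand's atoms are mapped through the
    inverse transform (reference -> mobile frame) and returned as a new
    :class:`Ligand`; otherwise the transplant is rejected.
    """
    policy = policy or TransplantPolicy()
    reference_chain = homology_model.chains[chain]
    best = None
    for strategy in policy.strategies:
        for radius in policy.radii:
            try:
                res = local_site_superpose(
                    ai_model, reference_chain, ligand, radius, strategy
                )
            except ProtrefineError:
                # site too small, no correspondence, degenerate fit:
                # that (radius, strategy) combination is simply skipped
                continue
            if best is None or res.rmsd < best.rmsd:
                best = res

    entry = TransplantEntry(
        het_id=ligand.het_id,
        chain_id=ligand.chain_id,
        seq_number=ligand.seq_number,
        outcome="no_valid_fit",
        chain_selected=chain,
    )
    if best is None:
        return None, entry
    entry.best_rmsd = best.rmsd
    entry.winning_strategy = best.strategy_label
    if best.rmsd > policy.rmsd_max:
        entry.outcome = "rmsd_gate_failed"
        return None, entry

    into_ai = best.inverse()  # reference (donor) frame -> mobile (AI) frame
    placed_atoms = []
    for a in ligand.atoms:
        na = copy.deepcopy(a)
        na.coords = into_ai.apply(a.coords.reshape(1, 3))[0]
        placed_atoms.append(na)
    placed = Ligand(
        het_id=ligand.het_id,
        chain_id=ligand.chain_id,
        seq_number=ligand.seq_number,
        atoms=placed_atoms,
    )
    entry.outcome = "transplanted"
    return placed, entry


def run_minimizer_hook(model: StructureModel, hook: str) -> StructureModel:
    """Run an external minimizer command on the model.

    ``hook`` is a command template containing ``{in}`` and ``{out}``
    placeholders for PDB paths; the minimized file is read back.  Process
    failure raises :class:`PipelineError` carrying the captured stderr.
    """
    with tempfile.TemporaryDirectory() as tmp:
        pin = Path(tmp) / "in.pdb"
        pout = Path(tmp) / "out.pdb"
        write_model(model, pin)
        cmd = [
            part.replace("{in}", str(pin)).replace("{out}", str(pout))
            for part in shlex.split(hook)
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not pout.exists():
            raise PipelineError(
                f"minimizer hook failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        out = read_model(pout, model_type=model.model_type)
        out.accession, out.description = model.accession, model.description
        out.metadata = dict(model.metadata)
        return out


def clash_screen(
    model: StructureModel,
    policy: TransplantPolicy | None = None,
    minimizer_hook: str | None = None,
) -> tuple[StructureModel, list[str]]:
    """Delete placed ligands that clash with the protein.

    If a minimizer hook is given it is run first (external relaxation may
    resolve borderline contacts); any ligand still having a heavy atom
    closer than ``clash_distance`` to a protein heavy atom is deleted.
    Returns the screened model and the het_ids deleted.
    """
    policy = policy or TransplantPolicy()
    if minimizer_hook:
        model = run_minimizer_hook(model, minimizer_hook)
    else:
        model = model.copy()
    if not model.ligands:
        return model, []
    protein = model.protein_coords(heavy_only=True)
    kept, deleted = [], []
    for lig in model.ligands:
        d = float(cdist(lig.coords_array(heavy_only=True), protein).min())
        if d < policy.clash_distance:
            deleted.append(lig.het_id)
        else:
            kept.append(lig)
    model.ligands = kept
    return model, deleted


def transplant_all(
    ai_model: StructureModel,
    homology_model: StructureModel,
    policy: TransplantPolicy | None = None,
    minimizer_hook: str | None = None,
) -> tuple[StructureModel, TransplantReport]:
    """Full transplantation pass for one AI model / donor pair.

    Selects the best-matching donor chain, transplants each eligible ligand
    independently via its own best local fit, then clash-screens the
    complex.  The acceptor's protein coordinates are never modified.
    """
    policy = policy or TransplantPolicy()
    if ai_model.accession and homology_model.accession and (
        ai_model.accession != homology_model.accession
    ):
        raise ValidationError(
            f"accession mismatch: {ai_model.accession} vs {homology_model.accession}"
        )
    report = TransplantReport()
    out = ai_model.copy()
    if not homology_model.ligands:
        return out, report

    chain = select_best_chain(ai_model, homology_model)
    report.chain_selected = chain
    assignment = _ligand_chain_assignment(homology_model)
    protein = homology_model.protein_coords()

    placed_any = False
    for lig in homology_model.ligands:
        if assignment[id(lig)] != chain:
            continue
        if lig.category != "small_molecule":
            report.entries.append(
                TransplantEntry(lig.het_id, lig.chain_id, lig.seq_number,
                                "excluded_category", chain_selected=chain)
            )
            continue
        if float(cdist(lig.coords_array(), protein).min()) > policy.donor_contact_distance:
            report.entries.append(
                TransplantEntry(lig.het_id, lig.chain_id, lig.seq_number,
                                "no_donor_contact", chain_selected=chain)
            )
            continue
        placed, entry = transplant_ligand(ai_model, homology_model, chain, lig, policy)
        report.entries.append(entry)
        if placed is not None:
            out.ligands.append(placed)
            placed_any = True

    if placed_any:
        out, deleted = clash_screen(out, policy, minimizer_hook)
        for het in deleted:
            for e in report.entries:
                if e.het_id == het and e.outcome == "transplanted":
                    e.outcome = "clash_after_minimization"
                    break
    return out, report
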