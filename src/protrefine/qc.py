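"""Per-model quality statistics: pLDDT summaries, Ramachandran dihedrals,
secondary-structure fractions, pairwise model RMSD, and the CSV report.

Quartiles use linear interpolation between order statistics; the "above
90" / "above 70" percentages use strict inequalities, so a residue at
exactly 90 does not count as high-confidence.  Secondary structure is a
deliberately simple dihedral-region assignment (not DSSP): it needs only
backbone atoms and is adequate for helix/strand/coil fractions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .model_io import Residue, StructureModel
from .superpose import kabsch_fit


@dataclass
class DihedralRecord:
    chain_id: str
    seq_number: int
    res_name: str
    phi: float | None  # degrees in (-180, 180]; None at N-terminus
    psi: float | None  # degrees in (-180, 180]; None at C-terminus


@dataclass
class ModelStats:
    """One row of the per-protein statistics report."""

    accession: str
    model_type: str
    n_residues: int
    plddt_min: float | None = None
    plddt_q1: float | None = None
    plddt_median: float | None = None
    plddt_q3: float | None = None
    plddt_max: float | None = None
    pct_above_90: float | None = None
    pct_above_70: float | None = None
    ligand_ids: list[str] = field(default_factory=list)
    sequence_coverage: float | None = None  # homology: monomer/full-length %
    z_score: float | None = None            # opaque pass-through metadata
    helix_pct: float | None = None
    strand_pct: float | None = None
    coil_pct: float | None = None
    gene_names: str = ""
    sequence: str = ""


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def plddt_summary(model: StructureModel) -> dict[str, float]:
    """Min/quartiles/max of the per-residue pLDDT profile plus the strict
    percentages of residues above 90 and above 70."""
    profile = model.plddt_profile()
    if profile.size == 0:
        raise ValidationError("model has no residues")
    q1, med, q3 = np.percentile(profile, [25, 50, 75])
    n = profile.size
    return {
        "plddt_min": float(profile.min()),
        "plddt_q1": float(q1),
        "plddt_median": float(med),
        "plddt_q3": float(q3),
        "plddt_max": float(profile.max()),
        "pct_above_90": float(100.0 * np.count_nonzero(profile > 90.0) / n),
        "pct_above_70": float(100.0 * np.count_nonzero(profile > 70.0) / n),
    }


def ramachandran(model: StructureModel) -> list[DihedralRecord]:
    """Backbone phi/psi angles per residue.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Terminal residues lack the respective angle; residues with missing
    backbone atoms are skipped with a warning.
    """
    records: list[DihedralRecord] = []
    for chain in model.chains.values():
        for i, res in enumerate(chain):
            bb = {name: res.atom(name) for name in ("N", "CA", "C")}
            if any(a is None for a in bb.values()):
                warnings.warn(f"residue {res.key}: missing backbone atom, skipped")
                continue
            phi = psi = None
            if i > 0:
                prev_c = chain[i - 1].atom("C")
                if prev_c is not None:
                    phi = dihedral_angle(prev_c.coords, bb["N"].coords,
                                         bb["CA"].coords, bb["C"].coords)
            if i < len(chain) - 1:
                next_n = chain[i + 1].atom("N")
                if next_n is not None:
                    psi = dihedral_angle(bb["N"].coords, bb["CA"].coords,
                                         bb["C"].coords, next_n.coords)
            if phi is None and psi is None:
                continue
            records.append(DihedralRecord(res.chain_id, res.seq_number,
                                          res.res_name, phi, psi))
    return records


def _classify(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "coil"
    if phi >= 180.0:  # fold +180 onto -180 for region tests
        phi -= 360.0
    if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
        return "helix"
    if -180.0 < phi < -100.0 and (90.0 < psi < 180.0 or -180.0 < psi < -170.0):
        return "strand"
    return "coil"


def secondary_structure_fractions(model: StructureModel) -> dict[str, float]:
    """Helix/strand/coil percentages from dihedral regions.

    Helix and strand runs shorter than 3 residues are reassigned to coil;
    the three fractions sum to 100 over all residues.
    """
    per_res: list[str] = []
    dihedrals = {(d.chain_id, d.seq_number): d for d in ramachandran(model)}
    for res in model.residues():
        d = dihedrals.get((res.chain_id, res.seq_number))
        per_res.append(_classify(d.phi, d.psi) if d else "coil")
    # suppress runs < 3
    n = len(per_res)
    i = 0
    while i < n:
        j = i
        while j < n and per_res[j] == per_res[i]:
            j += 1
        if per_res[i] in ("helix", "strand") and j - i < 3:
            for k in range(i, j):
                per_res[k] = "coil"
        i = j
    if n == 0:
        raise ValidationError("model has no residues")
    return {
        "helix_pct": 100.0 * per_res.count("helix") / n,
        "strand_pct": 100.0 * per_res.count("strand") / n,
        "coil_pct": 100.0 * per_res.count("coil") / n,
    }


def pairwise_model_rmsd(models: list[StructureModel]) -> np.ndarray:
    """Symmetric matrix of CA RMSDs after optimal superposition.

    Residues are corresponded by (chain id, residue number) common to both
    models, so partial-coverage homology models compare over their shared
    positions.  Pairs with fewer than 3 common residues get NaN.
    """
    if len(models) < 2:
        raise ValidationError("need at least 2 models")
    accs = {m.accession for m in models if m.accession}
    if len(accs) > 1:
        raise ValidationError(f"models span several accessions: {sorted(accs)}")
    ca_maps = []
    for m in models:
        ca = {}
        for res in m.residues():
            a = res.atom("CA")
            if a is not None:
                ca[(res.chain_id, res.seq_number)] = a.coords
        ca_maps.append(ca)
    k = len(models)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            common = sorted(set(ca_maps[i]) & set(ca_maps[j]))
            if len(common) < 3:
                mat[i, j] = mat[j, i] = np.nan
                continue
            a = np.array([ca_maps[i][key] for key in common])
            b = np.array([ca_maps[j][key] for key in common])
            mat[i, j] = mat[j, i] = kabsch_fit(a, b).rmsd
    return mat


def model_stats(
    model: StructureModel,
    full_sequence_length: int | None = None,
) -> ModelStats:
    """Assemble the full statistics row for one model."""
    stats = ModelStats(
        accession=model.accession,
        model_type=model.model_type,
        n_residues=model.n_residues,
        ligand_ids=sorted(lig.het_id for lig in model.ligands),
        gene_names=str(model.metadata.get("gene_names", "")),
        sequence=model.sequence() if model.chains else "",
    )
    if model.model_type != "homology":
        stats.__dict__.update(plddt_summary(model))
    else:
        z = model.metadata.get("z_score")
        stats.z_score = float(z) if z is not None else None
        if full_sequence_length:
            stats.sequence_coverage = 100.0 * model.n_residues / full_sequence_length
    stats.__dict__.update(secondary_structure_fractions(model))
    return stats


# ---------------------------------------------------------------------------
# CSV report

_AI_TYPES = ("alphafold2", "openfold", "esmfold")
_AI_FIELDS = (
    "n_residues", "plddt_min", "plddt_q1", "plddt_median", "plddt_q3",
    "plddt_max", "pct_above_90", "pct_above_70", "ligands",
    "helix_pct", "strand_pct", "coil_pct",
)
_HM_FIELDS = (
    "n_residues", "coverage_pct", "identity_pct", "similarity_pct",
    "z_score", "ligands", "helix_pct", "strand_pct", "coil_pct",
)

CSV_COLUMNS: tuple[str, ...] = (
    "accession", "gene_names", "sequence",
    *[f"{t}_available" for t in (*_AI_TYPES, "homology")],
    *[f"{t}_{f}" for t in _AI_TYPES for f in _AI_FIELDS],
    *[f"homology_{f}" for f in _HM_FIELDS],
)


def write_statistics_csv(stats: list[ModelStats], path: str | Path) -> None:
    """Write the statistics report: one RFC-4180 CSV row per accession,
    with one field group per model type."""
    rows: dict[str, dict[str, object]] = {}
    for s in stats:
        row = rows.setdefault(
            s.accession, {c: "" for c in CSV_COLUMNS} | {
                "accession": s.accession,
                **{f"{t}_available": False for t in (*_AI_TYPES, "homology")},
            },
        )
        if s.gene_names:
            row["gene_names"] = s.gene_names
        if s.sequence and s.model_type != "homology":
            row["sequence"] = s.sequence
        t = s.model_type
        row[f"{t}_available"] = True
        row[f"{t}_n_residues"] = s.n_residues
        row[f"{t}_ligands"] = ";".join(s.ligand_ids)
        for f in ("helix_pct", "strand_pct", "coil_pct"):
            row[f"{t}_{f}"] = _fmt(getattr(s, f))
        if t == "homology":
            row["homology_coverage_pct"] = _fmt(s.sequence_coverage)
            row["homology_z_score"] = _fmt(s.z_score)
        else:
            for f in ("plddt_min", "plddt_q1", "plddt_median", "plddt_q3",
                      "plddt_max", "pct_above_90", "pct_above_70"):
                row[f"{t}_{f}"] = _fmt(getattr(s, f))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CSV_COLUMNS))
        writer.writeheader()
        for acc in sorted(rows):
            writer.writerow(rows[acc])


def _fmt(val: float | None) -> str:
    return "" if val is None else f"{val:.4f}"
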