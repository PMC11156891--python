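"""PDB input/output and the in-memory structure container.

AI structure predictors (AlphaFold 2, OpenFold, ESMFold) write their
per-residue confidence score (pLDDT, 0-100) into the B-factor column of the
PDB files they emit.  This module reads such files into a light-weight
:class:`StructureModel`, harmonizes pLDDT scales (some services emit the
score as a fraction in [0, 1]), groups HETATM records into ligands, and
writes models back out with the dataset's header and naming conventions.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .errors import EmptyModelError, PDBParseError, ValidationError

#: 3-letter codes of the 20 standard amino acids.
STANDARD_AA: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Residue names of standard (deoxy)ribonucleotides as they appear in PDB files.
NUCLEOTIDE_CODES: frozenset[str] = frozenset(
    {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
)

WATER_CODES: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AI_MODEL_TYPES = ("alphafold2", "openfold", "esmfold")
MODEL_TYPES = AI_MODEL_TYPES + ("homology",)

#: Capitalized tokens used in dataset file names.
MODEL_TYPE_TOKEN = {
    "alphafold2": "AlphaFold2",
    "openfold": "OpenFold",
    "esmfold": "ESMFold",
}

STAGES = ("native", "relaxed", "refined", "relaxed_ligand", "refined_ligand", "homology")


@dataclass
class Atom:
    """A single atom record.

    ``bfactor`` carries either a crystallographic B-factor (homology models)
    or a pLDDT confidence value (AI models), per the PDB-column convention.
    """

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    is_hetatm: bool = False
    serial: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if self.serial < 1:
            raise ValidationError(f"atom {self.name!r}: serial must be >= 1")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    plddt: float | None = None

    def __post_init__(self):
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise ValidationError(f"residue {self.key}: pLDDT {self.plddt} outside [0, 100]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def coords_array(self, heavy_only: bool = True) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


LIGAND_CATEGORIES = ("small_molecule", "nucleic_acid", "hetatm_amino_acid")


@dataclass
class Ligand:
    """A HETATM group: one chemical component instance (e.g. one FAD)."""

    het_id: str
    chain_id: str
    seq_number: int
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValidationError(f"ligand {self.het_id}: no atoms")

    @property
    def category(self) -> str:
        if self.het_id in NUCLEOTIDE_CODES:
            return "nucleic_acid"
        if self.het_id in STANDARD_AA:
            return "hetatm_amino_acid"
        return "small_molecule"

    def coords_array(self, heavy_only: bool = True) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    """Chains of protein residues plus ligand groups and metadata."""

    accession: str = ""
    description: str = ""
    model_type: str = "alphafold2"
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Ligand] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_type not in MODEL_TYPES:
            raise ValidationError(f"unknown model_type {self.model_type!r}")
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise ValidationError(f"duplicate residue {res.key}")
            seen.add(res.key)

    # -- access helpers -------------------------------------------------

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def chain(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is None:
            if not self.chains:
                raise ValidationError("model has no chains")
            return next(iter(self.chains.values()))
        return self.chains[chain_id]

    def sequence(self, chain_id: str | None = None) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))

    def plddt_profile(self) -> np.ndarray:
        vals = []
        for res in self.residues():
            if res.plddt is None:
                raise ValidationError(f"residue {res.key} has no pLDDT value")
            vals.append(res.plddt)
        return np.array(vals, dtype=float)

    def protein_coords(self, heavy_only: bool = True) -> np.ndarray:
        arrs = [r.coords_array(heavy_only) for r in self.residues()]
        if not arrs:
            return np.zeros((0, 3))
        return np.vstack(arrs)

    def copy(self) -> "StructureModel":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom (protein + ligand) rigidly moved."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in out.residues():
            for a in res.atoms:
                a.coords = R @ a.coords + t
        for lig in out.ligands:
            for a in lig.atoms:
                a.coords = R @ a.coords + t
        return out


# ---------------------------------------------------------------------------
# pLDDT scale harmonization


def harmonize_plddt_scale(raw_bfactors: Sequence[float]) -> list[float]:
    """Bring per-residue confidence values onto the percent scale [0, 100].

    Some prediction services report pLDDT as a fraction (e.g. 0.953), others
    as a percentage (e.g. 95.32).  If every value is <= 1.0 the whole profile
    is interpreted as fractional and multiplied by 100; otherwise it is
    returned unchanged.  Output is clipped to [0, 100].
    """
    vals = np.asarray(list(raw_bfactors), dtype=float)
    if vals.size == 0:
        raise ValidationError("empty pLDDT list")
    if np.any(vals < 0):
        raise ValidationError("negative pLDDT value")
    if float(vals.max()) <= 1.0:
        vals = vals * 100.0
    return [float(v) for v in np.clip(vals, 0.0, 100.0)]


# ---------------------------------------------------------------------------
# Reading

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _prescan_pdb(lines: list[str]) -> tuple[str, str]:
    """Validate ATOM/HETATM coordinate fields and pull header metadata.

    Raises :class:`PDBParseError` naming the offending line for malformed
    coordinate fields, which gemmi would silently tolerate.
    """
    accession = ""
    description_parts: list[str] = []
    n_atom = 0
    for i, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            n_atom += 1
            for lo, hi in _COORD_SLICES:
                fragment = line[lo:hi].strip()
                try:
                    float(fragment)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fragment!r}", line_number=i
                    ) from None
        elif rec == "HEADER":
            m = re.search(r"ACCESSION\s+(\S+)", line)
            if m:
                accession = m.group(1)
        elif rec.startswith("TITLE"):
            description_parts.append(line[10:].rstrip())
    if n_atom == 0:
        raise EmptyModelError("no ATOM or HETATM records in file")
    return accession, " ".join(p for p in description_parts if p).strip()


def read_model(path: str | Path, model_type: str = "alphafold2") -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Protein residues come from ATOM records; HETATM records are grouped by
    (het_id, chain, residue number) into :class:`Ligand` objects.  Waters
    are dropped.  For AI model types the B-factor column is interpreted as
    pLDDT and harmonized to the percent scale.  Only the first MODEL of a
    multi-model file is read.
    """
    path = Path(path)
    if model_type not in MODEL_TYPES:
        raise ValidationError(f"unknown model_type {model_type!r}")
    text = path.read_text()  # propagates OSError for unreadable files
    accession, description = _prescan_pdb(text.splitlines())

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    gmodel = st[0]

    chains: dict[str, list[Residue]] = {}
    ligands: list[Ligand] = []
    for gchain in gmodel:
        cid = gchain.name or "A"
        for gres in gchain:
            resname = gres.name.strip()
            if resname in WATER_CODES:
                continue
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    bfactor=float(ga.b_iso),
                    occupancy=float(ga.occ),
                    is_hetatm=(gres.het_flag == "H"),
                    serial=max(1, int(ga.serial)),
                )
                for ga in gres
            ]
            if not atoms:
                continue
            seq_number = int(gres.seqid.num)
            icode = gres.seqid.icode.strip()
            if gres.het_flag == "H" or resname not in STANDARD_AA:
                ligands.append(
                    Ligand(het_id=resname, chain_id=cid, seq_number=seq_number, atoms=atoms)
                )
            else:
                chains.setdefault(cid, []).append(
                    Residue(
                        chain_id=cid,
                        seq_number=seq_number,
                        res_name=resname,
                        atoms=atoms,
                        insertion_code=icode,
                    )
                )

    model = StructureModel(
        accession=accession,
        description=description,
        model_type=model_type,
        chains=chains,
        ligands=ligands,
    )
    if model_type in AI_MODEL_TYPES:
        if len(model.chains) > 1:
            # AI predictors used here emit single-chain monomers
            raise ValidationError(
                f"{path}: AI model has {len(model.chains)} protein chains; expected 1"
            )
        _assign_plddt(model)
    return model


def _assign_plddt(model: StructureModel) -> None:
    """Set per-residue pLDDT from atom B-factors, harmonizing the scale."""
    residues = list(model.residues())
    if not residues:
        return
    raw = [res.atoms[0].bfactor for res in residues]
    harmonized = harmonize_plddt_scale(raw)
    for res, val in zip(residues, harmonized):
        res.plddt = val
        for a in res.atoms:
            a.bfactor = val


# ---------------------------------------------------------------------------
# Writing


def _format_atom_name(name: str) -> str:
    # Standard PDB convention: element right-aligned in cols 13-14 for
    # short names; 4-character names fill the whole field.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def _atom_record(rec: str, atom: Atom, res_name: str, chain_id: str,
                 seq_number: int, icode: str, serial: int) -> str:
    x, y, z = atom.coords
    return (
        f"{rec:<6}{serial:>5} {_format_atom_name(atom.name)} "
        f"{res_name:>3} {chain_id[:1]}{seq_number:>4}{(icode or ' '):1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element[:2].upper():>2}"
    )


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a model to PDB format.

    The HEADER carries the UniProt accession and TITLE the description;
    coordinates are written at the standard 3-decimal precision and
    B-factors (pLDDT for AI models) at 2 decimals.  HETATM records follow
    all ATOM records.
    """
    path = Path(path)
    lines: list[str] = []
    header = f"HEADER    PROTEIN STRUCTURE MODEL; ACCESSION {model.accession}"
    lines.append(header[:80])
    if model.description:
        desc = model.description
        cont = 0
        while desc:
            cont += 1
            prefix = "TITLE     " if cont == 1 else f"TITLE   {cont:>2} "
            lines.append(prefix + desc[:69])
            desc = desc[69:]
    serial = 0
    for cid, chain in model.chains.items():
        for res in chain:
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _atom_record("ATOM", atom, res.res_name, cid,
                                 res.seq_number, res.insertion_code, serial)
                )
        if chain:
            serial += 1
            last = chain[-1]
            lines.append(
                f"TER   {serial:>5}      {last.res_name:>3} "
                f"{cid[:1]}{last.seq_number:>4}"
            )
    for lig in model.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(
                _atom_record("HETATM", atom, lig.het_id, lig.chain_id,
                             lig.seq_number, "", serial)
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dataset file naming


def dataset_filename(model_type: str, accession: str, stage: str) -> str:
    """File name for one model at one refinement stage of the dataset.

    Stages follow the deposited-dataset layout: ``native`` ->
    ``[ModelType]_[accession].pdb``, ``refined`` ->
    ``refined_[ModelType]_[accession].pdb``, ligand-integrated stages carry
    a ``ligand_integrated_`` prefix, and homology models are
    ``HM_[accession].pdb``.
    """
    if not accession:
        raise ValidationError("accession must be non-empty")
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if stage == "homology":
        return f"HM_{accession}.pdb"
    if model_type not in MODEL_TYPE_TOKEN:
        raise ValidationError(f"stage {stage!r} requires an AI model type, got {model_type!r}")
    token = MODEL_TYPE_TOKEN[model_type]
    patterns = {
        "native": f"{token}_{accession}.pdb",
        "relaxed": f"relaxed_{token}_{accession}.pdb",
        "refined": f"refined_{token}_{accession}.pdb",
        "relaxed_ligand": f"ligand_integrated_relaxed_{token}_{accession}.pdb",
        "refined_ligand": f"ligand_integrated_refined_{token}_{accession}.pdb",
    }
    return patterns[stage]
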