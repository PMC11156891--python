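"""Deterministic synthetic structures for testing and demonstration.

Everything the pipeline consumes can be generated here: poly-alanine
chains with exact backbone torsions (ideal helices, extended strands),
models with prescribed pLDDT profiles and rigidly displaced segments at
known distances, and donor/acceptor pairs with pseudo-ligands whose
expected post-transplant coordinates are computed by direct geometry,
independent of the modules under test.

Chains are built atom-by-atom with the natural extension reference frame
(NeRF) construction, so the requested (phi, psi) torsions hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .model_io import Atom, Ligand, Residue, StructureModel

# Canonical backbone internal coordinates (A / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -135.0, 135.0


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) and
    torsion(A,B,C,D) as requested."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_chain(
    n: int,
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
    omega: float = 180.0,
    plddt: float = 90.0,
    chain_id: str = "A",
    accession: str = "TEST00001",
    model_type: str = "alphafold2",
) -> StructureModel:
    """Poly-alanine backbone (N, CA, C, O) with exact uniform torsions."""
    if n < 2:
        raise ValidationError("chain needs at least 2 residues")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[-1]
        ni = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        cai = place_atom(prev["CA"], prev["C"], ni, BOND_N_CA, ANGLE_C_N_CA, omega)
        ci = place_atom(prev["C"], ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": ni, "CA": cai, "C": ci})
    # carbonyl oxygens: dihedral N-CA-C-O = psi + 180 (trans to the next N)
    for res in coords:
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O,
                              ANGLE_CA_C_O, psi + 180.0)

    serial = 0
    residues = []
    for i, res in enumerate(coords, start=1):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(name=name, element=name[0], coords=res[name],
                              bfactor=plddt, serial=serial))
        residues.append(Residue(chain_id=chain_id, seq_number=i, res_name="ALA",
                                atoms=atoms, plddt=plddt))
    return StructureModel(
        accession=accession,
        description="synthetic poly-alanine test chain",
        model_type=model_type,
        chains={chain_id: residues},
    )


def make_helix(n: int, **kwargs) -> StructureModel:
    """Ideal right-handed alpha-helix (phi = -57, psi = -47)."""
    return make_chain(n, phi=HELIX_PHI, psi=HELIX_PSI, **kwargs)


def make_extended(n: int, phi: float = STRAND_PHI, psi: float = STRAND_PSI,
                  **kwargs) -> StructureModel:
    """Extended beta-strand-like chain (default phi = -135, psi = 135)."""
    return make_chain(n, phi=phi, psi=psi, **kwargs)


# ---------------------------------------------------------------------------
# pLDDT profiles


def profile_constant(n: int, value: float = 90.0) -> list[float]:
    return [value] * n


def profile_two_lobe_low_linker(
    n_lobe: int = 26, n_linker: int = 8, high: float = 90.0, low: float = 50.0
) -> list[float]:
    """Two confident lobes joined by a low-confidence linker."""
    return [high] * n_lobe + [low] * n_linker + [high] * n_lobe


def profile_ramp(n: int, start: float = 40.0, stop: float = 95.0) -> list[float]:
    return list(np.linspace(start, stop, n))


_NAMED_PROFILES = {
    "constant": lambda n: profile_constant(n),
    "two_lobe_low_linker": lambda n: _two_lobe_for(n),
    "ramp": lambda n: profile_ramp(n),
}


def _two_lobe_for(n: int) -> list[float]:
    n_linker = max(4, n // 6)
    n_lobe = (n - n_linker) // 2
    prof = profile_two_lobe_low_linker(n_lobe, n_linker)
    return prof + [90.0] * (n - len(prof))


@dataclass
class FixtureSpec:
    """Declarative description of a trimming/transplant test structure."""

    n_residues: int = 60
    plddt_profile: list[float] | str = "constant"
    segment_offsets: list[tuple[tuple[int, int], tuple[float, float, float]]] = field(
        default_factory=list
    )  # ((start, end) 0-based inclusive, translation vector in A)
    ligand_placements: list[tuple[int, tuple[float, float, float], int]] = field(
        default_factory=list
    )  # (anchor residue index, offset from its CA, n_atoms)
    seed: int = 42


def resolve_profile(spec: FixtureSpec) -> list[float]:
    if isinstance(spec.plddt_profile, str):
        try:
            return _NAMED_PROFILES[spec.plddt_profile](spec.n_residues)
        except KeyError:
            raise ValidationError(f"unknown profile {spec.plddt_profile!r}") from None
    profile = list(spec.plddt_profile)
    if len(profile) != spec.n_residues:
        raise ValidationError("profile length must equal n_residues")
    return profile


def make_trim_fixture(spec: FixtureSpec) -> StructureModel:
    """Helix with a prescribed pLDDT profile and rigidly displaced ranges.

    Displacing residue ranges creates detached segments whose distances to
    the rest of the chain are controlled by the offset vectors; ground
    truths for geometric tests should be recomputed with
    :func:`min_interatomic_distance` (direct geometry, no trim-module code).
    """
    profile = resolve_profile(spec)
    model = make_helix(spec.n_residues, accession=f"FIX{spec.seed:05d}")
    residues = model.chain()
    covered: set[int] = set()
    for (start, end), offset in spec.segment_offsets:
        if not (0 <= start <= end < spec.n_residues):
            raise ValidationError(f"range ({start}, {end}) out of bounds")
        rng_set = set(range(start, end + 1))
        if rng_set & covered:
            raise ValidationError("segment offset ranges overlap")
        covered |= rng_set
        vec = np.asarray(offset, float)
        for i in rng_set:
            for a in residues[i].atoms:
                a.coords = a.coords + vec
    for res, val in zip(residues, profile):
        res.plddt = float(val)
        for a in res.atoms:
            a.bfactor = float(val)
    for anchor, offset, k in spec.ligand_placements:
        model.ligands.append(_make_ligand(residues[anchor], offset, k,
                                          seq_number=1000 + anchor))
    return model


# ---------------------------------------------------------------------------
# Pseudo-ligands and donor pairs

# Fixed 10-point rigid cluster template (A), roughly globular, ~2.8 A wide.
_LIGAND_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.4, 0.0, 0.0],
    [0.0, 1.4, 0.0],
    [0.0, 0.0, 1.4],
    [1.0, 1.0, 0.2],
    [1.0, 0.2, 1.0],
    [0.2, 1.0, 1.0],
    [0.9, 0.9, 0.9],
    [1.8, 0.9, 0.4],
    [0.4, 1.8, 0.9],
])


def _make_ligand(anchor: Residue, offset, n_atoms: int, het_id: str = "LIG",
                 chain_id: str = "A", seq_number: int = 900) -> Ligand:
    if not (1 <= n_atoms <= len(_LIGAND_TEMPLATE)):
        raise ValidationError(f"n_atoms must be in [1, {len(_LIGAND_TEMPLATE)}]")
    ca = anchor.atom("CA")
    if ca is None:
        raise ValidationError("anchor residue has no CA atom")
    base = ca.coords + np.asarray(offset, float)
    atoms = [
        Atom(name=f"C{i+1}", element="C", coords=base + pt, bfactor=0.0,
             is_hetatm=True, serial=9000 + i)
        for i, pt in enumerate(_LIGAND_TEMPLATE[:n_atoms])
    ]
    return Ligand(het_id=het_id, chain_id=chain_id, seq_number=seq_number, atoms=atoms)


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random proper rotation plus a bounded random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


def make_donor_pair(
    n_residues: int = 40,
    ligand_specs: list[tuple[int, tuple[float, float, float], int]] | None = None,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
    truncate: tuple[int, int] | None = None,
    second_chain: bool = False,
    second_chain_ligands: int = 0,
    het_id: str = "LIG",
    require_no_clash: bool = True,
    accession: str = "TESTPAIR1",
) -> tuple[StructureModel, StructureModel, list[np.ndarray]]:
    """Build an (AI model, homology donor, ground truth) triple.

    The donor is a copy of the AI model, optionally rigidly transformed,
    truncated to a residue range, or duplicated into a second chain.
    Ligands are placed at offsets from anchor CA atoms *in the AI frame*;
    the donor carries their transform image, so the expected post-transplant
    coordinates (the returned ground truths) are exactly the AI-frame
    placements — computed here by direct geometry.
    """
    ai = make_helix(n_residues, accession=accession)
    residues = ai.chain()
    if ligand_specs is None:
        # default: one 6-atom ligand 5 A radially outward from the middle
        # residue's CA, guaranteed clear of the backbone
        anchor = n_residues // 2
        ca = residues[anchor].atom("CA").coords
        outward = ca - ai.protein_coords().mean(axis=0)
        if np.linalg.norm(outward) < 1e-6:
            outward = np.array([1.0, 0.0, 0.0])
        outward = 5.0 * outward / np.linalg.norm(outward)
        ligand_specs = [(anchor, tuple(outward), 6)]

    ground_truth: list[np.ndarray] = []
    ai_frame_ligands = []
    for anchor, offset, k in ligand_specs:
        lig = _make_ligand(residues[anchor], offset, k, het_id=het_id,
                           seq_number=500 + anchor)
        ai_frame_ligands.append(lig)
        ground_truth.append(lig.coords_array(heavy_only=False).copy())

    if require_no_clash:
        protein = ai.protein_coords()
        for lig in ai_frame_ligands:
            if float(cdist(lig.coords_array(), protein).min()) < 2.0:
                raise ValidationError(
                    f"requested non-clashing fixture but ligand at anchor clashes"
                )

    donor = ai.copy()
    donor.model_type = "homology"
    if truncate is not None:
        start, end = truncate
        donor.chains = {"A": donor.chain()[start:end + 1]}
    donor.ligands = [l for l in (_copy_ligand(l) for l in ai_frame_ligands)]
    if transform is not None:
        R, t = transform
        donor = donor.transformed(R, t)

    if second_chain:
        shift = np.array([80.0, 0.0, 0.0])
        chain_b = []
        for res in donor.chain("A"):
            r2 = Residue(chain_id="B", seq_number=res.seq_number,
                         res_name=res.res_name, insertion_code=res.insertion_code,
                         atoms=[Atom(name=a.name, element=a.element,
                                     coords=a.coords + shift, bfactor=a.bfactor,
                                     occupancy=a.occupancy, is_hetatm=a.is_hetatm,
                                     serial=a.serial) for a in res.atoms],
                         plddt=res.plddt)
            chain_b.append(r2)
        donor.chains["B"] = chain_b
        anchors_b = np.linspace(5, max(6, len(chain_b) - 5), second_chain_ligands).astype(int)
        for j, anchor in enumerate(anchors_b):
            donor.ligands.append(
                _make_ligand(chain_b[int(anchor)], (5.0, 0.0, 0.0), 5,
                             het_id=het_id, chain_id="B", seq_number=700 + j)
            )
    return ai, donor, ground_truth


def _copy_ligand(lig: Ligand) -> Ligand:
    return Ligand(
        het_id=lig.het_id, chain_id=lig.chain_id, seq_number=lig.seq_number,
        atoms=[Atom(name=a.name, element=a.element, coords=a.coords.copy(),
                    bfactor=a.bfactor, occupancy=a.occupancy,
                    is_hetatm=True, serial=a.serial) for a in lig.atoms],
    )


def min_interatomic_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Brute-force minimum pairwise distance; the geometric oracle used to
    derive ground truths, independent of the trimming module."""
    return float(cdist(np.asarray(coords_a, float), np.asarray(coords_b, float)).min())
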