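"""Rigid-body superposition: Kabsch fits and correspondence builders.

Two ways of pairing residues between a mobile and a reference chain are
provided, mirroring the two alignment modes commonly alternated in
structure-alignment tools: a sequence-guided mode (global pairwise sequence
alignment, then an iterative outlier-rejecting least-squares fit) and a
structure-guided mode (a geometry-seeded mutual-nearest-neighbour pairing
that ignores residue identities).  Both produce a :class:`Correspondence`
that :func:`kabsch_fit` / :func:`refine_fit` turn into a rigid transform
with an RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import CorrespondenceError, FitError, SiteTooSmallError, ValidationError
from .model_io import Ligand, Residue, StructureModel


@dataclass
class SuperpositionResult:
    """A proper rigid transform ``x -> R x + t`` with its fit statistics."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    strategy_label: str = "kabsch"
    metadata: dict = field(default_factory=dict)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "SuperpositionResult":
        Rinv = self.rotation.T
        return SuperpositionResult(
            rotation=Rinv,
            translation=-Rinv @ self.translation,
            rmsd=self.rmsd,
            n_pairs=self.n_pairs,
            strategy_label=self.strategy_label + ":inverse",
            metadata=dict(self.metadata),
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_pairs": self.n_pairs,
            "strategy_label": self.strategy_label,
        }


@dataclass
class Correspondence:
    """Matched residue pairs between a mobile and a reference chain."""

    pairs: list[tuple[Residue, Residue]]
    atom_rule: str = "CA"

    def __post_init__(self):
        if len({id(m) for m, _ in self.pairs}) != len(self.pairs) or len(
            {id(r) for _, r in self.pairs}
        ) != len(self.pairs):
            raise ValidationError("correspondence pairs must be unique in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        mob, ref = [], []
        for m, r in self.pairs:
            am, ar = m.atom(self.atom_rule), r.atom(self.atom_rule)
            if am is None or ar is None:
                continue
            mob.append(am.coords)
            ref.append(ar.coords)
        return (
            np.array(mob, dtype=float).reshape(-1, 3),
            np.array(ref, dtype=float).reshape(-1, 3),
        )

    def subset(self, keep: np.ndarray) -> "Correspondence":
        return Correspondence(
            [p for p, k in zip(self.pairs, keep) if k], atom_rule=self.atom_rule
        )


# ---------------------------------------------------------------------------
# Kabsch fit


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               strategy_label: str = "kabsch") -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch).

    Solves for the proper rotation R and translation t minimizing
    ``RMSD(R @ mobile + t, reference)`` via SVD of the cross-covariance,
    with the determinant correction that excludes reflections.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise FitError("point sets must be equal-length (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise FitError(f"need >= 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise FitError("degenerate (collinear) point configuration")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_pairs=n, strategy_label=strategy_label)


def refine_fit(correspondence: Correspondence, max_cycles: int = 5,
               reject_sd: float = 2.0,
               strategy_label: str = "refined") -> SuperpositionResult:
    """Iterative Kabsch fit with outlier rejection.

    Each cycle fits, then drops pairs whose deviation exceeds
    ``mean + reject_sd * sd`` of the per-pair deviations, and refits.
    Stops when nothing is dropped, ``max_cycles`` is reached, or fewer than
    3 pairs would remain.  Returns the lowest-RMSD fit seen, so the reported
    RMSD never exceeds that of the unrefined fit.
    """
    corr = correspondence
    best: SuperpositionResult | None = None
    for _ in range(max(1, max_cycles)):
        mob, ref = corr.coords()
        if mob.shape[0] < 3:
            if best is not None:
                return best
            raise FitError("fewer than 3 usable pairs")
        res = kabsch_fit(mob, ref, strategy_label=strategy_label)
        res.metadata["n_pairs_used"] = res.n_pairs
        if best is None or res.rmsd <= best.rmsd:
            best = res
        dev = np.linalg.norm(res.apply(mob) - ref, axis=1)
        if dev.max() < 1e-6:  # converged; don't reject numerical noise
            break
        cut = dev.mean() + reject_sd * dev.std()
        keep = dev <= cut
        if keep.all() or keep.sum() < 3:
            break
        corr = corr.subset(keep)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Correspondence builders

_aligner_cache: dict[str, Align.PairwiseAligner] = {}


def _blosum_aligner() -> Align.PairwiseAligner:
    if "blosum62" not in _aligner_cache:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _aligner_cache["blosum62"] = aligner
    return _aligner_cache["blosum62"]


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Global BLOSUM62 alignment score between two one-letter sequences."""
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    return float(_blosum_aligner().score(seq_a, seq_b))


def seq_guided_correspondence(
    mobile_chain: list[Residue], reference_chain: list[Residue]
) -> Correspondence:
    """Pair residues via a global BLOSUM62 sequence alignment.

    Aligned, non-gap positions with a CA atom on both sides become pairs.
    """
    if not mobile_chain or not reference_chain:
        raise CorrespondenceError("both chains must be non-empty")
    seq_m = "".join(r.one_letter for r in mobile_chain)
    seq_r = "".join(r.one_letter for r in reference_chain)
    alignment = _blosum_aligner().align(seq_m, seq_r)[0]
    pairs: list[tuple[Residue, Residue]] = []
    for (ms, me), (rs, re_) in zip(*alignment.aligned):
        for im, ir in zip(range(ms, me), range(rs, re_)):
            m, r = mobile_chain[im], reference_chain[ir]
            if m.atom("CA") is not None and r.atom("CA") is not None:
                pairs.append((m, r))
    if not pairs:
        raise CorrespondenceError("alignment produced no usable residue pairs")
    return Correspondence(pairs)


def _ca_coords(chain: list[Residue]) -> tuple[np.ndarray, list[int]]:
    pts, idx = [], []
    for i, res in enumerate(chain):
        ca = res.atom("CA")
        if ca is not None:
            pts.append(ca.coords)
            idx.append(i)
    return np.array(pts, dtype=float).reshape(-1, 3), idx


def _mutual_nn_pairs(mob: np.ndarray, ref: np.ndarray, cap: float) -> list[tuple[int, int]]:
    from scipy.spatial import cKDTree

    tree_r = cKDTree(ref)
    tree_m = cKDTree(mob)
    d_mr, j_mr = tree_r.query(mob)
    _, i_rm = tree_m.query(ref)
    out = []
    for i, (d, j) in enumerate(zip(d_mr, j_mr)):
        if d <= cap and i_rm[j] == i:
            out.append((i, j))
    return out


def structure_guided_correspondence(
    mobile_chain: list[Residue],
    reference_chain: list[Residue],
    distance_cap: float = 5.0,
    fragment_length: int = 8,
    seed_stride: int = 4,
) -> Correspondence:
    """Pair residues by backbone geometry alone (sequence-independent).

    A coarse search over CA fragments of both chains seeds a rigid fit;
    residues are then paired by mutual-nearest-neighbour CA proximity under
    ``distance_cap`` and the pairing is re-grown over a few fit/re-pair
    cycles.  Residue identities are never consulted.
    """
    mob_xyz, mob_idx = _ca_coords(mobile_chain)
    ref_xyz, ref_idx = _ca_coords(reference_chain)
    if mob_xyz.shape[0] < 3 or ref_xyz.shape[0] < 3:
        raise CorrespondenceError("both chains need >= 3 CA atoms")

    w = min(fragment_length, mob_xyz.shape[0], ref_xyz.shape[0])
    best_seed: SuperpositionResult | None = None
    best_support = -1
    mob_starts = list(range(0, mob_xyz.shape[0] - w + 1, seed_stride)) or [0]
    ref_starts = list(range(0, ref_xyz.shape[0] - w + 1, seed_stride)) or [0]
    for i0 in mob_starts:
        frag_m = mob_xyz[i0:i0 + w]
        for j0 in ref_starts:
            frag_r = ref_xyz[j0:j0 + w]
            try:
                fit = kabsch_fit(frag_m, frag_r)
            except FitError:
                continue
            moved = fit.apply(mob_xyz)
            support = len(_mutual_nn_pairs(moved, ref_xyz, distance_cap))
            if support > best_support or (
                support == best_support and best_seed is not None
                and fit.rmsd < best_seed.rmsd
            ):
                best_support, best_seed = support, fit
    if best_seed is None or best_support < 3:
        raise CorrespondenceError("no seed fragment match between the chains")

    # grow the pairing: fit on current pairs, re-pair, repeat to stability
    fit = best_seed
    pairs_idx: list[tuple[int, int]] = []
    for _ in range(3):
        moved = fit.apply(mob_xyz)
        new_pairs = _mutual_nn_pairs(moved, ref_xyz, distance_cap)
        if len(new_pairs) < 3:
            break
        if new_pairs == pairs_idx:
            break
        pairs_idx = new_pairs
        fit = kabsch_fit(mob_xyz[[i for i, _ in pairs_idx]],
                         ref_xyz[[j for _, j in pairs_idx]])
    if len(pairs_idx) < 3:
        raise CorrespondenceError("mutual-nearest-neighbour pairing too small")
    return Correspondence(
        [(mobile_chain[mob_idx[i]], reference_chain[ref_idx[j]]) for i, j in pairs_idx]
    )


# ---------------------------------------------------------------------------
# Local (binding-site) superposition


def local_site_superpose(
    mobile: StructureModel,
    reference_chain: list[Residue],
    ligand: Ligand,
    radius: float,
    strategy: str = "sequence",
    max_cycles: int = 5,
    reject_sd: float = 2.0,
) -> SuperpositionResult:
    """Superpose the mobile model onto the reference binding-site region.

    The correspondence (sequence- or structure-guided, over the full
    chains) is restricted to reference residues having at least one atom
    within ``radius`` of any ligand atom; at least 3 such pairs are
    required, else :class:`SiteTooSmallError`.  The restricted pair set is
    fitted with outlier rejection.  The returned transform maps mobile
    coordinates into the reference frame.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if strategy not in ("sequence", "structure"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    mobile_chain = mobile.chain()
    if strategy == "sequence":
        corr = seq_guided_correspondence(mobile_chain, reference_chain)
    else:
        corr = structure_guided_correspondence(mobile_chain, reference_chain)

    lig_xyz = ligand.coords_array(heavy_only=False)
    site_ids = set()
    from scipy.spatial import cKDTree

    tree = cKDTree(lig_xyz)
    for res in reference_chain:
        xyz = res.coords_array(heavy_only=False)
        if xyz.size and float(tree.query(xyz)[0].min()) <= radius:
            site_ids.add(id(res))

    site_pairs = [(m, r) for m, r in corr.pairs if id(r) in site_ids]
    label = f"{strategy}@{radius:g}"
    if len(site_pairs) < 3:
        raise SiteTooSmallError(
            f"{label}: only {len(site_pairs)} paired residues within {radius} A of {ligand.het_id}"
        )
    result = refine_fit(Correspondence(site_pairs), max_cycles=max_cycles,
                        reject_sd=reject_sd, strategy_label=label)
    result.metadata["n_site_residues"] = len(site_pairs)
    return result
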