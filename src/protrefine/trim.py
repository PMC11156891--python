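"""Removal of low-confidence regions from AI-predicted models.

Two criteria are composed.  First, residues whose pLDDT, averaged over a
window of +/- 3 neighbours, falls below 70 are flagged.  Second, the
surviving runs of consecutive residues ("segments") are screened
geometrically: the largest segment is taken as the protein core, and any
other segment is removed unless it lies within 10 A of the core, or within
5 A of a segment that itself lies within 10 A of the core (one hop).
Models left with fewer than 10 residues are dropped entirely, and ligands
no longer within 5 A of any protein atom are discarded.

Trimming is pure deletion: no retained coordinate is ever modified, and
window averages are computed once on the intact chain, so trimming is
idempotent on the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .model_io import Residue, StructureModel


@dataclass
class TrimPolicy:
    """Thresholds of the trimming procedure (defaults as published)."""

    window_halfwidth: int = 3          # residues averaged on each side
    plddt_threshold: float = 70.0      # strict: average < threshold flags
    core_distance: float = 10.0        # A, segment-to-core retention limit
    chain_distance: float = 5.0        # A, segment-to-bridge retention limit
    min_residues: int = 10             # survivors below this drop the model
    ligand_retention_distance: float = 5.0  # A, ligand-to-protein limit
    distance_atoms: str = "all"        # "all" heavy atoms or "ca" only

    def __post_init__(self):
        if self.window_halfwidth < 0:
            raise ValidationError("window_halfwidth must be >= 0")
        if not (0.0 < self.plddt_threshold < 100.0):
            raise ValidationError("plddt_threshold must be in (0, 100)")
        for name in ("core_distance", "chain_distance", "ligand_retention_distance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_residues < 1:
            raise ValidationError("min_residues must be >= 1")
        if self.distance_atoms not in ("all", "ca"):
            raise ValidationError("distance_atoms must be 'all' or 'ca'")


@dataclass
class Segment:
    """A maximal run of consecutive retained residues within one chain.

    Indices refer to the original residue ordering of the model (0-based,
    inclusive), so the segment's position is stable even after removal of
    other residues.
    """

    chain_id: str
    start_index: int
    end_index: int
    residues: list[Residue]

    def __post_init__(self):
        if self.start_index > self.end_index:
            raise ValidationError("segment start must not exceed end")
        if len(self.residues) != self.end_index - self.start_index + 1:
            raise ValidationError("segment residues must be consecutive")

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atoms: str = "all") -> np.ndarray:
        if atoms == "ca":
            pts = [r.atom("CA").coords for r in self.residues if r.atom("CA") is not None]
            return np.array(pts, dtype=float).reshape(-1, 3)
        return np.vstack([r.coords_array() for r in self.residues])


@dataclass
class TrimReport:
    removed_by_plddt: list[tuple[str, int, str]] = field(default_factory=list)
    removed_by_geometry: list[tuple[str, int, str]] = field(default_factory=list)
    segments_kept: list[Segment] = field(default_factory=list)
    model_dropped: bool = False
    ligands_dropped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_by_plddt": [list(k) for k in self.removed_by_plddt],
            "removed_by_geometry": [list(k) for k in self.removed_by_geometry],
            "segments_kept": [
                {"chain_id": s.chain_id, "start_index": s.start_index,
                 "end_index": s.end_index, "n_residues": len(s)}
                for s in self.segments_kept
            ],
            "model_dropped": self.model_dropped,
            "ligands_dropped": self.ligands_dropped,
        }


def window_average_plddt(plddt, halfwidth: int) -> np.ndarray:
    """Mean pLDDT over a +/- ``halfwidth`` residue window, truncated at the
    chain termini: out[i] = mean(plddt[max(0, i-h) : i+h+1])."""
    vals = np.asarray(plddt, dtype=float)
    if vals.size == 0:
        raise ValidationError("empty pLDDT profile")
    n = vals.size
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - halfwidth)
    hi = np.minimum(n - 1, idx + halfwidth)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def flag_low_confidence(window_avgs, threshold: float) -> np.ndarray:
    """Removal mask: True where the window average is strictly below the
    threshold.  A residue exactly at the threshold is retained."""
    return np.asarray(window_avgs, dtype=float) < threshold


def segment_partition(model: StructureModel, mask) -> list[Segment]:
    """Maximal runs of consecutive retained residues, split at flagged
    residues and at chain boundaries.  ``mask`` is aligned with the model's
    residue ordering (True = remove)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != model.n_residues:
        raise ValidationError("mask length does not match residue count")
    segments: list[Segment] = []
    offset = 0
    for cid, chain in model.chains.items():
        run: list[Residue] = []
        run_start = 0
        for j, res in enumerate(chain):
            gidx = offset + j
            if mask[gidx]:
                if run:
                    segments.append(Segment(cid, run_start, offset + j - 1, run))
                    run = []
            else:
                if not run:
                    run_start = gidx
                run.append(res)
        if run:
            segments.append(Segment(cid, run_start, offset + len(chain) - 1, run))
        offset += len(chain)
    return segments


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return np.inf
    return float(cdist(a, b).min())


def geometric_prune(
    segments: list[Segment], policy: TrimPolicy | None = None
) -> tuple[list[Segment], list[Segment]]:
    """Drop retained segments that are spatially detached from the core.

    The core is the segment with the most residues (ties: lowest start
    index).  A non-core segment survives iff its minimum inter-atomic
    distance to the core is <= ``core_distance``, or it lies within
    ``chain_distance`` of some other segment whose own distance to the core
    is <= ``core_distance``.  The bridging rule is applied for exactly one
    hop, not iterated.
    """
    policy = policy or TrimPolicy()
    if not segments:
        raise ValidationError("geometric_prune requires at least one segment")
    core = min(segments, key=lambda s: (-len(s), s.start_index))
    atoms = policy.distance_atoms
    core_xyz = core.coords(atoms)
    others = [s for s in segments if s is not core]
    d_core = {id(s): _min_distance(s.coords(atoms), core_xyz) for s in others}
    anchored = [s for s in others if d_core[id(s)] <= policy.core_distance]
    kept, removed = [core], []
    for seg in others:
        if d_core[id(seg)] <= policy.core_distance:
            kept.append(seg)
            continue
        xyz = seg.coords(atoms)
        if any(
            _min_distance(xyz, bridge.coords(atoms)) <= policy.chain_distance
            for bridge in anchored
            if bridge is not seg
        ):
            kept.append(seg)
        else:
            removed.append(seg)
    kept.sort(key=lambda s: s.start_index)
    return kept, removed


def ligand_retention_filter(
    model: StructureModel, policy: TrimPolicy | None = None
) -> StructureModel:
    """Drop ligands no longer within ``ligand_retention_distance`` of any
    protein atom; returns a new model (input untouched)."""
    policy = policy or TrimPolicy()
    out = model.copy()
    if not out.ligands:
        return out
    protein = out.protein_coords()
    out.ligands = [
        lig for lig in out.ligands
        if _min_distance(lig.coords_array(), protein) <= policy.ligand_retention_distance
    ]
    return out


def trim_model(
    model: StructureModel, policy: TrimPolicy | None = None
) -> tuple[StructureModel | None, TrimReport]:
    """Full trimming pass: window-average -> flag -> partition -> geometric
    prune -> survivor-count filter -> ligand retention.

    Returns ``(trimmed_model, report)``; the model is ``None`` (and
    ``report.model_dropped`` True) when fewer than ``min_residues`` residues
    survive.  Window averages are computed once per chain on the intact
    model.
    """
    policy = policy or TrimPolicy()
    report = TrimReport()
    residues = list(model.residues())
    if not residues:
        raise ValidationError("model has no residues")

    mask_parts = []
    for chain in model.chains.values():
        profile = []
        for res in chain:
            if res.plddt is None:
                raise ValidationError(f"residue {res.key} has no pLDDT value")
            profile.append(res.plddt)
        avgs = window_average_plddt(profile, policy.window_halfwidth)
        mask_parts.append(flag_low_confidence(avgs, policy.plddt_threshold))
    mask = np.concatenate(mask_parts)
    report.removed_by_plddt = [residues[i].key for i in np.flatnonzero(mask)]

    segments = segment_partition(model, mask)
    if not segments:
        report.model_dropped = True
        return None, report
    kept, pruned = geometric_prune(segments, policy)
    report.removed_by_geometry = [r.key for s in pruned for r in s.residues]
    report.segments_kept = kept

    n_survivors = sum(len(s) for s in kept)
    if n_survivors < policy.min_residues:
        report.model_dropped = True
        return None, report

    keep_keys = {r.key for s in kept for r in s.residues}
    out = model.copy()
    out.chains = {
        cid: [r for r in chain if r.key in keep_keys]
        for cid, chain in out.chains.items()
    }
    out.chains = {cid: chain for cid, chain in out.chains.items() if chain}
    before = {lig.het_id for lig in out.ligands}
    out = ligand_retention_filter(out, policy)
    report.ligands_dropped = sorted(before - {lig.het_id for lig in out.ligands})
    return out, report
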