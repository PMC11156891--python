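"""Window averaging, segment pruning and the trimming composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from protrefine import fixtures
from protrefine.errors import ValidationError
from protrefine.model_io import Atom, Residue
from protrefine.trim import (
    Segment,
    TrimPolicy,
    flag_low_confidence,
    geometric_prune,
    ligand_retention_filter,
    segment_partition,
    trim_model,
    window_average_plddt,
)


def brute_force_prune(segments, core_distance=10.0, chain_distance=5.0):
    """Independent pruning oracle: exhaustive pairwise atom distances and a
    literal one-hop bridging rule."""
    core = min(segments, key=lambda s: (-len(s), s.start_index))

    def dist(s1, s2):
        return cdist(s1.coords(), s2.coords()).min()

    kept = {id(core)}
    anchored = [s for s in segments if s is not core and dist(s, core) <= core_distance]
    kept |= {id(s) for s in anchored}
    for s in segments:
        if id(s) in kept:
            continue
        for b in anchored:
            if b is not s and dist(s, b) <= chain_distance:
                kept.add(id(s))
                break
    return kept


def random_segments(rng, n_segments):
    """Random small segments (clusters of 1-3 residues, 2-4 atoms each)
    scattered so distances straddle the 5/10 A thresholds."""
    segments = []
    start = 0
    for _ in range(n_segments):
        n_res = int(rng.integers(1, 4))
        center = rng.uniform(-18, 18, size=3)
        residues = []
        for j in range(n_res):
            atoms = [
                Atom(name=f"C{k}", element="C",
                     coords=center + rng.uniform(-1.5, 1.5, size=3),
                     serial=1 + k)
                for k in range(int(rng.integers(2, 5)))
            ]
            residues.append(Residue("A", start + j + 1, "ALA", atoms=atoms))
        segments.append(Segment("A", start, start + n_res - 1, residues))
        start += n_res + 1
    return segments


class TestWindowAverage:
    def test_constant_profile_is_fixed_point(self):
        out = window_average_plddt([80.0] * 11, 3)
        assert np.allclose(out, 80.0)

    def test_interior_window_mean(self):
        # 7-residue window centred on position 4 (1-based): mean = 500/7
        prof = [60, 60, 60, 80, 80, 80, 80]
        out = window_average_plddt(prof, 3)
        assert out[3] == pytest.approx(500 / 7)

    def test_terminal_window_truncated(self):
        prof = [50, 90, 90, 90, 90, 90]
        out = window_average_plddt(prof, 3)
        assert out[0] == pytest.approx((50 + 90 + 90 + 90) / 4)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            window_average_plddt([], 3)

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=60),
        st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_mean(self, prof, h):
        out = window_average_plddt(prof, h)
        n = len(prof)
        naive = [
            np.mean(prof[max(0, i - h): min(n - 1, i + h) + 1]) for i in range(n)
        ]
        assert np.allclose(out, naive)


class TestFlagging:
    def test_strictly_below_threshold_flags(self):
        mask = flag_low_confidence([69.99, 70.0, 70.01, 100.0], 70.0)
        assert list(mask) == [True, False, False, False]


class TestSegmentPartition:
    def test_interior_removal_splits_chain(self, helix30):
        mask = np.zeros(30, dtype=bool)
        mask[4:8] = True  # residues 5-8 (1-based)
        segs = segment_partition(helix30, mask)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 3), (8, 29)]

    def test_nothing_flagged_gives_one_segment_per_chain(self, helix30):
        segs = segment_partition(helix30, np.zeros(30, dtype=bool))
        assert len(segs) == 1 and len(segs[0]) == 30

    def test_everything_flagged_gives_empty_list(self, helix30):
        assert segment_partition(helix30, np.ones(30, dtype=bool)) == []


class TestGeometricPrune:
    def _seg_at(self, offset, n_res=2, start=100):
        base = np.asarray(offset, float)
        residues = [
            Residue("A", start + j, "ALA",
                    atoms=[Atom("CA", "C", base + [j * 3.8, 0, 0], serial=1)])
            for j in range(n_res)
        ]
        return Segment("A", start, start + n_res - 1, residues)

    def _core(self):
        return self._seg_at((0, 0, 0), n_res=5, start=0)

    def test_far_segment_removed(self):
        kept, removed = geometric_prune([self._core(), self._seg_at((0, 12, 0))])
        assert len(removed) == 1

    def test_one_hop_bridge_retains(self):
        core = self._core()
        bridge = self._seg_at((0, 8, 0), start=50)       # 8 A from core
        far = self._seg_at((0, 12, 0), start=100)        # 12 A from core, 4 A from bridge
        kept, removed = geometric_prune([core, bridge, far])
        assert removed == [] and len(kept) == 3

    def test_single_segment_is_its_own_core(self):
        seg = self._seg_at((0, 0, 0))
        kept, removed = geometric_prune([seg])
        assert kept == [seg] and removed == []

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(20240917)
        policy = TrimPolicy()
        for _ in range(1000):
            segments = random_segments(rng, int(rng.integers(2, 6)))
            kept, removed = geometric_prune(segments, policy)
            expected = brute_force_prune(segments)
            assert {id(s) for s in kept} == expected
            assert {id(s) for s in removed} == {id(s) for s in segments} - expected


class TestTrimModel:
    def test_two_lobe_linker_removed_exactly(self, two_lobe_model):
        out, report = trim_model(two_lobe_model)
        profile = [r.plddt for r in two_lobe_model.residues()]
        avgs = window_average_plddt(profile, 3)
        expected = {i + 1 for i in np.flatnonzero(np.asarray(avgs) < 70.0)}
        assert {k[1] for k in report.removed_by_plddt} == expected
        assert report.removed_by_geometry == []
        assert out.n_residues == 60 - len(expected)

    def test_confident_model_untouched(self, helix30):
        out, report = trim_model(helix30)
        assert out.n_residues == 30
        assert report.removed_by_plddt == [] and report.removed_by_geometry == []

    def test_retained_coordinates_unmodified(self, two_lobe_model):
        before = {
            r.key: r.coords_array().copy() for r in two_lobe_model.residues()
        }
        out, _ = trim_model(two_lobe_model)
        for res in out.residues():
            assert np.array_equal(res.coords_array(), before[res.key])

    def test_every_survivor_meets_threshold_on_original_profile(self, two_lobe_model):
        out, _ = trim_model(two_lobe_model)
        profile = [r.plddt for r in two_lobe_model.residues()]
        avgs = window_average_plddt(profile, 3)
        by_seq = {r.seq_number: avgs[i] for i, r in enumerate(two_lobe_model.residues())}
        for res in out.residues():
            assert by_seq[res.seq_number] >= 70.0

    @pytest.mark.parametrize("n, dropped", [(9, True), (10, False)])
    def test_min_residue_survival_filter(self, n, dropped):
        model = fixtures.make_helix(n)
        out, report = trim_model(model)
        assert report.model_dropped is dropped
        assert (out is None) is dropped

    def test_exactly_at_threshold_retained(self):
        model = fixtures.make_helix(15, plddt=70.0)
        out, report = trim_model(model)
        assert out.n_residues == 15 and report.removed_by_plddt == []

    def test_threshold_monotonicity(self, two_lobe_model):
        sizes = []
        for thr in (50.0, 60.0, 70.0, 80.0, 89.0):
            out, _ = trim_model(two_lobe_model, TrimPolicy(plddt_threshold=thr))
            sizes.append(out.n_residues if out is not None else 0)
        assert sizes == sorted(sizes, reverse=True)

    def test_trim_is_deterministic(self, two_lobe_model):
        out1, rep1 = trim_model(two_lobe_model)
        out2, rep2 = trim_model(two_lobe_model)
        assert rep1.to_dict() == rep2.to_dict()
        assert np.array_equal(out1.protein_coords(), out2.protein_coords())

    def test_missing_plddt_rejected(self, helix30):
        helix30.chain()[5].plddt = None
        with pytest.raises(ValidationError):
            trim_model(helix30)


class TestLigandRetention:
    @pytest.mark.parametrize("gap, survives", [(4.9, True), (6.0, False)])
    def test_distance_boundary(self, gap, survives):
        model = fixtures.make_helix(20)
        protein = model.protein_coords()
        ca = model.chain()[10].atom("CA").coords
        direction = ca - protein.mean(axis=0)
        direction /= np.linalg.norm(direction)

        def gap_at(s):  # direct-geometry oracle for a single-atom ligand
            return fixtures.min_interatomic_distance(
                (ca + s * direction).reshape(1, 3), protein)

        lo, hi = 0.0, 40.0
        for _ in range(60):  # bisect the offset to the exact target gap
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if gap_at(mid) < gap else (lo, mid)
        point = ca + 0.5 * (lo + hi) * direction
        model.ligands.append(
            fixtures._make_ligand(model.chain()[10],
                                  point - ca, 1, seq_number=900))
        assert gap_at(0.5 * (lo + hi)) == pytest.approx(gap, abs=1e-6)
        filtered = ligand_retention_filter(model)
        assert (len(filtered.ligands) == 1) is survives

    def test_no_ligands_is_noop(self, helix30):
        assert ligand_retention_filter(helix30).n_residues == 30
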