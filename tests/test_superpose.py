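"""Kabsch fits, correspondence builders and local-site superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protrefine import fixtures
from protrefine.errors import CorrespondenceError, FitError, SiteTooSmallError
from protrefine.superpose import (
    Correspondence,
    kabsch_fit,
    local_site_superpose,
    refine_fit,
    seq_guided_correspondence,
    structure_guided_correspondence,
)


def rand_points(rng, n=20, scale=5.0):
    return rng.normal(size=(n, 3)) * scale


class TestKabschFit:
    def test_identity_on_identical_sets(self):
        pts = rand_points(np.random.default_rng(1))
        res = kabsch_fit(pts, pts)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0, atol=1e-10)
        assert res.rmsd == pytest.approx(0, abs=1e-10)

    def test_exact_recovery_of_known_rotation(self):
        rng = np.random.default_rng(2)
        pts = rand_points(rng)
        R, t = fixtures.random_rigid_transform(rng)
        res = kabsch_fit(pts, pts @ R.T + t)
        assert np.allclose(res.rotation, R, atol=1e-8)
        assert res.rmsd == pytest.approx(0, abs=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        # independent library cross-check of the optimal rotation
        rng = np.random.default_rng(3)
        pts = rand_points(rng)
        ref = rand_points(rng) * 0.5 + pts
        ours = kabsch_fit(pts, ref)
        rot, scipy_rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), pts - pts.mean(axis=0))
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-8)
        assert ours.rmsd == pytest.approx(scipy_rssd / np.sqrt(len(pts)), rel=1e-6)

    def test_monte_carlo_optimality(self):
        rng = np.random.default_rng(4)
        pts = rand_points(rng)
        ref = pts + rng.normal(size=pts.shape) * 0.8
        best = kabsch_fit(pts, ref).rmsd
        for _ in range(2000):
            R, t = fixtures.random_rigid_transform(rng, max_translation=5.0)
            rmsd = np.sqrt((((pts @ R.T + t) - ref) ** 2).sum() / len(pts))
            assert best <= rmsd + 1e-12

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            res = kabsch_fit(rand_points(rng), rand_points(rng))
            R = res.rotation
            assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(6)
        pts, ref = rand_points(rng), rand_points(rng)
        base = kabsch_fit(pts, ref).rmsd
        for _ in range(10):
            R, t = fixtures.random_rigid_transform(rng)
            assert kabsch_fit(pts @ R.T + t, ref).rmsd == pytest.approx(base, abs=1e-8)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(FitError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(FitError):
            kabsch_fit(line, line)


class TestSeqGuidedCorrespondence:
    def test_identical_sequences_pair_fully(self, helix30):
        other = fixtures.make_helix(30)
        corr = seq_guided_correspondence(helix30.chain(), other.chain())
        assert len(corr) == 30
        assert all(m.seq_number == r.seq_number for m, r in corr.pairs)

    def test_reference_gap_excluded(self, helix30):
        truncated = fixtures.make_helix(30)
        chain = truncated.chain()[:9] + truncated.chain()[20:]  # residues 10-20 missing
        corr = seq_guided_correspondence(helix30.chain(), chain)
        ref_numbers = {r.seq_number for _, r in corr.pairs}
        assert ref_numbers.isdisjoint(set(range(10, 21)))
        assert len(corr) == len(chain)

    def test_unrelated_sequences_still_align(self):
        rng = np.random.default_rng(7)
        # random mutations: alignment exists; quality gating happens later
        a = fixtures.make_helix(50)
        b = fixtures.make_helix(50)
        names = list("GAVLIPFMWSTCYNQDEKRH")
        three = {"G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU"}
        for res in b.chain():
            res.res_name = three[str(rng.choice(list(three)))]
        corr = seq_guided_correspondence(a.chain(), b.chain())
        assert len(corr) >= 3


class TestRefineFit:
    def _corr(self, n=20, displace=None):
        mob = fixtures.make_helix(n)
        ref = fixtures.make_helix(n)
        if displace is not None:
            idx, vec = displace
            for a in mob.chain()[idx].atoms:
                a.coords = a.coords + np.asarray(vec)
        return Correspondence(list(zip(mob.chain(), ref.chain())))

    def test_consistent_pairs_are_fixpoint(self):
        res = refine_fit(self._corr())
        assert res.rmsd == pytest.approx(0, abs=1e-10)
        assert res.n_pairs == 20

    def test_gross_outlier_dropped(self):
        res = refine_fit(self._corr(displace=(10, (25.0, 0, 0))))
        assert res.n_pairs == 19
        assert res.rmsd == pytest.approx(0, abs=1e-6)

    def test_never_worse_than_unrefined(self):
        rng = np.random.default_rng(8)
        corr = self._corr()
        for m, _ in corr.pairs:
            for a in m.atoms:
                a.coords = a.coords + rng.normal(size=3)
        mob, ref = corr.coords()
        unrefined = kabsch_fit(mob, ref).rmsd
        assert refine_fit(corr).rmsd <= unrefined + 1e-12


class TestStructureGuidedCorrespondence:
    def test_sequence_independent_recovery(self, helix30):
        other = fixtures.make_helix(30)
        for res in other.chain():
            res.res_name = "ALA"  # identities must not matter
        corr = structure_guided_correspondence(helix30.chain(), other.chain())
        assert len(corr) == 30
        assert refine_fit(corr).rmsd == pytest.approx(0, abs=1e-8)

    def test_agrees_with_sequence_branch_on_identical_inputs(self, helix30):
        other = fixtures.make_helix(30)
        c_seq = seq_guided_correspondence(helix30.chain(), other.chain())
        c_str = structure_guided_correspondence(helix30.chain(), other.chain())
        pairs_seq = {(m.seq_number, r.seq_number) for m, r in c_seq.pairs}
        pairs_str = {(m.seq_number, r.seq_number) for m, r in c_str.pairs}
        assert pairs_seq == pairs_str
        assert abs(refine_fit(c_seq).rmsd - refine_fit(c_str).rmsd) < 1e-6

    def test_insertion_left_unpaired(self):
        mobile = fixtures.make_chain(35)
        reference = fixtures.make_chain(30)
        # build mobile = reference with a 5-residue kinked insertion at 15
        ref_chain = reference.chain()
        mob_chain = mobile.chain()
        for i, res in enumerate(ref_chain[:15]):
            for a_m, a_r in zip(mob_chain[i].atoms, res.atoms):
                a_m.coords = a_r.coords.copy()
        for j, res in enumerate(ref_chain[15:]):
            for a_m, a_r in zip(mob_chain[20 + j].atoms, res.atoms):
                a_m.coords = a_r.coords.copy()
        for k in range(15, 20):  # the insertion: shifted well off the fold
            for a in mob_chain[k].atoms:
                a.coords = a.coords + np.array([0.0, 25.0, 0.0])
        corr = structure_guided_correspondence(mob_chain, ref_chain)
        mob_paired = {m.seq_number for m, _ in corr.pairs}
        assert mob_paired.isdisjoint(set(range(16, 21)))
        assert len(corr) >= 25

    def test_unrelated_folds_fail_or_fit_poorly(self):
        coil = fixtures.make_chain(30, phi=-75.0, psi=160.0)
        helix = fixtures.make_helix(30)
        try:
            corr = structure_guided_correspondence(helix.chain(), coil.chain())
        except CorrespondenceError:
            return
        assert refine_fit(corr).rmsd > 1.0 or len(corr) < 10


class TestLocalSiteSuperpose:
    def test_self_transplant_site_rmsd_zero(self, donor_pair):
        ai, donor, _ = donor_pair
        res = local_site_superpose(ai, donor.chain("A"), donor.ligands[0],
                                   radius=10.0, strategy="sequence")
        assert res.rmsd == pytest.approx(0, abs=1e-8)
        assert res.strategy_label == "sequence@10"

    def test_rigidly_shifted_site_recovered_locally(self, donor_pair):
        ai, donor, _ = donor_pair
        # shift the whole acceptor: global displacement, local fit absorbs it
        shifted = ai.transformed(np.eye(3), np.array([2.0, 0.0, 0.0]))
        res = local_site_superpose(shifted, donor.chain("A"), donor.ligands[0],
                                   radius=10.0, strategy="sequence")
        assert res.rmsd == pytest.approx(0, abs=1e-8)
        assert np.allclose(res.translation, [-2.0, 0.0, 0.0], atol=1e-8)

    def test_tiny_radius_raises_site_too_small(self, donor_pair):
        ai, donor, _ = donor_pair
        with pytest.raises(SiteTooSmallError):
            local_site_superpose(ai, donor.chain("A"), donor.ligands[0],
                                 radius=0.5, strategy="sequence")
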