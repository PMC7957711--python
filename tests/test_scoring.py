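import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdock import synth
from pepdock.scoring import (DEFAULT_WEIGHTS, TERMS, ConfigError, Pose,
                             ScoringParams, SearchConfig, apply_pose,
                             cluster_poses, decompose_by_residue, dock_rigid,
                             pair_terms, pose_coords, quat_to_matrix,
                             score_complex, surface_distance)
from pepdock.structio import Atom, RegionSpec, Residue, Structure, ligand_rmsd


def _atom(name="C1", element="C", pos=(0, 0, 0), **flags):
    a = Atom(1, name, element, np.array(pos, dtype=float))
    a.xs_radius = {"C": 1.9, "N": 1.8, "O": 1.7}[element]
    a.sasa_radius = 1.7
    for k, v in flags.items():
        setattr(a, k, v)
    return a


def _mono(atoms, chain="A", number=1):
    s = Structure()
    r = Residue(chain, number, "", "LIG")
    r.atoms = list(atoms)
    s.residues.append(r)
    return s


class TestSurfaceDistance:
    def test_cc_touching(self):
        a = _atom(pos=(0, 0, 0))
        b = _atom(pos=(3.8, 0, 0))
        assert surface_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_co_gap(self):
        a = _atom(pos=(0, 0, 0))
        b = _atom(element="O", pos=(5.0, 0, 0))
        assert surface_distance(a, b) == pytest.approx(1.4, abs=1e-12)

    def test_coincident_negative(self):
        a = _atom(pos=(0, 0, 0))
        b = _atom(pos=(0, 0, 0))
        assert surface_distance(a, b) == pytest.approx(-3.8, abs=1e-12)


class TestPairTerms:
    def test_zero_distance(self):
        a, b = _atom(), _atom()
        t = pair_terms(0.0, a, b)
        assert t["gauss1"] == pytest.approx(1.0)
        assert t["repulsion"] == 0.0

    def test_hydrophobic_midpoint(self):
        a = _atom(is_hydrophobic=True)
        b = _atom(is_hydrophobic=True)
        assert pair_terms(1.0, a, b)["hydrophobic"] == pytest.approx(0.5)

    def test_hydrophobic_requires_both(self):
        a = _atom(is_hydrophobic=True)
        b = _atom()
        assert pair_terms(1.0, a, b)["hydrophobic"] == 0.0

    def test_hbond_midpoint(self):
        d = _atom(element="N", is_donor=True)
        a = _atom(element="O", is_acceptor=True)
        assert pair_terms(-0.35, d, a)["hbond"] == pytest.approx(0.5)

    def test_hbond_needs_donor_acceptor(self):
        a, b = _atom(), _atom()
        assert pair_terms(-0.35, a, b)["hbond"] == 0.0

    def test_gauss2_shape(self):
        a, b = _atom(), _atom()
        assert pair_terms(3.0, a, b)["gauss2"] == pytest.approx(1.0)

    def test_repulsion_quadratic(self):
        a, b = _atom(), _atom()
        assert pair_terms(-0.5, a, b)["repulsion"] == pytest.approx(0.25)


class TestScoreComplex:
    def test_hand_computed_cc_pair(self):
        # single hydrophobic C...C at center distance 3.8 (surface distance 0)
        rec = _mono([_atom(pos=(0, 0, 0), is_hydrophobic=True)], chain="A")
        lig = _mono([_atom(pos=(3.8, 0, 0), is_hydrophobic=True)], chain="B")
        expect = (DEFAULT_WEIGHTS["gauss1"] * 1.0
                  + DEFAULT_WEIGHTS["gauss2"] * math.exp(-2.25)
                  + DEFAULT_WEIGHTS["hydrophobic"] * 1.0)
        bd = score_complex(rec, lig)
        assert bd.total == pytest.approx(expect, abs=1e-12)
        assert bd.total == pytest.approx(-0.0712, abs=1e-4)

    def test_beyond_cutoff_zero(self, helix_pair):
        rec, lig = helix_pair
        bd = score_complex(rec, lig)
        assert bd.total == 0.0
        assert bd.per_receptor_residue == {} and bd.per_ligand_residue == {}

    def test_conservation(self, planted):
        _, rec, lig, _ = planted
        bd = score_complex(rec, lig)
        assert sum(bd.per_receptor_residue.values()) == pytest.approx(
            bd.total, abs=1e-9)
        assert sum(bd.per_ligand_residue.values()) == pytest.approx(
            bd.total, abs=1e-9)

    def test_oracle_equivalence_small_random(self):
        # naive double loop over pair_terms is the independent oracle
        rng = np.random.default_rng(42)
        params = ScoringParams()
        for _ in range(20):
            rec = synth.make_peptide("AKA", chain_id="A")
            lig = synth.make_peptide("SE", chain_id="B")
            shift = rng.uniform(4, 12)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for a in lig.atoms():
                a.position = a.position + shift * direction
            expected = 0.0
            for ra in rec.heavy_atoms():
                for la in lig.heavy_atoms():
                    r = np.linalg.norm(ra.position - la.position)
                    if r > params.cutoff:
                        continue
                    t = pair_terms(surface_distance(ra, la), ra, la, params)
                    expected += sum(params.weights[k] * t[k] for k in TERMS)
            got = score_complex(rec, lig, params).total
            assert got == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, planted):
        _, rec, lig, _ = planted
        before = score_complex(rec, lig).total
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        rec2, lig2 = rec.copy(), lig.copy()
        for s in (rec2, lig2):
            for a in s.atoms():
                a.position = R @ a.position + t
        after = score_complex(rec2, lig2).total
        assert after == pytest.approx(before, abs=1e-6)

    def test_monotone_tail(self):
        # two neutral carbons: total decays monotonically to 0 once the
        # surface distance passes every ramp bound and the far gaussian
        # centre (3 Å, i.e. centre distance 6.8 for C-C)
        params = ScoringParams()
        prev = None
        for centre_dist in np.arange(6.85, 7.95, 0.05):
            rec = _mono([_atom(pos=(0, 0, 0))], chain="A")
            lig = _mono([_atom(pos=(centre_dist, 0, 0))], chain="B")
            total = score_complex(rec, lig, params).total
            if prev is not None:
                assert abs(total) <= abs(prev) + 1e-15
            prev = total
        rec = _mono([_atom(pos=(0, 0, 0))], chain="A")
        lig = _mono([_atom(pos=(8.01, 0, 0))], chain="B")
        assert score_complex(rec, lig, params).total == 0.0

    def test_empty_molecule_error(self):
        rec = _mono([_atom()])
        empty = Structure()
        empty.residues.append(Residue("B", 1, "", "LIG"))
        with pytest.raises(ValueError):
            score_complex(rec, empty)


class TestDecompose:
    def test_single_residue_carries_total(self):
        rec = _mono([_atom(pos=(0, 0, 0))], chain="A")
        lig = _mono([_atom(pos=(4.0, 0, 0))], chain="B")
        bd = score_complex(rec, lig)
        dec = decompose_by_residue(bd)
        assert len(dec) == 1
        assert dec[0][1] == pytest.approx(bd.total)

    def test_symmetric_contacts_equal(self):
        a1 = _atom(pos=(0, 0, 0), is_hydrophobic=True)
        a2 = _atom(pos=(0, 10, 0), is_hydrophobic=True)
        rec = Structure()
        for i, a in enumerate((a1, a2), start=1):
            r = Residue("A", i, "", "LIG")
            r.atoms = [a]
            rec.residues.append(r)
        lig = Structure()
        for i, pos in enumerate(((3.8, 0, 0), (3.8, 10, 0)), start=1):
            r = Residue("B", i, "", "LIG")
            r.atoms = [_atom(pos=pos, is_hydrophobic=True)]
            lig.residues.append(r)
        bd = score_complex(rec, lig)
        dec = decompose_by_residue(bd)
        assert dec[0][1] == pytest.approx(dec[1][1])

    def test_ranking_matches_bruteforce(self, planted):
        _, rec, lig, _ = planted
        params = ScoringParams()
        bd = score_complex(rec, lig, params)
        brute = {}
        for rr in rec.residues:
            val = 0.0
            for ra in rr.heavy_atoms():
                for la in lig.heavy_atoms():
                    if np.linalg.norm(ra.position - la.position) > params.cutoff:
                        continue
                    t = pair_terms(surface_distance(ra, la), ra, la, params)
                    val += sum(params.weights[k] * t[k] for k in TERMS)
            if val != 0.0:
                brute[rr.id] = val
        order = [k for k, _ in decompose_by_residue(bd)]
        expected_order = [k for k, _ in sorted(brute.items(),
                                               key=lambda kv: (kv[1], kv[0]))]
        assert order == expected_order
        for k, v in brute.items():
            assert bd.per_receptor_residue[k] == pytest.approx(v, abs=1e-9)

    def test_region_restriction(self, planted):
        _, rec, lig, _ = planted
        bd = score_complex(rec, lig)
        region = RegionSpec(members=[("A", 4)])
        dec = decompose_by_residue(bd, region=region)
        assert all(k == ("A", 4, "") for k, _ in dec)


class TestPoseMath:
    def test_quaternion_normalised(self):
        p = Pose(np.array([2.0, 0, 0, 0]), np.zeros(3))
        assert np.linalg.norm(p.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_identity_pose_is_noop(self, planted):
        _, _, lig, _ = planted
        p = Pose(np.array([1.0, 0, 0, 0]), np.zeros(3))
        moved = apply_pose(lig, p)
        np.testing.assert_allclose(moved.coords(), lig.coords(), atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rotation_matrix_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = quat_to_matrix(q)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestSearchConfig:
    def test_restarts_validation(self):
        with pytest.raises(ConfigError):
            SearchConfig(box_center=np.zeros(3), box_half=np.ones(3),
                         n_restarts=0)

    def test_keep_top_validation(self):
        with pytest.raises(ConfigError):
            SearchConfig(box_center=np.zeros(3), box_half=np.ones(3),
                         keep_top=0)

    def test_box_too_small(self, planted):
        _, rec, lig, _ = planted
        cfg = SearchConfig(box_center=lig.coords().mean(axis=0),
                           box_half=np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ConfigError):
            dock_rigid(rec, lig, cfg)


class TestDockDeterminism:
    def test_same_seed_identical(self, planted):
        _, rec, lig, _ = planted
        cfg = SearchConfig(box_center=lig.coords().mean(axis=0),
                           box_half=np.array([6.0, 6.0, 6.0]),
                           n_restarts=4, n_steps=60, seed=11, keep_top=4,
                           quench=False)
        r1 = dock_rigid(rec, lig, cfg)
        r2 = dock_rigid(rec, lig, cfg)
        assert len(r1) == len(r2)
        for (p1, b1), (p2, b2) in zip(r1, r2):
            np.testing.assert_array_equal(p1.rotation, p2.rotation)
            np.testing.assert_array_equal(p1.translation, p2.translation)
            assert b1.total == b2.total

    def test_different_seed_differs(self, planted):
        _, rec, lig, _ = planted
        base = dict(box_center=lig.coords().mean(axis=0),
                    box_half=np.array([6.0, 6.0, 6.0]),
                    n_restarts=2, n_steps=40, keep_top=2, quench=False)
        r1 = dock_rigid(rec, lig, SearchConfig(seed=1, **base))
        r2 = dock_rigid(rec, lig, SearchConfig(seed=2, **base))
        assert any(
            not np.array_equal(p1.translation, p2.translation)
            for (p1, _), (p2, _) in zip(r1, r2))


class TestClusterPoses:
    def _poses_at(self, lig, offsets):
        return [Pose(np.array([1.0, 0, 0, 0]), np.array(o, dtype=float))
                for o in offsets]

    def test_duplicates_collapse(self, planted):
        _, _, lig, _ = planted
        poses = self._poses_at(lig, [(0, 0, 0)] * 5)
        assert len(cluster_poses(poses, lig, 2.0)) == 1

    def test_distant_poses_kept(self, planted):
        _, _, lig, _ = planted
        poses = self._poses_at(lig, [(0, 0, 0), (10, 0, 0)])
        assert len(cluster_poses(poses, lig, 2.0)) == 2

    def test_chain_spacing_property(self, planted):
        _, _, lig, _ = planted
        poses = self._poses_at(lig, [(i, 0, 0) for i in range(10)])
        kept = cluster_poses(poses, lig, 2.0)
        # brute-force: all survivors pairwise > 2 Å apart
        xyz0 = lig.coords()
        c0 = xyz0.mean(axis=0)
        coords = [pose_coords(xyz0, c0, p) for p in kept]
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                rmsd = np.sqrt(np.mean(np.sum(
                    (coords[i] - coords[j]) ** 2, axis=1)))
                assert rmsd > 2.0
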