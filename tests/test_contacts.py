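import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdock import synth
from pepdock.contacts import (RRCS_INNER, RRCS_OUTER, ContactThresholds,
                              close_contact_residues, detect_hbonds,
                              detect_hydrophobic, detect_pi_cation,
                              detect_salt_bridges, rrcs_aggregate, rrcs_matrix,
                              rrcs_pair)
from pepdock.structio import (Atom, RegionSpec, Residue, SelectionError,
                              Structure, assign_atom_types)


def _single_atom_residue(chain, number, pos, element="C", name="C1"):
    r = Residue(chain, number, "", "LIG")
    a = Atom(1, name, element, np.array(pos, dtype=float))
    a.xs_radius = 1.9
    a.sasa_radius = 1.7
    r.atoms.append(a)
    return r


def _pair_structures(d):
    s1 = Structure()
    s1.residues.append(_single_atom_residue("A", 1, (0, 0, 0)))
    s2 = Structure()
    s2.residues.append(_single_atom_residue("B", 1, (d, 0, 0)))
    return s1, s2


class TestRrcsPair:
    def test_plateau(self):
        a, b = _pair_structures(3.00)
        assert rrcs_pair(a.residues[0], b.residues[0]) == pytest.approx(1.0)

    def test_midramp(self):
        a, b = _pair_structures(3.93)
        assert rrcs_pair(a.residues[0], b.residues[0]) == pytest.approx(
            (4.63 - 3.93) / 1.4)

    def test_zero_beyond_outer(self):
        a, b = _pair_structures(4.63)
        assert rrcs_pair(a.residues[0], b.residues[0]) == 0.0

    def test_continuity_at_knots(self):
        def val(d):
            a, b = _pair_structures(d)
            return rrcs_pair(a.residues[0], b.residues[0])
        eps = 1e-9
        assert abs(val(RRCS_INNER - eps) - val(RRCS_INNER + eps)) < 1e-6
        assert abs(val(RRCS_OUTER - eps) - val(RRCS_OUTER + eps)) < 1e-6

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.5, 6.0), st.floats(0.0, 1.0))
    def test_non_increasing(self, d, delta):
        def val(x):
            a, b = _pair_structures(x)
            return rrcs_pair(a.residues[0], b.residues[0])
        assert val(d + delta) <= val(d) + 1e-12

    def test_sequence_adjacent_rule_excludes_backbone(self):
        pep = synth.make_peptide("AA", chain_id="A")
        r1, r2 = pep.residues
        with_rule = rrcs_pair(r1, r2, seq_adjacent_rule=True)
        without = rrcs_pair(r1, r2, seq_adjacent_rule=False)
        assert without > with_rule  # backbone N/CA/C/O pairs dominate


def _brute_rrcs(ligand, receptor):
    total = {}
    for lr in ligand.residues:
        for rr in receptor.residues:
            s = 0.0
            for a in lr.heavy_atoms():
                for b in rr.heavy_atoms():
                    d = float(np.linalg.norm(a.position - b.position))
                    if d <= RRCS_INNER:
                        s += 1.0
                    elif d < RRCS_OUTER:
                        s += (RRCS_OUTER - d) / 1.4
            if s > 0:
                total[(lr.id, rr.id)] = s
    return total


class TestRrcsMatrix:
    def test_separated_chains_empty(self, helix_pair):
        rec, lig = helix_pair
        m = rrcs_matrix(lig, rec)
        assert m.entries == {}
        assert rrcs_aggregate(m, partition="all") == 0.0

    def test_planted_pairs_exact(self, planted):
        _, rec, lig, gt = planted
        m = rrcs_matrix(lig, rec)
        assert set(m.entries) == gt.rrcs_pairs

    def test_matches_bruteforce(self, planted):
        _, rec, lig, _ = planted
        m = rrcs_matrix(lig, rec)
        brute = _brute_rrcs(lig, rec)
        assert set(m.entries) == set(brute)
        for k, v in brute.items():
            assert m.entries[k] == pytest.approx(v, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_random(self, seed):
        spec = synth.random_planted_spec(seed)
        rec, lig, _ = synth.plant_complex(spec)
        m = rrcs_matrix(lig, rec)
        brute = _brute_rrcs(lig, rec)
        assert set(m.entries) == set(brute)
        for k, v in brute.items():
            assert m.entries[k] == pytest.approx(v, abs=1e-9)

    def test_value_bounded_by_pair_count(self, planted):
        _, rec, lig, _ = planted
        m = rrcs_matrix(lig, rec)
        n_lig = {r.id: len(r.heavy_atoms()) for r in lig.residues}
        n_rec = {r.id: len(r.heavy_atoms()) for r in rec.residues}
        for (li, ri), v in m.entries.items():
            assert 0.0 <= v <= n_lig[li] * n_rec[ri]


class TestRrcsAggregate:
    def test_partition_sums(self, planted):
        _, rec, lig, _ = planted
        m = rrcs_matrix(lig, rec)
        total = rrcs_aggregate(m, partition="all")
        aa = rrcs_aggregate(m, partition="AA")
        gly = rrcs_aggregate(m, partition="glycan")
        assert aa + gly == pytest.approx(total)

    def test_region_column_sum(self, planted):
        _, rec, lig, _ = planted
        m = rrcs_matrix(lig, rec)
        region = RegionSpec(members=[("A", 4)])
        got = rrcs_aggregate(m, region, partition="all", receptor=rec)
        assert got == pytest.approx(m.receptor_column_sum(("A", 4, "")))

    def test_empty_region_raises(self, planted):
        _, rec, lig, _ = planted
        m = rrcs_matrix(lig, rec)
        with pytest.raises(SelectionError):
            rrcs_aggregate(m, RegionSpec(members=[("Z", 1)]), receptor=rec)


def _planted_single(kind, seed_offset=0):
    base = {"salt_bridge": 0, "hbond": 1, "hydrophobic": 2, "pi_cation": 3}
    spec = synth.random_planted_spec(base[kind] + 4 * seed_offset)
    return synth.plant_complex(spec)


class TestDetectHbonds:
    def test_planted_ser_backbone(self):
        spec = synth.SyntheticComplexSpec(
            receptor_sequence="AAAAAAAAAAA", ligand_sequence="AASAA",
            interactions=[synth.PlantedInteraction(
                "hbond", 6, 3, 2.9, receptor_atom="O", ligand_atom="OG")],
            seed=3)
        rec, lig, gt = synth.plant_complex(spec)
        recs = detect_hbonds(lig, rec)
        match = [r for r in recs if r.ligand_atom == "OG"
                 and r.receptor_atom == "O"]
        assert len(match) == 1
        assert match[0].contact_class == "sb"
        assert match[0].distance == pytest.approx(2.9, abs=1e-6)

    def test_beyond_threshold_absent(self):
        rec = synth.make_peptide("AAA", chain_id="A")
        lig = synth.make_peptide("S", chain_id="B")
        og = lig.residues[0].get_atom("OG")
        o = rec.residues[1].get_atom("O")
        shift = o.position - og.position
        target = shift - 3.8 * shift / np.linalg.norm(shift)
        for a in lig.atoms():
            a.position = a.position + target
        d = np.linalg.norm(rec.residues[1].get_atom("O").position
                           - lig.residues[0].get_atom("OG").position)
        assert d == pytest.approx(3.8, abs=1e-9)
        recs = detect_hbonds(lig, rec)
        assert not [r for r in recs if r.ligand_atom == "OG"
                    and r.receptor_atom == "O"
                    and r.receptor_residue == ("A", 2, "")]

    def test_hydrophobic_carbons_ignored(self):
        s1 = Structure()
        r1 = _single_atom_residue("A", 1, (0, 0, 0))
        r1.atoms[0].is_hydrophobic = True
        s1.residues.append(r1)
        s2 = Structure()
        r2 = _single_atom_residue("B", 1, (3.0, 0, 0))
        r2.atoms[0].is_hydrophobic = True
        s2.residues.append(r2)
        assert detect_hbonds(s2, s1) == []

    def test_matches_ground_truth(self, planted):
        _, rec, lig, gt = planted
        got = {(r.ligand_residue, r.receptor_residue, r.ligand_atom,
                r.receptor_atom) for r in detect_hbonds(lig, rec)}
        assert got == gt.hbonds


class TestDetectSaltBridges:
    def test_planted(self):
        (rec, lig, gt) = _planted_single("salt_bridge")
        recs = detect_salt_bridges(lig, rec)
        assert {(r.ligand_residue, r.receptor_residue)
                for r in recs} == gt.salt_bridges
        assert len(gt.salt_bridges) >= 1

    def test_beyond_threshold(self):
        rec = synth.make_peptide("E", chain_id="A")
        lig = synth.make_peptide("K", chain_id="B")
        oe1 = rec.residues[0].get_atom("OE1")
        nz = lig.residues[0].get_atom("NZ")
        shift = oe1.position - nz.position
        move = shift - 4.5 * shift / np.linalg.norm(shift)
        for a in lig.atoms():
            a.position = a.position + move
        got = detect_salt_bridges(lig, rec)
        d = np.linalg.norm(rec.residues[0].get_atom("OE1").position
                           - lig.residues[0].get_atom("NZ").position)
        assert d == pytest.approx(4.5, abs=1e-9)
        # NZ-OE1 is now 4.5; OE2 may still be closer, so only assert on pairs
        for r in got:
            assert r.distance <= 4.0

    def test_like_charges_ignored(self):
        s1 = Structure()
        r1 = _single_atom_residue("A", 1, (0, 0, 0), element="N", name="NZ")
        r1.atoms[0].formal_charge_class = "cationic"
        s1.residues.append(r1)
        s2 = Structure()
        r2 = _single_atom_residue("B", 1, (3.0, 0, 0), element="N", name="NZ")
        r2.atoms[0].formal_charge_class = "cationic"
        s2.residues.append(r2)
        assert detect_salt_bridges(s2, s1) == []

    def test_one_record_per_pair_min_distance(self, planted):
        _, rec, lig, _ = planted
        recs = detect_salt_bridges(lig, rec)
        pairs = [(r.ligand_residue, r.receptor_residue) for r in recs]
        assert len(pairs) == len(set(pairs))


class TestDetectPiCation:
    def _ring_and_cation(self, offset, along_normal=True):
        rec = synth.make_peptide("F", chain_id="A")
        from pepdock.contacts import _ring_geometry
        centroid, normal = _ring_geometry(rec.residues[0])
        lig = Structure()
        r = _single_atom_residue("B", 1, (0, 0, 0), element="N", name="NZ")
        r.atoms[0].formal_charge_class = "cationic"
        direction = normal if along_normal else _in_plane(normal)
        r.atoms[0].position = centroid + offset * direction
        lig.residues.append(r)
        return rec, lig

    def test_cation_on_normal_detected(self):
        rec, lig = self._ring_and_cation(4.0, along_normal=True)
        recs = detect_pi_cation(lig, rec)
        assert len(recs) == 1
        assert recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_in_plane_rejected(self):
        rec, lig = self._ring_and_cation(4.0, along_normal=False)
        assert detect_pi_cation(lig, rec) == []

    def test_cation_too_far(self):
        rec, lig = self._ring_and_cation(7.0, along_normal=True)
        assert detect_pi_cation(lig, rec) == []

    def test_planted_fixture(self):
        rec, lig, gt = _planted_single("pi_cation")
        got = {(r.ligand_residue, r.receptor_residue)
               for r in detect_pi_cation(lig, rec)}
        assert got == gt.pi_cations
        assert len(gt.pi_cations) >= 1


def _in_plane(normal):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(normal, ref)
    return v / np.linalg.norm(v)


class TestDetectHydrophobic:
    def test_planted(self):
        rec, lig, gt = _planted_single("hydrophobic")
        got = {(r.ligand_residue, r.receptor_residue)
               for r in detect_hydrophobic(lig, rec)}
        assert got == gt.hydrophobic
        assert len(gt.hydrophobic) >= 1

    def test_carbonyl_carbon_not_hydrophobic(self):
        rec = synth.make_peptide("AAA", chain_id="A")
        c = rec.residues[1].get_atom("C")  # carbonyl, bonded to O
        lig = Structure()
        r = _single_atom_residue("B", 1, c.position + np.array([4.0, 0, 0]))
        r.atoms[0].is_hydrophobic = True
        lig.residues.append(r)
        recs = detect_hydrophobic(lig, rec)
        assert not [x for x in recs if x.receptor_atom == "C"]

    def test_empty_when_far(self, helix_pair):
        rec, lig = helix_pair
        assert detect_hydrophobic(lig, rec) == []

    def test_atom_pair_count(self):
        # two hydrophobic ligand atoms near one receptor atom -> count 2
        s1 = Structure()
        r1 = _single_atom_residue("A", 1, (0, 0, 0))
        r1.atoms[0].is_hydrophobic = True
        s1.residues.append(r1)
        s2 = Structure()
        r2 = Residue("B", 1, "", "LIG")
        for i, pos in enumerate(((4.0, 0, 0), (0, 4.0, 0)), start=1):
            a = Atom(i, f"C{i}", "C", np.array(pos, dtype=float))
            a.xs_radius, a.sasa_radius, a.is_hydrophobic = 1.9, 1.7, True
            r2.atoms.append(a)
        s2.residues.append(r2)
        recs = detect_hydrophobic(s2, s1)
        assert len(recs) == 1 and recs[0].n_atom_pairs == 2


class TestCloseContacts:
    def test_pair_below_cutoff(self):
        a, b = _pair_structures(2.4)
        assert close_contact_residues(b, a) == [(("B", 1, ""), ("A", 1, ""))]

    def test_pair_above_cutoff(self):
        a, b = _pair_structures(2.6)
        assert close_contact_residues(b, a) == []

    def test_separated(self, helix_pair):
        rec, lig = helix_pair
        assert close_contact_residues(lig, rec) == []

    def test_bad_cutoff(self, helix_pair):
        rec, lig = helix_pair
        with pytest.raises(ValueError):
            close_contact_residues(lig, rec, cutoff=0.0)


class TestRigidMotionInvariance:
    def test_all_detectors(self, planted):
        _, rec, lig, _ = planted
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=5).as_matrix()
        t = np.array([13.0, -7.0, 21.0])
        rec2, lig2 = rec.copy(), lig.copy()
        for s in (rec2, lig2):
            for a in s.atoms():
                a.position = R @ a.position + t
        for detect in (detect_hbonds, detect_salt_bridges,
                       detect_pi_cation, detect_hydrophobic):
            before = {(r.ligand_residue, r.receptor_residue,
                       r.ligand_atom, r.receptor_atom)
                      for r in detect(lig, rec)}
            after = {(r.ligand_residue, r.receptor_residue,
                      r.ligand_atom, r.receptor_atom)
                     for r in detect(lig2, rec2)}
            assert before == after
        m1 = rrcs_matrix(lig, rec)
        m2 = rrcs_matrix(lig2, rec2)
        assert set(m1.entries) == set(m2.entries)
        for k in m1.entries:
            assert m1.entries[k] == pytest.approx(m2.entries[k], abs=1e-9)

    def test_records_inter_chain_only(self, planted):
        _, rec, lig, _ = planted
        for detect in (detect_hbonds, detect_salt_bridges,
                       detect_pi_cation, detect_hydrophobic):
            for r in detect(lig, rec):
                assert r.ligand_residue[0] != r.receptor_residue[0]


class TestHbondAngleMode:
    def _donor_with_h(self, acceptor_pos):
        s1 = Structure()
        r1 = Residue("A", 1, "", "LIG")
        d = Atom(1, "N1", "N", np.array([0.0, 0.0, 0.0]))
        d.xs_radius, d.sasa_radius, d.is_donor = 1.8, 1.55, True
        h = Atom(2, "H1", "H", np.array([1.0, 0.0, 0.0]))
        r1.atoms.extend([d, h])
        s1.residues.append(r1)
        s2 = Structure()
        r2 = Residue("B", 1, "", "LIG")
        a = Atom(1, "O1", "O", np.array(acceptor_pos, dtype=float))
        a.xs_radius, a.sasa_radius, a.is_acceptor = 1.7, 1.52, True
        r2.atoms.append(a)
        s2.residues.append(r2)
        return s1, s2

    def test_linear_geometry_accepted(self):
        s1, s2 = self._donor_with_h((3.0, 0.0, 0.0))
        th = ContactThresholds(hbond_angle_mode=True)
        assert len(detect_hbonds(s2, s1, th)) == 1

    def test_bent_geometry_rejected(self):
        # D-A distance 2.97 (passes), but D-H...A angle is 90 degrees
        s1, s2 = self._donor_with_h((1.0, 2.8, 0.0))
        th = ContactThresholds(hbond_angle_mode=True)
        assert detect_hbonds(s2, s1, th) == []
        # without angle mode the same pair is reported
        assert len(detect_hbonds(s2, s1)) == 1

    def test_no_hydrogens_falls_back_to_distance(self, planted):
        _, rec, lig, _ = planted
        th = ContactThresholds(hbond_angle_mode=True)
        with_mode = detect_hbonds(lig, rec, th)
        without = detect_hbonds(lig, rec)
        assert len(with_mode) == len(without)
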