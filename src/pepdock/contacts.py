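"""Residue-residue contact scores and geometric interaction detectors.

All criteria are heavy-atom based by default.  The contact score of a
residue pair sums a piecewise-linear ramp over every inter-residue
heavy-atom distance: 1 at or below 3.23 Å, falling linearly to 0 at
4.63 Å.  Detector thresholds (hydrogen bond 3.5 Å donor-acceptor, salt
bridge 4.0 Å, π-cation 6.0 Å within 60° of the ring normal, hydrophobic
carbon-carbon 4.5 Å, close contact 2.5 Å) are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import BACKBONE_ATOMS, RegionSpec, Residue, Structure, SelectionError

__all__ = [
    "RRCS_INNER",
    "RRCS_OUTER",
    "ContactThresholds",
    "RRCSMatrix",
    "ContactRecord",
    "rrcs_pair",
    "rrcs_matrix",
    "rrcs_aggregate",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_pi_cation",
    "detect_hydrophobic",
    "close_contact_residues",
]

RRCS_INNER = 3.23  # Å, full-contact plateau
RRCS_OUTER = 4.63  # Å, ramp reaches zero

#: Ring atom names per aromatic residue.
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class ContactThresholds:
    hbond: float = 3.5
    salt_bridge: float = 4.0
    pi_cation: float = 6.0
    pi_cation_angle: float = 60.0  # degrees from ring normal
    hydrophobic: float = 4.5
    close_contact: float = 2.5
    hbond_angle_mode: bool = False
    hbond_min_angle: float = 110.0  # D-H...A, explicit-hydrogen mode only


@dataclass
class ContactRecord:
    kind: str
    ligand_residue: tuple
    receptor_residue: tuple
    ligand_atom: str
    receptor_atom: str
    contact_class: str  # ss / sb / bb, empty where not applicable
    distance: float
    angle: float | None = None
    n_atom_pairs: int = 1
    ligand_label: str = ""
    receptor_label: str = ""


@dataclass
class RRCSMatrix:
    entries: dict = field(default_factory=dict)  # (lig id, rec id) -> score
    receptor_is_glycan: dict = field(default_factory=dict)
    ligand_is_glycan: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def receptor_column_sum(self, rec_id: tuple) -> float:
        return float(sum(v for (li, ri), v in self.entries.items() if ri == rec_id))

    def nonzero_pairs(self) -> list[tuple]:
        return sorted(self.entries.keys())


def _ramp(d: np.ndarray) -> np.ndarray:
    return np.clip((RRCS_OUTER - d) / (RRCS_OUTER - RRCS_INNER), 0.0, 1.0)


def rrcs_pair(res_i: Residue, res_j: Residue, seq_adjacent_rule: bool = True) -> float:
    """Contact score of one residue pair.

    With ``seq_adjacent_rule``, residues of the same chain closer than 5 in
    sequence exclude backbone N, CA, C, O atoms from the summation.
    """
    atoms_i = res_i.heavy_atoms()
    atoms_j = res_j.heavy_atoms()
    if (seq_adjacent_rule and res_i.chain_id == res_j.chain_id
            and abs(res_i.number - res_j.number) < 5):
        skip = {"N", "CA", "C", "O"}
        atoms_i = [a for a in atoms_i if a.name not in skip]
        atoms_j = [a for a in atoms_j if a.name not in skip]
    if not atoms_i or not atoms_j:
        return 0.0
    xi = np.array([a.position for a in atoms_i])
    xj = np.array([a.position for a in atoms_j])
    d = np.linalg.norm(xi[:, None, :] - xj[None, :, :], axis=2)
    return float(_ramp(d).sum())


def rrcs_matrix(ligand: Structure, receptor: Structure) -> RRCSMatrix:
    """Sparse inter-chain contact-score matrix (ligand rows, receptor columns).

    Residue pairs are prefiltered by an any-atom distance test at the ramp
    support before full summation; residues with all atom pairs at or
    beyond the outer radius are absent from the result.
    """
    m = RRCSMatrix()
    lig_res = ligand.residues
    rec_res = receptor.residues
    if not lig_res or not rec_res:
        return m
    rec_atoms, rec_map = [], []
    for ri, r in enumerate(rec_res):
        for a in r.heavy_atoms():
            rec_atoms.append(a.position)
            rec_map.append(ri)
    if not rec_atoms:
        return m
    tree = cKDTree(np.array(rec_atoms))
    rec_map = np.array(rec_map)
    for lr in lig_res:
        la = lr.heavy_atoms()
        if not la:
            continue
        hits = tree.query_ball_point(np.array([a.position for a in la]),
                                     RRCS_OUTER)
        rset = {int(rec_map[j]) for js in hits for j in js}
        for ri in sorted(rset):
            rr = rec_res[ri]
            score = rrcs_pair(lr, rr, seq_adjacent_rule=False)
            if score > 0.0:
                m.entries[(lr.id, rr.id)] = score
                m.receptor_is_glycan[rr.id] = rr.is_glycan
                m.ligand_is_glycan[lr.id] = lr.is_glycan
    return m


def rrcs_aggregate(m: RRCSMatrix, receptor_region: RegionSpec | None = None,
                   partition: str = "all",
                   receptor: Structure | None = None) -> float:
    """Sum of matrix entries, optionally restricted by receptor region/partition.

    ``partition`` is one of ``all``, ``AA`` (non-glycan receptor residues) or
    ``glycan``.  A region requires the *receptor* structure to resolve
    against and must resolve to at least one residue.
    """
    keep_ids = None
    if receptor_region is not None:
        if receptor is None:
            raise ValueError("receptor structure required to resolve the region")
        resolved = receptor_region.resolve(receptor)
        if not resolved:
            raise SelectionError(f"region {receptor_region.name!r} resolved to no residues")
        keep_ids = {r.id for r in resolved}
    total = 0.0
    for (li, ri), v in m.entries.items():
        if keep_ids is not None and ri not in keep_ids:
            continue
        is_gly = m.receptor_is_glycan.get(ri, False)
        if partition == "AA" and is_gly:
            continue
        if partition == "glycan" and not is_gly:
            continue
        total += v
    return float(total)


# ---------------------------------------------------------------------------
# Interaction detectors
# ---------------------------------------------------------------------------

def _side_class(res: Residue, atom_name: str) -> str:
    if res.is_glycan:
        return "s"
    return "b" if atom_name in BACKBONE_ATOMS else "s"


def _residue_pairs_within(ligand: Structure, receptor: Structure, cutoff: float):
    """Yield (lig res, rec res, lig heavy atoms, rec heavy atoms) with any
    heavy-atom pair within *cutoff*."""
    rec_atoms, rec_map = [], []
    for ri, r in enumerate(receptor.residues):
        for a in r.heavy_atoms():
            rec_atoms.append(a.position)
            rec_map.append(ri)
    if not rec_atoms:
        return
    tree = cKDTree(np.array(rec_atoms))
    rec_map = np.array(rec_map)
    for lr in ligand.residues:
        la = lr.heavy_atoms()
        if not la:
            continue
        hits = tree.query_ball_point(np.array([a.position for a in la]), cutoff)
        rset = {int(rec_map[j]) for js in hits for j in js}
        for ri in sorted(rset):
            rr = receptor.residues[ri]
            yield lr, rr, la, rr.heavy_atoms()


def _hbond_angle_ok(donor, acceptor, donor_res, min_angle: float) -> bool:
    """D-H...A angle check using any hydrogen bonded to the donor."""
    hydrogens = [a for a in donor_res.atoms
                 if a.is_hydrogen and np.linalg.norm(a.position - donor.position) < 1.3]
    if not hydrogens:
        return True  # no explicit hydrogen on this donor: fall back to distance
    for h in hydrogens:
        v1 = donor.position - h.position
        v2 = acceptor.position - h.position
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang >= min_angle:
            return True
    return False


def detect_hbonds(ligand: Structure, receptor: Structure,
                  thresholds: ContactThresholds | None = None) -> list[ContactRecord]:
    """Inter-chain donor-acceptor pairs within the heavy-atom distance cutoff.

    One record per qualifying atom pair; with ``hbond_angle_mode`` and
    explicit hydrogens present, the D-H...A angle must also pass.
    """
    th = thresholds or ContactThresholds()
    out = []
    for lr, rr, la, ra in _residue_pairs_within(ligand, receptor, th.hbond):
        for ai in la:
            for aj in ra:
                pairs = []
                if ai.is_donor and aj.is_acceptor:
                    pairs.append((ai, aj, lr))
                if aj.is_donor and ai.is_acceptor:
                    pairs.append((aj, ai, rr))
                if not pairs:
                    continue
                d = float(np.linalg.norm(ai.position - aj.position))
                if d > th.hbond:
                    continue
                for donor, acceptor, donor_res in pairs:
                    if th.hbond_angle_mode and not _hbond_angle_ok(
                            donor, acceptor, donor_res, th.hbond_min_angle):
                        continue
                    cls = _side_class(lr, ai.name) + _side_class(rr, aj.name)
                    out.append(ContactRecord(
                        "hbond", lr.id, rr.id, ai.name, aj.name, cls, d,
                        ligand_label=lr.label, receptor_label=rr.label))
                    break  # one record per atom pair even if doubly capable
    return out


def detect_salt_bridges(ligand: Structure, receptor: Structure,
                        thresholds: ContactThresholds | None = None) -> list[ContactRecord]:
    """Cationic-N / anionic-O inter-chain pairs; one record per residue pair
    carrying the minimal distance."""
    th = thresholds or ContactThresholds()
    best: dict[tuple, ContactRecord] = {}
    for lr, rr, la, ra in _residue_pairs_within(ligand, receptor, th.salt_bridge):
        for ai in la:
            for aj in ra:
                cat_an = (ai.formal_charge_class == "cationic"
                          and aj.formal_charge_class == "anionic")
                an_cat = (ai.formal_charge_class == "anionic"
                          and aj.formal_charge_class == "cationic")
                if not (cat_an or an_cat):
                    continue
                d = float(np.linalg.norm(ai.position - aj.position))
                if d > th.salt_bridge:
                    continue
                key = (lr.id, rr.id)
                if key not in best or d < best[key].distance:
                    cls = _side_class(lr, ai.name) + _side_class(rr, aj.name)
                    best[key] = ContactRecord(
                        "salt_bridge", lr.id, rr.id, ai.name, aj.name, cls, d,
                        ligand_label=lr.label, receptor_label=rr.label)
    return [best[k] for k in sorted(best)]


def _ring_geometry(res: Residue):
    names = AROMATIC_RINGS.get(res.name)
    if names is None:
        return None
    pts = []
    for n in names:
        a = res.get_atom(n)
        if a is None:
            return None
        pts.append(a.position)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # normal = smallest principal axis of the ring points
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def detect_pi_cation(ligand: Structure, receptor: Structure,
                     thresholds: ContactThresholds | None = None) -> list[ContactRecord]:
    """Aromatic-ring centroid / cationic-nitrogen pairs across chains.

    Requires centroid-cation distance within the cutoff and the
    centroid-to-cation vector within the angular cutoff of the ring normal.
    """
    th = thresholds or ContactThresholds()

    def rings(s: Structure):
        for r in s.residues:
            g = _ring_geometry(r)
            if g is not None:
                yield r, g

    def cations(s: Structure):
        for r in s.residues:
            for a in r.heavy_atoms():
                if a.formal_charge_class == "cationic" and a.element == "N":
                    yield r, a

    out = []
    for (ring_side, cation_side, flip) in (
            (ligand, receptor, False), (receptor, ligand, True)):
        for ring_res, (centroid, normal) in rings(ring_side):
            for cat_res, cat in cations(cation_side):
                v = cat.position - centroid
                d = float(np.linalg.norm(v))
                if d > th.pi_cation or d == 0.0:
                    continue
                cosang = abs(float(np.dot(v / d, normal)))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang > th.pi_cation_angle:
                    continue
                if flip:
                    rec = ContactRecord("pi_cation", cat_res.id, ring_res.id,
                                        cat.name, "ring", "ss", d, angle=ang,
                                        ligand_label=cat_res.label,
                                        receptor_label=ring_res.label)
                else:
                    rec = ContactRecord("pi_cation", ring_res.id, cat_res.id,
                                        "ring", cat.name, "ss", d, angle=ang,
                                        ligand_label=ring_res.label,
                                        receptor_label=cat_res.label)
                out.append(rec)
    return sorted(out, key=lambda r: (r.ligand_residue, r.receptor_residue))


def detect_hydrophobic(ligand: Structure, receptor: Structure,
                       thresholds: ContactThresholds | None = None) -> list[ContactRecord]:
    """Hydrophobic-carbon pairs across chains, aggregated per residue pair."""
    th = thresholds or ContactThresholds()
    agg: dict[tuple, list] = {}
    for lr, rr, la, ra in _residue_pairs_within(ligand, receptor, th.hydrophobic):
        for ai in la:
            if not ai.is_hydrophobic:
                continue
            for aj in ra:
                if not aj.is_hydrophobic:
                    continue
                d = float(np.linalg.norm(ai.position - aj.position))
                if d > th.hydrophobic:
                    continue
                key = (lr.id, rr.id)
                if key not in agg or d < agg[key][0].distance:
                    rec = ContactRecord(
                        "hydrophobic", lr.id, rr.id, ai.name, aj.name,
                        _side_class(lr, ai.name) + _side_class(rr, aj.name), d,
                        ligand_label=lr.label, receptor_label=rr.label)
                    count = agg[key][1] + 1 if key in agg else 1
                    agg[key] = [rec, count]
                else:
                    agg[key][1] += 1
    out = []
    for key in sorted(agg):
        rec, count = agg[key]
        rec.n_atom_pairs = count
        out.append(rec)
    return out


def close_contact_residues(ligand: Structure, receptor: Structure,
                           cutoff: float = 2.5) -> list[tuple]:
    """Inter-chain residue pairs with any heavy-atom distance below *cutoff*."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = set()
    for lr, rr, la, ra in _residue_pairs_within(ligand, receptor, cutoff):
        xi = np.array([a.position for a in la])
        xj = np.array([a.position for a in ra])
        d = np.linalg.norm(xi[:, None, :] - xj[None, :, :], axis=2)
        if float(d.min()) < cutoff:
            out.add((lr.id, rr.id))
    return sorted(out)
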