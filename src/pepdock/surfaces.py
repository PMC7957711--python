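"""Solvent-accessible surface area and interface burial metrics.

SASA uses the Shrake-Rupley point-sphere method with a deterministic
golden-section spiral (no random seeds), probe radius 1.4 Å and 960 points
per atom by default.  Interface metrics compare per-residue areas of each
molecule in isolation against the assembled complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure

__all__ = [
    "SASAResult",
    "InterfaceReport",
    "sasa",
    "residue_bsa",
    "interface_metrics",
]

#: Per-residue burial below this (Å^2) is quadrature noise, not interface.
RESIDUE_BSA_EPS = 0.1
ATOM_BSA_EPS = 0.01


@dataclass
class SASAResult:
    per_atom: np.ndarray  # Å^2, one entry per heavy atom in structure order
    per_residue: dict  # residue id -> Å^2
    total: float
    probe: float
    n_points: int


@dataclass
class ResidueBurial:
    residue_id: tuple
    label: str
    name: str
    is_glycan: bool
    asa_isolated: float
    asa_complex: float
    bsa: float
    percent_bsa: float
    is_interface: bool
    side: str  # "ligand" | "receptor"


@dataclass
class InterfaceReport:
    residues: list = field(default_factory=list)  # ResidueBurial
    toxin_aa_in_interface_percent: float = 0.0
    glycan_atoms_in_interface_percent: float = 0.0
    asa_ti_percent: float = 0.0
    asa_navi_percent: float = 0.0

    def residue(self, residue_id: tuple, side: str | None = None) -> ResidueBurial | None:
        for rb in self.residues:
            if rb.residue_id == residue_id and (side is None or rb.side == side):
                return rb
        return None

    def interface_residues(self, side: str | None = None) -> list:
        return [rb for rb in self.residues
                if rb.is_interface and (side is None or rb.side == side)]


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def _atom_frame(xyz: np.ndarray, i: int, neighbours: list) -> np.ndarray:
    """Rotation aligning the point sphere to the atom's neighbour geometry.

    Anchoring the quadrature grid to the nearest (and second-nearest)
    neighbour directions makes the areas exactly invariant under rigid
    motion of the molecule and symmetric for symmetric configurations.
    """
    if not neighbours:
        return np.eye(3)
    rel = xyz[neighbours] - xyz[i]
    dist = np.linalg.norm(rel, axis=1)
    unit = rel / dist[:, None]
    # two smooth distance-weighted moments: purely geometric, so they
    # co-rotate exactly even when neighbour distances tie exactly
    m1 = (np.exp(-dist)[:, None] * unit).sum(axis=0)
    m2 = (np.exp(-dist / 2.0)[:, None] * unit).sum(axis=0)
    n1 = np.linalg.norm(m1)
    if n1 < 1e-8:
        return np.eye(3)
    z = m1 / n1
    x = m2 - np.dot(m2, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, z)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = ref - np.dot(ref, z) * z
        x /= np.linalg.norm(x)
    else:
        x /= nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _sasa_arrays(xyz: np.ndarray, radii: np.ndarray, probe: float,
                 n_points: int) -> np.ndarray:
    """Per-atom accessible areas for inflated spheres of radius r+probe."""
    sphere = _sphere_points(n_points)
    inflated = radii + probe
    tree = cKDTree(xyz)
    max_r = float(inflated.max())
    areas = np.zeros(len(xyz))
    for i in range(len(xyz)):
        ri = inflated[i]
        neighbours = [j for j in tree.query_ball_point(xyz[i], ri + max_r)
                      if j != i]
        if neighbours:
            frame = _atom_frame(xyz, i, neighbours)
            pts = xyz[i] + ri * (sphere @ frame.T)
            npos = xyz[neighbours]
            nrad = inflated[neighbours]
            d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        areas[i] = (accessible / n_points) * 4.0 * np.pi * ri * ri
    return areas


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area (heavy atoms only)."""
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    atoms = s.heavy_atoms()
    if not atoms:
        raise ValueError("structure has no heavy atoms")
    for a in atoms:
        if a.sasa_radius is None:
            raise ValueError(f"atom {a.serial} {a.name} has no sasa_radius; "
                             "run assign_atom_types first")
    xyz = np.array([a.position for a in atoms])
    radii = np.array([a.sasa_radius for a in atoms])
    per_atom = _sasa_arrays(xyz, radii, probe, n_points)
    per_res: dict = {}
    idx = 0
    for r in s.residues:
        n_heavy = len(r.heavy_atoms())
        per_res[r.id] = float(per_atom[idx:idx + n_heavy].sum())
        idx += n_heavy
    return SASAResult(per_atom=per_atom, per_residue=per_res,
                      total=float(per_atom.sum()), probe=probe, n_points=n_points)


def _complex_arrays(ligand: Structure, receptor: Structure):
    lig_atoms = ligand.heavy_atoms()
    rec_atoms = receptor.heavy_atoms()
    xyz = np.array([a.position for a in lig_atoms + rec_atoms])
    radii = np.array([a.sasa_radius for a in lig_atoms + rec_atoms])
    return xyz, radii, len(lig_atoms)


def residue_bsa(ligand: Structure, receptor: Structure,
                probe: float = 1.4, n_points: int = 960) -> InterfaceReport:
    """Per-residue burial upon complexation for both molecules.

    BSA is the isolated-molecule ASA minus the in-complex ASA (clamped at
    zero beyond numerical noise); percent_BSA is relative to the residue's
    isolated ASA.  A residue is interfacial iff BSA exceeds 0.1 Å^2.
    """
    lig_iso = sasa(ligand, probe, n_points)
    rec_iso = sasa(receptor, probe, n_points)
    xyz, radii, n_lig = _complex_arrays(ligand, receptor)
    per_atom_cplx = _sasa_arrays(xyz, radii, probe, n_points)

    report = InterfaceReport()
    report._lig_atom_bsa = lig_iso.per_atom - per_atom_cplx[:n_lig]
    report._rec_atom_bsa = rec_iso.per_atom - per_atom_cplx[n_lig:]
    report._lig_iso_total = lig_iso.total
    report._rec_iso_total = rec_iso.total
    report._complex_total = float(per_atom_cplx.sum())

    for side, struct, iso, atom_bsa in (
            ("ligand", ligand, lig_iso, report._lig_atom_bsa),
            ("receptor", receptor, rec_iso, report._rec_atom_bsa)):
        idx = 0
        for r in struct.residues:
            n_heavy = len(r.heavy_atoms())
            asa_i = iso.per_residue[r.id]
            burial = float(atom_bsa[idx:idx + n_heavy].sum())
            idx += n_heavy
            bsa = max(0.0, burial)
            pct = 100.0 * bsa / asa_i if asa_i > 0 else 0.0
            report.residues.append(ResidueBurial(
                residue_id=r.id, label=r.label, name=r.name,
                is_glycan=r.is_glycan, asa_isolated=asa_i,
                asa_complex=asa_i - burial, bsa=bsa,
                percent_bsa=min(pct, 100.0),
                is_interface=bsa > RESIDUE_BSA_EPS, side=side))
    return report


def interface_metrics(ligand: Structure, receptor: Structure,
                      report: InterfaceReport) -> InterfaceReport:
    """Populate the four percentage metrics on *report* (in place).

    ASA_TI: share of the ligand's isolated ASA carried by its interface
    residues; ASA_NavI: same for the receptor.  The amino-acid interface
    percentage counts non-glycan ligand residues; the glycan-atom
    percentage counts glycan heavy atoms with per-atom burial above the
    atomic epsilon, over glycan heavy atoms of both molecules.
    """
    lig_rows = [rb for rb in report.residues if rb.side == "ligand"]
    rec_rows = [rb for rb in report.residues if rb.side == "receptor"]
    lig_total = sum(rb.asa_isolated for rb in lig_rows)
    rec_total = sum(rb.asa_isolated for rb in rec_rows)
    if lig_total <= 0:
        raise ValueError("ligand has zero accessible surface")
    lig_if = sum(rb.asa_isolated for rb in lig_rows if rb.is_interface)
    rec_if = sum(rb.asa_isolated for rb in rec_rows if rb.is_interface)
    report.asa_ti_percent = 100.0 * lig_if / lig_total
    report.asa_navi_percent = 100.0 * rec_if / rec_total if rec_total > 0 else 0.0

    lig_aa = [rb for rb in lig_rows if not rb.is_glycan]
    if lig_aa:
        report.toxin_aa_in_interface_percent = (
            100.0 * sum(1 for rb in lig_aa if rb.is_interface) / len(lig_aa))

    glycan_total = 0
    glycan_buried = 0
    for struct, atom_bsa in ((ligand, report._lig_atom_bsa),
                             (receptor, report._rec_atom_bsa)):
        idx = 0
        for r in struct.residues:
            n_heavy = len(r.heavy_atoms())
            if r.is_glycan:
                glycan_total += n_heavy
                glycan_buried += int((atom_bsa[idx:idx + n_heavy] > ATOM_BSA_EPS).sum())
            idx += n_heavy
    if glycan_total:
        report.glycan_atoms_in_interface_percent = 100.0 * glycan_buried / glycan_total
    return report
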