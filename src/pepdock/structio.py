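"""Molecular data model and PDB input/output.

Structures are modelled as a flat, file-ordered list of residues, each
holding its atoms.  Atoms carry the physical annotations (radii,
donor/acceptor/hydrophobic flags, formal charge class) that the scoring,
contact and surface modules consume; :func:`assign_atom_types` populates
them from documented tables.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RegionSpec",
    "PDBFormatError",
    "SelectionError",
    "TopologyError",
    "TypingError",
    "read_pdb",
    "write_pdb",
    "strip_residues",
    "assign_atom_types",
    "select_region",
    "ligand_rmsd",
]


class PDBFormatError(ValueError):
    """Raised for unparseable PDB records (message carries the line number)."""


class SelectionError(ValueError):
    """Raised when a selector resolves to nothing where residues are required."""


class TopologyError(ValueError):
    """Raised when two structures expected to share topology do not."""


class TypingError(ValueError):
    """Raised when an atom cannot be assigned physical types."""


# Scoring radii (Å), by element.
XS_RADII = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
}

# Surface (SASA) radii (Å), by element.
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: Residue names flagged as glycans by default.
GLYCAN_RESNAMES = frozenset({"NAG", "BMA", "MAN"})

#: Backbone heavy-atom names for amino acids.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Covalent bond inference thresholds (Å).
BOND_CUTOFF = 1.9
BOND_CUTOFF_SP = 2.2  # when either atom is S or P

# Side-chain hydrogen-bond capabilities: residue -> atom -> (donor, acceptor).
_SIDECHAIN_HB = {
    "SER": {"OG": (True, True)},
    "THR": {"OG1": (True, True)},
    "TYR": {"OH": (True, True)},
    "CYS": {"SG": (True, False)},
    "ASN": {"ND2": (True, False), "OD1": (False, True)},
    "GLN": {"NE2": (True, False), "OE1": (False, True)},
    "LYS": {"NZ": (True, False)},
    "ARG": {"NE": (True, False), "NH1": (True, False), "NH2": (True, False)},
    "TRP": {"NE1": (True, False)},
    "HIS": {"ND1": (False, True), "NE2": (False, True)},
    "ASP": {"OD1": (False, True), "OD2": (False, True)},
    "GLU": {"OE1": (False, True), "OE2": (False, True)},
    "HYP": {"OD1": (True, True)},
}

_CATIONIC = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}}
_ANIONIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    position: np.ndarray
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    xs_radius: float | None = None
    sasa_radius: float | None = None
    is_hydrophobic: bool = False
    is_donor: bool = False
    is_acceptor: bool = False
    formal_charge_class: str = "neutral"

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_glycan: bool = False
    segment_label: str | None = None

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.name}{self.number}{icode}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    model_id: int = 1
    residues: list[Residue] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if not a.is_hydrogen]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        ats = self.heavy_atoms() if heavy_only else list(self.atoms())
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.position for a in ats], dtype=float)

    def set_coords(self, xyz: np.ndarray, heavy_only: bool = True) -> None:
        ats = self.heavy_atoms() if heavy_only else list(self.atoms())
        if len(ats) != len(xyz):
            raise TopologyError(
                f"coordinate array has {len(xyz)} rows for {len(ats)} atoms"
            )
        for a, p in zip(ats, xyz):
            a.position = np.asarray(p, dtype=float)

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.id == (chain_id, number, icode):
                return r
        return None

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "Structure":
        """Return a copy with ``x -> R (x - c) + c + t`` applied to every atom."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        for a in out.atoms():
            a.position = R @ (a.position - c) + c + t
        return out

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class RegionSpec:
    """Named selection: explicit residue ids and/or residue-name selectors.

    ``members`` entries are ``(chain_id, number)`` or
    ``(chain_id, number, insertion_code)`` tuples; ``resnames`` selects by
    3-letter residue name; ``glycans=True`` selects every glycan residue.
    """

    name: str = "region"
    members: Sequence[tuple] = ()
    resnames: Sequence[str] = ()
    glycans: bool = False

    def resolve(self, s: Structure) -> list[Residue]:
        keys = set()
        for m in self.members:
            if len(m) == 2:
                keys.add((str(m[0]), int(m[1]), ""))
            else:
                keys.add((str(m[0]), int(m[1]), str(m[2])))
        names = {n.upper() for n in self.resnames}
        out = []
        for r in s.residues:
            if r.id in keys or r.name in names or (self.glycans and r.is_glycan):
                out.append(r)
        return out


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # Two-letter elements appearing in protein/glycan context.
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA") and len(stripped) <= 2:
        return two
    lead = stripped.lstrip("0123456789")
    return lead[:1].upper()


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, tuple[str, int, str, str]]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _element_from_name(line[12:16])
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        position=np.array([x, y, z], dtype=float),
        is_hetero=line.startswith("HETATM"),
        altloc=altloc,
        occupancy=occ,
        bfactor=bfac,
    )
    return atom, (chain, resnum, icode, resname)


def _resolve_altlocs(residue: Residue) -> None:
    """Keep the highest-occupancy altloc per atom name; ties -> first in file."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in residue.atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    residue.atoms = [best[n] for n in order]


def read_pdb(path, model_index: int | None = None,
             glycan_resnames: Iterable[str] = GLYCAN_RESNAMES):
    """Read a PDB file into :class:`Structure` objects.

    Returns a single :class:`Structure` when the file has one model or
    ``model_index`` is given (1-based MODEL serial position, 0-based list
    index otherwise); a list of structures for multi-model files.
    """
    path = Path(path)
    glycans = {n.upper() for n in glycan_resnames}
    models: list[Structure] = []
    current: Structure | None = None
    seen_any_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    mid = int(line[10:14])
                except ValueError:
                    mid = len(models) + 1
                current = Structure(model_id=mid, provenance=f"{path}#model{mid}")
                models.append(current)
            elif rec in ("ATOM  ", "HETATM"):
                seen_any_atom = True
                if current is None:
                    current = Structure(model_id=1, provenance=str(path))
                    models.append(current)
                atom, (chain, resnum, icode, resname) = _parse_atom_record(line, lineno)
                res = current.residues[-1] if current.residues else None
                if res is None or res.id != (chain, resnum, icode) or res.name != resname:
                    res = Residue(chain, resnum, icode, resname,
                                  is_glycan=resname.upper() in glycans)
                    current.residues.append(res)
                res.atoms.append(atom)
            elif rec == "ENDMDL":
                current = None
    if not seen_any_atom:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    for m in models:
        for r in m.residues:
            _resolve_altlocs(r)
    if model_index is not None:
        if not 0 <= model_index < len(models):
            raise IndexError(
                f"model_index {model_index} out of range for {len(models)} models"
            )
        return models[model_index]
    if len(models) == 1:
        return models[0]
    return models


def _format_atom_line(a: Atom, r: Residue) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name
    # PDB alignment: 1-char elements start in column 14 unless 4 chars long.
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    name = name.ljust(4)[:4]
    element = a.element.rjust(2)[:2]
    return (
        f"{rec}{a.serial:>5} {name}{a.altloc or ' '}{r.name:>3} "
        f"{r.chain_id[:1]}{r.number:>4}{r.insertion_code or ' '}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {element}  "
    )


def write_pdb(structures: Structure | Sequence[Structure], path) -> None:
    """Write one structure (single-model) or several (MODEL/ENDMDL blocks)."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    lines: list[str] = []
    for i, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4}")
        serial = 0
        prev_chain = None
        for r in s.residues:
            if prev_chain is not None and r.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = r.chain_id
            for a in r.atoms:
                serial += 1
                line = _format_atom_line(a, r)
                # renumber serially so concatenated chains stay valid
                lines.append(f"{line[:6]}{serial:>5}{line[11:]}")
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def strip_residues(s: Structure, selector: RegionSpec | str) -> Structure:
    """Return a copy of *s* without the residues selected by *selector*.

    *selector* may be a :class:`RegionSpec` or a chain id.
    """
    if isinstance(selector, str):
        selected = {r.id for r in s.residues if r.chain_id == selector}
    else:
        selected = {r.id for r in selector.resolve(s)}
    if not selected:
        raise SelectionError(f"selector resolved to no residues in {s.provenance or 'structure'}")
    out = s.copy()
    out.residues = [r for r in out.residues if r.id not in selected]
    return out


def select_region(s: Structure, region: RegionSpec) -> list[Residue]:
    """Resolve *region* against *s*; empty result is returned, not raised."""
    return region.resolve(s)


def _infer_bonds(structure: Structure) -> dict[int, list[int]]:
    """Heavy-atom covalent bonds by distance; keys/values index heavy atoms."""
    atoms = structure.heavy_atoms()
    if not atoms:
        return {}
    xyz = np.array([a.position for a in atoms])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(BOND_CUTOFF_SP, output_type="ndarray")
    bonds: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in pairs:
        cutoff = BOND_CUTOFF
        if atoms[i].element in ("S", "P") or atoms[j].element in ("S", "P"):
            cutoff = BOND_CUTOFF_SP
        if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
            bonds[int(i)].append(int(j))
            bonds[int(j)].append(int(i))
    return bonds


def assign_atom_types(s: Structure,
                      protonated_his: Iterable[tuple] | None = None) -> Structure:
    """Populate radii and physical flags on every heavy atom of *s* (in place).

    ``protonated_his`` lists residue ids ``(chain, number[, icode])`` of
    histidines to treat as cationic donors instead of neutral acceptors.
    """
    his_ids = set()
    for m in (protonated_his or ()):
        his_ids.add((str(m[0]), int(m[1]), str(m[2]) if len(m) > 2 else ""))

    atoms = s.heavy_atoms()
    for a in atoms:
        el = a.element.upper()
        if el not in XS_RADII:
            raise TypingError(f"unknown element {a.element!r} for atom {a.serial} {a.name}")
        a.xs_radius = XS_RADII[el]
        a.sasa_radius = SASA_RADII.get(el, XS_RADII[el])

    bonds = _infer_bonds(s)
    for idx, a in enumerate(atoms):
        a.is_hydrophobic = (
            a.element == "C"
            and all(atoms[j].element == "C" for j in bonds.get(idx, []))
        )

    for r in s.residues:
        sidechain = _SIDECHAIN_HB.get(r.name, {})
        cationic = _CATIONIC.get(r.name, set())
        anionic = _ANIONIC.get(r.name, set())
        his_protonated = r.name == "HIS" and r.id in his_ids
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            donor = acceptor = False
            charge = "neutral"
            if r.is_glycan:
                if a.element == "O":
                    donor = acceptor = True
                elif a.element == "N":
                    donor = True
            elif a.name == "N":
                donor = r.name != "PRO"
            elif a.name in ("O", "OXT"):
                acceptor = True
                if a.name == "OXT":
                    charge = "anionic"
            elif a.name in sidechain:
                donor, acceptor = sidechain[a.name]
            if a.name in cationic:
                charge = "cationic"
            elif a.name in anionic:
                charge = "anionic"
            if his_protonated and a.name in ("ND1", "NE2"):
                donor, acceptor = True, False
                charge = "cationic"
            a.is_donor = donor
            a.is_acceptor = acceptor
            a.formal_charge_class = charge
    return s


def ligand_rmsd(a: Structure, b: Structure) -> float:
    """Heavy-atom RMSD between two placements of the same molecule.

    No superposition is applied: both structures are assumed to live in the
    shared receptor frame.
    """
    aa, bb = a.heavy_atoms(), b.heavy_atoms()
    if len(aa) != len(bb) or any(x.name != y.name for x, y in zip(aa, bb)):
        raise TopologyError("structures do not share atom names/order")
    xa = np.array([x.position for x in aa])
    xb = np.array([x.position for x in bb])
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
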