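"""Five-term empirical scoring of rigid ligand poses and pose search.

The inter-molecular score is a weighted sum, over heavy-atom pairs within a
center-distance cutoff, of two Gaussians, a quadratic steric repulsion, a
hydrophobic ramp and a donor-acceptor ramp, all functions of the
surface-to-surface distance (center distance minus the sum of the scoring
radii).  The ligand is rigid, so no torsion-count normalisation is applied
(divisor 1) and totals are reported on a kcal/mol scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, RegionSpec, Structure, TypingError

__all__ = [
    "ScoringParams",
    "Pose",
    "ScoreBreakdown",
    "SearchConfig",
    "ConfigError",
    "surface_distance",
    "pair_terms",
    "score_complex",
    "decompose_by_residue",
    "dock_rigid",
    "cluster_poses",
    "apply_pose",
]

TERMS = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")

#: Published default weights of the empirical function (kcal/mol scale).
DEFAULT_WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}


class ConfigError(ValueError):
    pass


@dataclass
class ScoringParams:
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    cutoff: float = 8.0  # center-distance cutoff, Å
    gauss1_width: float = 0.5
    gauss2_offset: float = 3.0
    gauss2_width: float = 2.0
    hydrophobic_ramp: tuple = (0.5, 1.5)  # 1 -> 0 over this surface-distance range
    hbond_ramp: tuple = (-0.7, 0.0)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if not (self.hydrophobic_ramp[0] < self.hydrophobic_ramp[1]
                and self.hbond_ramp[0] < self.hbond_ramp[1]):
            raise ConfigError("ramp bounds must be ordered")


@dataclass
class Pose:
    rotation: np.ndarray  # unit quaternion (w, x, y, z)
    translation: np.ndarray  # Å, applied after rotation about the start centroid
    ligand_model_id: int = 1
    rank: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            q = q / n
        self.rotation = q
        self.translation = np.asarray(self.translation, dtype=float)


@dataclass
class ScoreBreakdown:
    total: float
    per_term: dict
    per_receptor_residue: dict
    per_ligand_residue: dict
    receptor: Structure | None = None
    ligand: Structure | None = None


@dataclass
class SearchConfig:
    box_center: np.ndarray
    box_half: np.ndarray
    n_restarts: int = 8
    n_steps: int = 500
    t_start: float = 2.0
    t_end: float = 0.05
    seed: int = 0
    keep_top: int = 20
    dedup_rmsd: float = 2.0
    translation_sigma: float = 0.5  # Å
    rotation_sigma_deg: float = 5.0
    quench: bool = True  # deterministic local optimisation of each restart's best
    quench_maxiter: int = 60

    def __post_init__(self) -> None:
        self.box_center = np.asarray(self.box_center, dtype=float)
        self.box_half = np.asarray(self.box_half, dtype=float)
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.keep_top < 1:
            raise ConfigError("keep_top must be >= 1")
        if np.any(self.box_half <= 0):
            raise ConfigError("box half-widths must be positive")


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------

def surface_distance(atom_i: Atom, atom_j: Atom) -> float:
    """Center distance minus the sum of scoring radii (may be negative)."""
    if atom_i.xs_radius is None or atom_j.xs_radius is None:
        raise TypingError("atoms must be typed (xs_radius missing)")
    r = float(np.linalg.norm(atom_i.position - atom_j.position))
    return r - atom_i.xs_radius - atom_j.xs_radius


def pair_terms(d: float, type_i: Atom, type_j: Atom,
               params: ScoringParams | None = None) -> dict:
    """Unweighted values of the five terms at surface distance *d*."""
    p = params or ScoringParams()
    out = {
        "gauss1": math.exp(-((d / p.gauss1_width) ** 2)),
        "gauss2": math.exp(-(((d - p.gauss2_offset) / p.gauss2_width) ** 2)),
        "repulsion": d * d if d < 0 else 0.0,
        "hydrophobic": 0.0,
        "hbond": 0.0,
    }
    lo, hi = p.hydrophobic_ramp
    if type_i.is_hydrophobic and type_j.is_hydrophobic:
        out["hydrophobic"] = min(1.0, max(0.0, (hi - d) / (hi - lo)))
    lo, hi = p.hbond_ramp
    if ((type_i.is_donor and type_j.is_acceptor)
            or (type_j.is_donor and type_i.is_acceptor)):
        out["hbond"] = min(1.0, max(0.0, (hi - d) / (hi - lo)))
    return out


# ---------------------------------------------------------------------------
# Vectorised scoring engine
# ---------------------------------------------------------------------------

class _MoleculeArrays:
    """Flat per-heavy-atom arrays plus the residue index of each atom."""

    def __init__(self, s: Structure):
        atoms = []
        res_index = []
        self.residue_ids = []
        self.residue_labels = []
        for ri, r in enumerate(s.residues):
            self.residue_ids.append(r.id)
            self.residue_labels.append(r.label)
            for a in r.atoms:
                if a.is_hydrogen:
                    continue
                if a.xs_radius is None:
                    raise TypingError(
                        f"atom {a.serial} {a.name} of {r.label} is untyped")
                atoms.append(a)
                res_index.append(ri)
        if not atoms:
            raise ValueError("molecule has no heavy atoms")
        self.xyz = np.array([a.position for a in atoms], dtype=float)
        self.radius = np.array([a.xs_radius for a in atoms], dtype=float)
        self.hydrophobic = np.array([a.is_hydrophobic for a in atoms], dtype=bool)
        self.donor = np.array([a.is_donor for a in atoms], dtype=bool)
        self.acceptor = np.array([a.is_acceptor for a in atoms], dtype=bool)
        self.res_index = np.array(res_index, dtype=np.intp)
        self.n_residues = len(s.residues)


class ScoringEngine:
    """Receptor-side KD-tree scoring of arbitrary ligand placements."""

    def __init__(self, receptor: Structure, ligand: Structure,
                 params: ScoringParams | None = None):
        self.params = params or ScoringParams()
        self.rec = _MoleculeArrays(receptor)
        self.lig = _MoleculeArrays(ligand)
        self.tree = cKDTree(self.rec.xyz)

    def _pairs(self, lig_xyz: np.ndarray):
        """Interacting (ligand atom, receptor atom) index pairs within cutoff."""
        if len(lig_xyz) * len(self.rec.xyz) <= 250_000:
            # dense path: cheaper than tree traversal for small systems
            d2 = ((lig_xyz[:, None, :] - self.rec.xyz[None, :, :]) ** 2).sum(axis=2)
            li, rj = np.nonzero(d2 <= self.params.cutoff ** 2)
            return li, rj
        neigh = self.tree.query_ball_point(lig_xyz, self.params.cutoff)
        counts = [len(js) for js in neigh]
        li = np.repeat(np.arange(len(lig_xyz), dtype=np.intp), counts)
        rj = np.concatenate([np.asarray(js, dtype=np.intp) for js in neigh]
                            or [np.empty(0, dtype=np.intp)])
        return li, rj

    def _term_matrix(self, lig_xyz, li, rj):
        """(n_pairs, 5) unweighted term values for the given pairs."""
        p = self.params
        d = (np.linalg.norm(lig_xyz[li] - self.rec.xyz[rj], axis=1)
             - self.lig.radius[li] - self.rec.radius[rj])
        g1 = np.exp(-((d / p.gauss1_width) ** 2))
        g2 = np.exp(-(((d - p.gauss2_offset) / p.gauss2_width) ** 2))
        rep = np.where(d < 0, d * d, 0.0)
        lo, hi = p.hydrophobic_ramp
        hyd = np.clip((hi - d) / (hi - lo), 0.0, 1.0)
        hyd *= self.lig.hydrophobic[li] & self.rec.hydrophobic[rj]
        lo, hi = p.hbond_ramp
        hb = np.clip((hi - d) / (hi - lo), 0.0, 1.0)
        hb *= ((self.lig.donor[li] & self.rec.acceptor[rj])
               | (self.rec.donor[rj] & self.lig.acceptor[li]))
        return np.column_stack([g1, g2, rep, hyd, hb])

    def score(self, lig_xyz: np.ndarray) -> float:
        """Weighted total only (fast path for the search)."""
        li, rj = self._pairs(lig_xyz)
        if len(li) == 0:
            return 0.0
        terms = self._term_matrix(lig_xyz, li, rj)
        w = np.array([self.params.weights[t] for t in TERMS])
        return float((terms @ w).sum())

    def breakdown(self, lig_xyz: np.ndarray,
                  receptor: Structure | None = None,
                  ligand: Structure | None = None) -> ScoreBreakdown:
        li, rj = self._pairs(lig_xyz)
        w = np.array([self.params.weights[t] for t in TERMS])
        if len(li) == 0:
            return ScoreBreakdown(0.0, {t: 0.0 for t in TERMS}, {}, {},
                                  receptor=receptor, ligand=ligand)
        terms = self._term_matrix(lig_xyz, li, rj)
        pair_scores = terms @ w
        total = float(pair_scores.sum())
        per_term = {t: float(terms[:, k].sum()) for k, t in enumerate(TERMS)}
        rec_contrib = np.zeros(self.rec.n_residues)
        np.add.at(rec_contrib, self.rec.res_index[rj], pair_scores)
        lig_contrib = np.zeros(self.lig.n_residues)
        np.add.at(lig_contrib, self.lig.res_index[li], pair_scores)
        per_rec = {self.rec.residue_ids[i]: float(v)
                   for i, v in enumerate(rec_contrib) if v != 0.0}
        per_lig = {self.lig.residue_ids[i]: float(v)
                   for i, v in enumerate(lig_contrib) if v != 0.0}
        # keep exact conservation: total re-derived from the same partial sums
        total = float(rec_contrib.sum())
        return ScoreBreakdown(total, per_term, per_rec, per_lig,
                              receptor=receptor, ligand=ligand)


def score_complex(receptor: Structure, ligand: Structure,
                  params: ScoringParams | None = None) -> ScoreBreakdown:
    """Score *ligand* in its current placement against *receptor*."""
    eng = ScoringEngine(receptor, ligand, params)
    return eng.breakdown(eng.lig.xyz, receptor=receptor, ligand=ligand)


def decompose_by_residue(b: ScoreBreakdown, region: RegionSpec | None = None,
                         side: str = "receptor") -> list[tuple]:
    """Per-residue contributions sorted most-stabilising (most negative) first."""
    contrib = b.per_receptor_residue if side == "receptor" else b.per_ligand_residue
    items = list(contrib.items())
    if region is not None:
        struct = b.receptor if side == "receptor" else b.ligand
        if struct is None:
            raise ValueError("breakdown lacks a structure reference for region filtering")
        keep = {r.id for r in region.resolve(struct)}
        items = [(k, v) for k, v in items if k in keep]
    return sorted(items, key=lambda kv: (kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Rigid-body pose search
# ---------------------------------------------------------------------------

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _axis_angle_quat(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    half = angle_rad / 2.0
    return np.concatenate([[math.cos(half)], math.sin(half) * axis])


def pose_coords(lig_xyz0: np.ndarray, centroid0: np.ndarray, pose: Pose) -> np.ndarray:
    R = quat_to_matrix(pose.rotation)
    return (lig_xyz0 - centroid0) @ R.T + centroid0 + pose.translation


def apply_pose(ligand: Structure, pose: Pose) -> Structure:
    """Return the ligand structure moved to *pose* (all atoms, incl. H)."""
    out = ligand.copy()
    xyz0 = ligand.coords(heavy_only=False)
    c0 = ligand.coords(heavy_only=True).mean(axis=0)
    out.set_coords(pose_coords(xyz0, c0, pose), heavy_only=False)
    return out


def _pose_rmsd(lig_xyz0, c0, pa: Pose, pb: Pose) -> float:
    xa = pose_coords(lig_xyz0, c0, pa)
    xb = pose_coords(lig_xyz0, c0, pb)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _quench(eng: ScoringEngine, lig_xyz0, c0, pose: Pose, energy: float,
            cfg: SearchConfig) -> tuple[Pose, float]:
    """Deterministic derivative-free local minimisation around *pose*."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    ref = pose_coords(lig_xyz0, c0, pose)
    cref = ref.mean(axis=0)

    def objective(x):
        xyz = Rotation.from_rotvec(x[:3]).apply(ref - cref) + cref + x[3:]
        if np.any(np.abs(xyz.mean(axis=0) - cfg.box_center) > cfg.box_half):
            return energy + 100.0
        return eng.score(xyz)

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxiter": cfg.quench_maxiter,
                            "xtol": 1e-8, "ftol": 1e-10})
    if res.fun >= energy:
        return pose, energy
    q = Rotation.from_rotvec(res.x[:3]).as_quat()
    dq = np.array([q[3], q[0], q[1], q[2]])
    # the quench rotates about the current centroid (cref = c0 + t), so the
    # composition stays in the pose parameterisation: R' = dR R, t' = t + dt
    cand = Pose(quat_multiply(dq, pose.rotation),
                pose.translation + res.x[3:],
                ligand_model_id=pose.ligand_model_id)
    return cand, float(res.fun)


def dock_rigid(receptor: Structure, ligand: Structure, cfg: SearchConfig,
               params: ScoringParams | None = None) -> list[tuple[Pose, ScoreBreakdown]]:
    """Seeded multi-restart Metropolis Monte-Carlo rigid-body search.

    Each restart starts from a uniform random orientation and a uniform
    centroid position inside the box, refines under the score with a
    geometric cooling schedule, and contributes its best visited pose.  The
    pooled poses are deduplicated greedily at ``cfg.dedup_rmsd`` and the
    ``cfg.keep_top`` best are returned sorted ascending by total score
    (ties broken by restart index).
    """
    eng = ScoringEngine(receptor, ligand, params)
    lig_xyz0 = eng.lig.xyz.copy()
    c0 = lig_xyz0.mean(axis=0)
    radius = float(np.max(np.linalg.norm(lig_xyz0 - c0, axis=1)))
    if 2 * radius > 2 * float(np.linalg.norm(cfg.box_half)):
        raise ConfigError("search box too small to contain the ligand")

    sigma_rot = math.radians(cfg.rotation_sigma_deg)
    candidates: list[tuple[float, int, Pose]] = []
    for restart in range(cfg.n_restarts):
        rng = np.random.default_rng([cfg.seed, restart])
        q = _random_quat(rng)
        t = (cfg.box_center + rng.uniform(-cfg.box_half, cfg.box_half)) - c0
        pose = Pose(q, t, ligand_model_id=ligand.model_id)
        energy = eng.score(pose_coords(lig_xyz0, c0, pose))
        best_pose, best_energy = pose, energy
        if cfg.n_steps > 0:
            cool = (cfg.t_end / cfg.t_start) ** (1.0 / cfg.n_steps)
        temp = cfg.t_start
        for _ in range(cfg.n_steps):
            dt = rng.normal(scale=cfg.translation_sigma, size=3)
            axis = rng.normal(size=3)
            angle = rng.normal(scale=sigma_rot)
            dq = _axis_angle_quat(axis, angle)
            prop = Pose(quat_multiply(dq, pose.rotation), pose.translation + dt,
                        ligand_model_id=ligand.model_id)
            new_c = c0 + prop.translation
            if np.any(np.abs(new_c - cfg.box_center) > cfg.box_half):
                temp *= cool
                continue
            e_new = eng.score(pose_coords(lig_xyz0, c0, prop))
            if e_new <= energy or rng.random() < math.exp(-(e_new - energy) / temp):
                pose, energy = prop, e_new
                if energy < best_energy:
                    best_pose, best_energy = pose, energy
            temp *= cool
        if cfg.quench:
            best_pose, best_energy = _quench(eng, lig_xyz0, c0, best_pose,
                                             best_energy, cfg)
        candidates.append((best_energy, restart, best_pose))

    candidates.sort(key=lambda c: (c[0], c[1]))
    kept: list[tuple[float, int, Pose]] = []
    for cand in candidates:
        if all(_pose_rmsd(lig_xyz0, c0, cand[2], k[2]) > cfg.dedup_rmsd
               for k in kept):
            kept.append(cand)
        if len(kept) >= cfg.keep_top:
            break
    results = []
    for rank, (energy, _, pose) in enumerate(kept, start=1):
        pose.rank = rank
        bd = eng.breakdown(pose_coords(lig_xyz0, c0, pose))
        results.append((pose, bd))
    return results


def cluster_poses(scored_poses: list, ligand: Structure,
                  dedup_rmsd: float) -> list:
    """Greedy best-first deduplication of a ranked pose list.

    ``scored_poses`` is a list of ``Pose`` or ``(Pose, ...)`` tuples in rank
    order; a pose is kept iff its ligand RMSD to every kept pose exceeds
    ``dedup_rmsd``.
    """
    lig_xyz0 = ligand.coords()
    c0 = lig_xyz0.mean(axis=0)
    kept = []
    for item in scored_poses:
        pose = item[0] if isinstance(item, tuple) else item
        if all(_pose_rmsd(lig_xyz0, c0, pose,
                          k[0] if isinstance(k, tuple) else k) > dedup_rmsd
               for k in kept):
            kept.append(item)
    return kept
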