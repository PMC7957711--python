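"""Workflow orchestration: ensemble screening, region filtering, full reports.

``analyze_complex`` assembles every interface parameter of a receptor-ligand
complex (total score and per-residue decomposition, contact-score totals
partitioned into amino-acid and glycan receptors plus region restrictions,
interface surface metrics, per-key-residue burial, and the typed contact
lists) into one reproducible report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contacts, scoring, structio, surfaces
from .contacts import ContactThresholds
from .scoring import ScoringParams, SearchConfig
from .structio import RegionSpec, Structure, TopologyError

__all__ = [
    "AnalysisConfig",
    "EnsembleScreenResult",
    "ComplexReport",
    "ConfigError",
    "load_config",
    "screen_ensemble",
    "filter_poses_by_region",
    "analyze_complex",
    "run_full",
]

log = logging.getLogger("pepdock")

REGION_CONTACT_CUTOFF = 4.5  # Å, membership test for pose-region filtering


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    regions: dict = field(default_factory=dict)  # name -> RegionSpec
    key_residues: list = field(default_factory=list)  # (chain, number[, icode])
    scoring_params: ScoringParams = field(default_factory=ScoringParams)
    search: dict = field(default_factory=dict)  # SearchConfig kwargs sans box
    thresholds: ContactThresholds = field(default_factory=ContactThresholds)
    probe: float = 1.4
    n_points: int = 960
    seed: int = 0
    output_dir: str = "pepdock_out"

    def region(self, name: str) -> RegionSpec | None:
        return self.regions.get(name)


def _region_from_dict(name: str, d: dict) -> RegionSpec:
    members = [tuple(m) for m in d.get("members", [])]
    return RegionSpec(name=name, members=members,
                      resnames=d.get("resnames", ()),
                      glycans=bool(d.get("glycans", False)))


def load_config(path) -> AnalysisConfig:
    """Load a YAML analysis configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig()
    for name, d in (raw.get("regions") or {}).items():
        cfg.regions[name] = _region_from_dict(name, d or {})
    cfg.key_residues = [tuple(m) for m in raw.get("key_residues", [])]
    sc = raw.get("scoring") or {}
    try:
        cfg.scoring_params = ScoringParams(**sc)
    except TypeError as exc:
        raise ConfigError(f"bad scoring section: {exc}") from exc
    th = raw.get("contacts") or {}
    try:
        cfg.thresholds = ContactThresholds(**th)
    except TypeError as exc:
        raise ConfigError(f"bad contacts section: {exc}") from exc
    surf = raw.get("surface") or {}
    cfg.probe = float(surf.get("probe", 1.4))
    cfg.n_points = int(surf.get("n_points", 960))
    cfg.search = dict(raw.get("search") or {})
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = str(raw.get("output_dir", "pepdock_out"))
    return cfg


@dataclass
class EnsembleScreenResult:
    per_model_best: list  # (model_id, best total) in input order
    selected_model_id: int
    best: float
    worst: float
    sigma: float  # population standard deviation

    @classmethod
    def from_scores(cls, scores: list) -> "EnsembleScreenResult":
        vals = [v for _, v in scores]
        best = min(vals)
        sel = next(mid for mid, v in scores if v == best)
        return cls(per_model_best=scores, selected_model_id=sel,
                   best=best, worst=max(vals),
                   sigma=float(np.std(vals)))


@dataclass
class ComplexReport:
    total_score: float
    per_term: dict
    receptor_decomposition: list  # (residue label, contribution), best first
    ligand_decomposition: list
    rrcs_total: float
    rrcs_aa_total: float
    rrcs_glycan_total: float
    rrcs_region_totals: dict  # region name -> total
    toxin_aa_in_interface_percent: float
    glycan_atoms_in_interface_percent: float
    asa_ti_percent: float
    asa_navi_percent: float
    key_residue_percent_bsa: dict  # residue label -> %BSA
    contact_records: dict  # kind -> list of ContactRecord
    interface: "surfaces.InterfaceReport"
    rrcs: "contacts.RRCSMatrix"
    breakdown: "scoring.ScoreBreakdown"

    def to_dict(self) -> dict:
        def recs(lst):
            return [{
                "kind": r.kind,
                "ligand": r.ligand_label, "receptor": r.receptor_label,
                "ligand_atom": r.ligand_atom, "receptor_atom": r.receptor_atom,
                "class": r.contact_class,
                "distance": round(r.distance, 3),
                "angle": None if r.angle is None else round(r.angle, 2),
                "n_atom_pairs": r.n_atom_pairs,
            } for r in lst]
        return {
            "total_score": self.total_score,
            "per_term": self.per_term,
            "receptor_decomposition": [
                [lbl, val] for lbl, val in self.receptor_decomposition],
            "ligand_decomposition": [
                [lbl, val] for lbl, val in self.ligand_decomposition],
            "rrcs": {
                "total": self.rrcs_total,
                "aa_total": self.rrcs_aa_total,
                "glycan_total": self.rrcs_glycan_total,
                "region_totals": self.rrcs_region_totals,
            },
            "interface": {
                "toxin_aa_in_interface_percent": self.toxin_aa_in_interface_percent,
                "glycan_atoms_in_interface_percent": self.glycan_atoms_in_interface_percent,
                "asa_ti_percent": self.asa_ti_percent,
                "asa_navi_percent": self.asa_navi_percent,
                "key_residue_percent_bsa": self.key_residue_percent_bsa,
            },
            "contacts": {k: recs(v) for k, v in self.contact_records.items()},
        }


def _check_same_topology(models: list[Structure]) -> None:
    ref = [(r.name, a.name) for r in models[0].residues for a in r.atoms]
    for m in models[1:]:
        cur = [(r.name, a.name) for r in m.residues for a in r.atoms]
        if cur != ref:
            raise TopologyError(
                f"model {m.model_id} topology differs from model "
                f"{models[0].model_id}")


def screen_ensemble(receptor: Structure, models: list[Structure],
                    cfg: AnalysisConfig,
                    box_center=None, box_half=None) -> EnsembleScreenResult:
    """Dock every ensemble model once and rank models by their best score.

    Seeds are derived per model as ``seed + model index`` so the screen is
    reproducible yet models are searched independently.
    """
    if not models:
        raise ValueError("no models given")
    _check_same_topology(models)
    scores = []
    for i, model in enumerate(models):
        search = _search_config(cfg, model, box_center, box_half,
                                seed=cfg.seed + i)
        results = scoring.dock_rigid(receptor, model, search,
                                     cfg.scoring_params)
        best = results[0][1].total
        log.info("screen: model %d best score %.3f", model.model_id, best)
        scores.append((model.model_id, best))
    return EnsembleScreenResult.from_scores(scores)


def _search_config(cfg: AnalysisConfig, ligand: Structure,
                   box_center, box_half, seed=None) -> SearchConfig:
    kw = dict(cfg.search)
    if box_center is None:
        box_center = kw.pop("box_center", None)
        if box_center is None:
            box_center = ligand.coords().mean(axis=0)
    else:
        kw.pop("box_center", None)
    if box_half is None:
        box_half = kw.pop("box_half", (10.0, 10.0, 10.0))
    else:
        kw.pop("box_half", None)
    kw.setdefault("seed", cfg.seed)
    if seed is not None:
        kw["seed"] = seed
    return SearchConfig(box_center=np.asarray(box_center, float),
                        box_half=np.asarray(box_half, float), **kw)


def filter_poses_by_region(poses: list, receptor: Structure,
                           ligand: Structure, region: RegionSpec,
                           cutoff: float = REGION_CONTACT_CUTOFF) -> list:
    """Keep poses with >= 1 heavy-atom pair within *cutoff* of the region.

    ``poses`` is the ranked ``(Pose, ScoreBreakdown)`` list from
    :func:`scoring.dock_rigid`; ranking is preserved.
    """
    region_res = region.resolve(receptor)
    if not region_res:
        raise structio.SelectionError(
            f"region {region.name!r} resolved to no residues")
    region_xyz = np.array([a.position for r in region_res
                           for a in r.heavy_atoms()])
    from scipy.spatial import cKDTree
    tree = cKDTree(region_xyz)
    lig_xyz0 = ligand.coords()
    c0 = lig_xyz0.mean(axis=0)
    kept = []
    for item in poses:
        pose = item[0] if isinstance(item, tuple) else item
        xyz = scoring.pose_coords(lig_xyz0, c0, pose)
        d, _ = tree.query(xyz, k=1)
        if float(np.min(d)) <= cutoff:
            kept.append(item)
    return kept


def analyze_complex(receptor: Structure, ligand_pose: Structure,
                    cfg: AnalysisConfig) -> ComplexReport:
    """Full per-complex report: score, contact-score aggregates, surfaces,
    typed contacts and key-residue burial."""
    breakdown = scoring.score_complex(receptor, ligand_pose, cfg.scoring_params)
    rec_dec = scoring.decompose_by_residue(breakdown, side="receptor")
    lig_dec = scoring.decompose_by_residue(breakdown, side="ligand")

    matrix = contacts.rrcs_matrix(ligand_pose, receptor)
    region_totals = {}
    for name, region in cfg.regions.items():
        resolved = region.resolve(receptor)
        if resolved:
            region_totals[name] = contacts.rrcs_aggregate(
                matrix, region, partition="all", receptor=receptor)
        else:
            region_totals[name] = 0.0

    iface = surfaces.residue_bsa(ligand_pose, receptor,
                                 probe=cfg.probe, n_points=cfg.n_points)
    surfaces.interface_metrics(ligand_pose, receptor, iface)

    key_bsa = {}
    for key in cfg.key_residues:
        chain, number = key[0], int(key[1])
        icode = key[2] if len(key) > 2 else ""
        rb = iface.residue((chain, number, icode), side="receptor")
        label = f"{chain}/{number}{icode}"
        key_bsa[label] = rb.percent_bsa if rb is not None else None

    th = cfg.thresholds
    records = {
        "hbond": contacts.detect_hbonds(ligand_pose, receptor, th),
        "salt_bridge": contacts.detect_salt_bridges(ligand_pose, receptor, th),
        "pi_cation": contacts.detect_pi_cation(ligand_pose, receptor, th),
        "hydrophobic": contacts.detect_hydrophobic(ligand_pose, receptor, th),
    }
    close = contacts.close_contact_residues(ligand_pose, receptor,
                                            th.close_contact)

    labels = {r.id: r.label for r in receptor.residues}
    labels.update({r.id: r.label for r in ligand_pose.residues})
    report = ComplexReport(
        total_score=breakdown.total,
        per_term=dict(breakdown.per_term),
        receptor_decomposition=[(labels[k], v) for k, v in rec_dec],
        ligand_decomposition=[(labels[k], v) for k, v in lig_dec],
        rrcs_total=contacts.rrcs_aggregate(matrix, partition="all"),
        rrcs_aa_total=contacts.rrcs_aggregate(matrix, partition="AA"),
        rrcs_glycan_total=contacts.rrcs_aggregate(matrix, partition="glycan"),
        rrcs_region_totals=region_totals,
        toxin_aa_in_interface_percent=iface.toxin_aa_in_interface_percent,
        glycan_atoms_in_interface_percent=iface.glycan_atoms_in_interface_percent,
        asa_ti_percent=iface.asa_ti_percent,
        asa_navi_percent=iface.asa_navi_percent,
        key_residue_percent_bsa=key_bsa,
        contact_records=records,
        interface=iface,
        rrcs=matrix,
        breakdown=breakdown,
    )
    report.close_contacts = close
    return report


def _contacts_tsv(records: dict, path: Path) -> None:
    cols = ["kind", "ligand", "receptor", "class", "ligand_atom",
            "receptor_atom", "distance", "angle", "n_atom_pairs"]
    lines = ["\t".join(cols)]
    for kind in ("salt_bridge", "pi_cation", "hbond", "hydrophobic"):
        for r in records.get(kind, []):
            lines.append("\t".join([
                r.kind, r.ligand_label, r.receptor_label, r.contact_class,
                r.ligand_atom, r.receptor_atom, f"{r.distance:.3f}",
                "" if r.angle is None else f"{r.angle:.2f}",
                str(r.n_atom_pairs)]))
    path.write_text("\n".join(lines) + "\n")


def _interface_tsv(iface, path: Path) -> None:
    cols = ["side", "chain", "number", "name", "asa_isolated", "asa_complex",
            "bsa", "percent_bsa", "interface"]
    lines = ["\t".join(cols)]
    for rb in iface.residues:
        chain, number, icode = rb.residue_id
        lines.append("\t".join([
            rb.side, chain, f"{number}{icode}", rb.name,
            f"{rb.asa_isolated:.2f}", f"{rb.asa_complex:.2f}",
            f"{rb.bsa:.2f}", f"{rb.percent_bsa:.2f}",
            "1" if rb.is_interface else "0"]))
    lines.append("")
    lines.append(f"# toxin_aa_in_interface_percent\t{iface.toxin_aa_in_interface_percent:.2f}")
    lines.append(f"# glycan_atoms_in_interface_percent\t{iface.glycan_atoms_in_interface_percent:.2f}")
    lines.append(f"# asa_ti_percent\t{iface.asa_ti_percent:.2f}")
    lines.append(f"# asa_navi_percent\t{iface.asa_navi_percent:.2f}")
    path.write_text("\n".join(lines) + "\n")


def run_full(receptor_path, ligand_paths, config_path,
             mode: str = "dock", out_dir=None) -> dict:
    """End-to-end pipeline.

    ``mode="rescore"`` analyses the provided complex placement(s) directly;
    ``mode="dock"`` screens the ligand ensemble, docks the selected model,
    filters poses by the ``site3`` region when configured, and analyses the
    best surviving pose.  Returns a manifest of written files.
    """
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage=read receptor=%s", receptor_path)
    receptor = structio.read_pdb(receptor_path)
    if isinstance(receptor, list):
        receptor = receptor[0]
    structio.assign_atom_types(receptor)

    written = {}
    for lig_path in ([ligand_paths] if isinstance(ligand_paths, (str, Path))
                     else list(ligand_paths)):
        models = structio.read_pdb(lig_path)
        if isinstance(models, Structure):
            models = [models]
        for m in models:
            structio.assign_atom_types(m)
        stem = Path(lig_path).stem

        if mode == "rescore":
            selected = models[0]
            posed = selected
        elif mode == "dock":
            log.info("stage=screen ligand=%s n_models=%d seed=%d",
                     lig_path, len(models), cfg.seed)
            screen = screen_ensemble(receptor, models, cfg)
            selected = next(m for m in models
                            if m.model_id == screen.selected_model_id)
            (out / f"{stem}_screen.json").write_text(json.dumps({
                "per_model_best": screen.per_model_best,
                "selected_model_id": screen.selected_model_id,
                "best": screen.best, "worst": screen.worst,
                "sigma": screen.sigma}, indent=2))
            written[f"{stem}_screen"] = str(out / f"{stem}_screen.json")
            search = _search_config(cfg, selected, None, None, seed=cfg.seed)
            log.info("stage=dock model=%d seed=%d", selected.model_id,
                     search.seed)
            poses = scoring.dock_rigid(receptor, selected, search,
                                       cfg.scoring_params)
            region = cfg.region("site3")
            if region is not None and region.resolve(receptor):
                poses = filter_poses_by_region(poses, receptor, selected,
                                               region)
            if not poses:
                raise RuntimeError("no pose passed the region filter")
            pose_structs = [scoring.apply_pose(selected, p) for p, _ in poses]
            structio.write_pdb(pose_structs, out / f"{stem}_poses.pdb")
            written[f"{stem}_poses"] = str(out / f"{stem}_poses.pdb")
            tsv = ["rank\ttotal\t" + "\t".join(scoring.TERMS)]
            for p, bd in poses:
                tsv.append(f"{p.rank}\t{bd.total:.4f}\t" + "\t".join(
                    f"{bd.per_term[t]:.4f}" for t in scoring.TERMS))
            (out / f"{stem}_scores.tsv").write_text("\n".join(tsv) + "\n")
            written[f"{stem}_scores"] = str(out / f"{stem}_scores.tsv")
            posed = pose_structs[0]
        else:
            raise ConfigError(f"unknown mode {mode!r}")

        log.info("stage=analyze ligand=%s", lig_path)
        report = analyze_complex(receptor, posed, cfg)
        (out / f"{stem}_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        _contacts_tsv(report.contact_records, out / f"{stem}_contacts.tsv")
        _interface_tsv(report.interface, out / f"{stem}_interface.tsv")
        written[f"{stem}_report"] = str(out / f"{stem}_report.json")
        written[f"{stem}_contacts"] = str(out / f"{stem}_contacts.tsv")
        written[f"{stem}_interface"] = str(out / f"{stem}_interface.tsv")
    return written
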