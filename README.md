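# pepdock

Rigid-body peptide–protein docking, rescoring and interface analysis.

The package re-implements, as a tested and reusable pipeline, the analysis
used to characterise how peptide toxins engage a voltage-gated sodium
channel: a five-term empirical scoring function with per-residue energy
decomposition, a seeded rigid-body Monte-Carlo pose search with clustering,
residue–residue contact scores (a piecewise-linear distance ramp summed
over heavy-atom pairs), Shrake–Rupley solvent-accessible surface areas with
buried-surface interface metrics, and geometric detectors for hydrogen
bonds, salt bridges, π-cation and hydrophobic contacts — all orchestrated
as an ensemble-screening workflow with region-based pose filtering.

## Layout

| module | role |
|---|---|
| `pepdock.structio` | PDB I/O (multi-model, HETATM glycans), molecular data model, atom typing, selections, ligand RMSD |
| `pepdock.scoring` | five-term empirical score, per-residue decomposition, Monte-Carlo rigid docking, pose clustering |
| `pepdock.contacts` | residue–residue contact scores and aggregates; H-bond / salt-bridge / π-cation / hydrophobic / close-contact detectors |
| `pepdock.surfaces` | Shrake–Rupley SASA, per-residue BSA, interface percentage metrics |
| `pepdock.pipeline` | ensemble screening, site-region pose filtering, full complex reports, YAML config |
| `pepdock.synth` | deterministic synthetic complexes with planted, machine-readable ground truth |

A default analysis configuration for the sodium-channel receptor (site-3
region residue list, S4 subset, key residues for burial reporting) ships
as `pepdock/data/navpas_site3.yaml`.

## CLI

```sh
# rigid docking into a box (centre + half-widths, Å)
pepdock dock --receptor rec.pdb --ligand lig.pdb \
    --box 10,2,4,8,8,8 --restarts 32 --seed 1 \
    --out poses.pdb --scores scores.tsv

# analyse a complex that is already assembled (no search)
pepdock rescore --receptor rec.pdb --complex placed.pdb --config cfg.yaml

# screen a multi-model NMR-style ensemble by best docking score
pepdock screen --receptor rec.pdb --ensemble toxin.pdb --config cfg.yaml

# full pipeline: screen -> dock -> region filter -> report
pepdock analyze --receptor rec.pdb --ligand toxin.pdb --config cfg.yaml

# write the canonical synthetic fixture + ground truth
pepdock synth --out-dir fixture/
```

Reports are JSON (scores, contact-score aggregates, interface metrics,
per-key-residue burial) plus TSV tables (contacts, per-residue surface
areas) and multi-MODEL PDB pose files.

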