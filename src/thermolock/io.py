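"""Formats and persistence: ensembles as multi-model PDB, tables as TSV,
configuration as YAML/TOML, and run manifests as JSON.

The canonical interchange format for ensembles is a directory with one
multi-model PDB per temperature (coordinates in Å on disk, nm in memory),
per-rung energy tables, the exchange log, the serialized topology, and a
manifest.  Externally produced all-atom trajectories (multi-model PDB, or
DCD/XTC next to a PDB topology) are read through mdtraj and adapted to the
metric suite via :func:`chain_view_from_mdtraj`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from thermolock.energy import EnergyModel
from thermolock.metrics import ChainView, HBondSiteSet
from thermolock.sampler import EnsembleSet, Trajectory
from thermolock.topology import ChainTopology

NM_PER_ANGSTROM = 0.1

_CATEGORY_RESNAME = {"sticker": "TYR", "hydrophobic_spacer": "LEU",
                     "polar_spacer": "SER", "flexible": "GLY"}


class EnsembleIOError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Multi-model PDB


def _template_atoms(topology: ChainTopology):
    import biotite.structure as struc

    n = topology.n_beads
    atoms = struc.AtomArray(n)
    chain_ids = np.array([chr(ord("A") + c) for c in topology.bead_chain_ids()])
    res_ids = topology.bead_residue_ids() % topology.n_residues + 1
    names = np.where(np.arange(n) % 2 == 0, "BB", "SC")
    res_names = np.array([_CATEGORY_RESNAME[topology.residues[r % topology.n_residues].category]
                          for r in topology.bead_residue_ids()])
    atoms.chain_id = chain_ids
    atoms.res_id = res_ids.astype(int)
    atoms.res_name = res_names
    atoms.atom_name = names
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    return atoms


def write_trajectory_pdb(path, trajectory: Trajectory, topology: ChainTopology):
    """One MODEL per stored frame; coordinates converted nm → Å."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = _template_atoms(topology)
    stack = struc.AtomArrayStack(trajectory.n_frames, topology.n_beads)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, atoms.get_annotation(cat))
    stack.coord = np.asarray(trajectory.coordinates) / NM_PER_ANGSTROM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _validate_multimodel_pdb(path):
    """Detect truncated trajectories up front, naming the failing frame."""
    n_model = n_end = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                n_model += 1
            elif line.startswith("ENDMDL"):
                n_end += 1
    if n_model and n_model != n_end:
        raise EnsembleIOError(
            f"{path}: truncated trajectory — frame {n_model - 1} has no ENDMDL")


def read_trajectory_pdb(path, temperature: float = float("nan")) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (coordinates in nm)."""
    from biotite.structure.io.pdb import PDBFile

    _validate_multimodel_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise EnsembleIOError(f"{path}: malformed PDB ({exc})") from exc
    coords = np.asarray(stack.coord) * NM_PER_ANGSTROM
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    return Trajectory(coordinates=coords,
                      sweep_indices=np.arange(n, dtype=np.int64),
                      energies=np.full(n, np.nan),
                      temperature=temperature)


# --------------------------------------------------------------------------
# Ensemble directories


def write_ensemble(directory, ensemble: EnsembleSet) -> Path:
    """Persist an EnsembleSet: per-rung PDB + energies, logs, topology."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for t, tr in zip(ensemble.temperatures, ensemble.trajectories):
        stem = f"T{t:.1f}K"
        write_trajectory_pdb(d / f"{stem}.pdb", tr, ensemble.topology)
        pd.DataFrame({"sweep": tr.sweep_indices,
                      "energy_kj_mol": tr.energies}).to_csv(
            d / f"{stem}_energies.tsv", sep="\t", index=False)
    (d / "topology.json").write_text(json.dumps(ensemble.topology.to_dict()))
    (d / "model.json").write_text(json.dumps(ensemble.model.to_dict()))
    log = {
        "temperatures": list(ensemble.temperatures),
        "exchange_attempts": ensemble.exchange_attempts.tolist(),
        "exchange_accepts": ensemble.exchange_accepts.tolist(),
        "seed": ensemble.seed,
        "config_digest": ensemble.config_digest,
        "equilibration_fraction": ensemble.equilibration_fraction,
    }
    (d / "exchange_log.json").write_text(json.dumps(log, indent=1))
    np.savetxt(d / "replica_walk.tsv", ensemble.replica_walk, fmt="%d",
               delimiter="\t")
    return d


def read_ensemble(directory) -> EnsembleSet:
    """Load an ensemble directory written by :func:`write_ensemble`."""
    d = Path(directory)
    log = json.loads((d / "exchange_log.json").read_text())
    topology = ChainTopology.from_dict(json.loads((d / "topology.json").read_text()))
    model_file = d / "model.json"
    model = EnergyModel(**json.loads(model_file.read_text())) \
        if model_file.exists() else EnergyModel()
    trajectories = []
    for t in log["temperatures"]:
        stem = f"T{t:.1f}K"
        tr = read_trajectory_pdb(d / f"{stem}.pdb", temperature=t)
        etab = d / f"{stem}_energies.tsv"
        if etab.exists():
            df = pd.read_csv(etab, sep="\t")
            if len(df) != tr.n_frames:
                raise EnsembleIOError(
                    f"{etab}: {len(df)} energies for {tr.n_frames} frames")
            tr.sweep_indices = df["sweep"].to_numpy(dtype=np.int64)
            tr.energies = df["energy_kj_mol"].to_numpy(dtype=float)
        trajectories.append(tr)
    walk_file = d / "replica_walk.tsv"
    walk = np.loadtxt(walk_file, dtype=np.int64, delimiter="\t", ndmin=2) \
        if walk_file.exists() else np.zeros((1, len(trajectories)), dtype=np.int64)
    return EnsembleSet(topology=topology, model=model,
                       temperatures=tuple(log["temperatures"]),
                       trajectories=trajectories,
                       exchange_attempts=np.asarray(log["exchange_attempts"],
                                                    dtype=np.int64),
                       exchange_accepts=np.asarray(log["exchange_accepts"],
                                                   dtype=np.int64),
                       replica_walk=walk, seed=log["seed"],
                       config_digest=log["config_digest"],
                       equilibration_fraction=log["equilibration_fraction"])


# --------------------------------------------------------------------------
# All-atom trajectories (mdtraj)


def load_mdtraj(trajectory_path, topology_path: Optional[str] = None):
    """Load multi-model PDB, or DCD/XTC paired with a PDB topology."""
    import mdtraj as md

    p = str(trajectory_path)
    if p.endswith(".pdb"):
        return md.load(p)
    if topology_path is None:
        raise EnsembleIOError("DCD/XTC input needs a PDB topology file")
    return md.load(p, top=str(topology_path))


_DEFAULT_RADII = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "H": 0.12,
                  "P": 0.18}


def chain_view_from_mdtraj(traj) -> ChainView:
    """Adapt an all-atom mdtraj trajectory to the metric suite.

    Side-chain selection: heavy atoms outside the backbone (N, CA, C, O);
    glycine-like residues end up with an empty selection and are skipped by
    the contact rule.  H-bond sites: backbone N donors with their amide
    hydrogen where present, carbonyl O acceptors.
    """
    top = traj.topology
    n_chains = top.n_chains
    per_chain = [c.n_residues for c in top.chains]
    if len(set(per_chain)) != 1:
        raise EnsembleIOError(
            f"chains have unequal residue counts {per_chain}; the metric "
            "suite expects identical chains")
    backbone_names = {"N", "CA", "C", "O", "OXT"}
    sidechain_atoms, backbone_atom = [], []
    chain_of_residue = []
    d_at, d_h, d_res, a_at, a_res = [], [], [], [], []
    for ci, chain in enumerate(top.chains):
        for res in chain.residues:
            rid = len(chain_of_residue)
            chain_of_residue.append(ci)
            atoms = list(res.atoms)
            sc = [a.index for a in atoms
                  if a.element.symbol != "H" and a.name not in backbone_names]
            sidechain_atoms.append(np.array(sc, dtype=np.int64))
            ca = [a.index for a in atoms if a.name == "CA"]
            backbone_atom.append(ca[0] if ca else atoms[0].index)
            n_atom = [a.index for a in atoms if a.name == "N"]
            h_atom = [a.index for a in atoms if a.name in ("H", "HN", "H1")]
            if n_atom:
                d_at.append(n_atom[0])
                d_h.append(h_atom[0] if h_atom else -1)
                d_res.append(rid)
            o_atom = [a.index for a in atoms if a.name == "O"]
            if o_atom:
                a_at.append(o_atom[0])
                a_res.append(rid)
    sites = HBondSiteSet(
        donor_atoms=np.array(d_at, dtype=np.int64),
        donor_h=np.array(d_h, dtype=np.int64),
        donor_residue=np.array(d_res, dtype=np.int64),
        acceptor_atoms=np.array(a_at, dtype=np.int64),
        acceptor_residue=np.array(a_res, dtype=np.int64))
    masses = np.array([a.element.mass for a in top.atoms])
    radii = np.array([_DEFAULT_RADII.get(a.element.symbol, 0.17)
                      for a in top.atoms])
    return ChainView(n_chains=n_chains, residues_per_chain=per_chain[0],
                     chain_of_residue=np.array(chain_of_residue),
                     sidechain_atoms=sidechain_atoms,
                     backbone_atom=np.array(backbone_atom, dtype=np.int64),
                     masses=masses, radii=radii, hbond_sites=sites,
                     box=None, kind="all-atom")


# --------------------------------------------------------------------------
# Proteomics tables


def read_peptide_table(path) -> pd.DataFrame:
    """Long TSV: protein, peptide, replicate, condition, area ('' / NA missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["", "NA"])
    return df


def read_protein_table(path):
    """Wide TSV: protein column plus ``bait_<r>`` / ``control_<r>`` columns."""
    from thermolock.proteomics import ProteinQuant

    df = pd.read_csv(path, sep="\t", na_values=["", "NA"]).set_index("protein")
    cols = []
    for c in df.columns:
        cond, _, rep = c.rpartition("_")
        if cond not in ("bait", "control") or not rep.isdigit():
            raise ValueError(f"unrecognized protein-table column {c!r}")
        cols.append((cond, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
    return ProteinQuant(areas=df.sort_index(axis=1), provenance="direct")


def write_protein_table(path, quant) -> None:
    df = quant.areas.copy()
    df.columns = [f"{c}_{r}" for c, r in df.columns]
    df.to_csv(path, sep="\t", index_label="protein")


def write_enrichment_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="protein")


# --------------------------------------------------------------------------
# Config and manifest


def load_config(path) -> dict:
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    if p.suffix == ".toml":
        import tomllib
        return tomllib.loads(text)
    raise ValueError(f"unsupported config format {p.suffix!r} (use YAML/TOML)")


@dataclasses.dataclass
class RunManifest:
    """Provenance of one pipeline invocation."""

    tool: str
    version: str
    command: str
    seed: Optional[int]
    config_digest: str
    inputs: list
    outputs: list
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")


def write_manifest(directory, manifest: RunManifest) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    return path


def digest_of(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()
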