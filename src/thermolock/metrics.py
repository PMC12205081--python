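"""Trajectory metrics for coarse-grained and all-atom ensembles.

All operations take a stack of frames ``(F, A, 3)`` in nm together with a
:class:`ChainView` describing which atoms belong to which residue.  The same
definitions apply to both resolutions:

* side-chain contact: minimum side-chain heavy-atom (or side-chain bead)
  distance below 0.6 nm, intramolecular pairs closer than 3 residues in
  sequence excluded;
* hydrogen bond: acceptor–donor distance within 0.35 nm and
  acceptor–donor–hydrogen angle (vertex at the donor) below 30°.  Coarse
  bead models carry no explicit hydrogens, so CG site sets set the hydrogen
  index to -1 and the angle criterion is vacuous for those donors;
* β-strand: a residue is strand in a frame if it takes part in two
  consecutive rungs of an inter-segment hydrogen-bond ladder while its
  local backbone is extended (all-atom input instead goes through DSSP,
  see :func:`beta_strand_probability`);
* SASA: Shrake–Rupley point sampling with configurable probe and density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from thermolock.topology import ChainTopology


# --------------------------------------------------------------------------
# Configuration and views


@dataclass(frozen=True)
class AnalysisConfig:
    """Cutoffs and sampling parameters of the metric suite (nm, degrees)."""

    contact_cutoff: float = 0.6
    adjacency_exclusion: int = 3  # exclude intramolecular pairs |i-j| <= this
    hbond_distance_cutoff: float = 0.35
    hbond_angle_cutoff: float = 30.0
    hbond_min_separation: int = 3  # intramolecular D/A residue separation
    sasa_probe_radius: float = 0.14
    sasa_points: int = 960
    equilibration_fraction: float = 0.2
    block_count: int = 10
    strand_extension_min: float = 0.56  # local backbone extension for strand

    def __post_init__(self):
        if self.contact_cutoff <= 0 or self.hbond_distance_cutoff <= 0 \
                or self.sasa_probe_radius <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.hbond_angle_cutoff < 90:
            raise ValueError("hbond_angle_cutoff must lie in (0, 90) degrees")
        if self.sasa_points < 60:
            raise ValueError("sasa_points must be >= 60")


@dataclass
class HBondSiteSet:
    """Donor/hydrogen/acceptor atom indices with residue assignment.

    ``donor_h`` entries of -1 mean "no explicit hydrogen" (CG pseudo-sites);
    the angle criterion is then skipped for that donor.
    """

    donor_atoms: np.ndarray      # (nd,)
    donor_h: np.ndarray          # (nd,) hydrogen attached to each donor, -1 ok
    donor_residue: np.ndarray    # (nd,) global residue id
    acceptor_atoms: np.ndarray   # (na,)
    acceptor_residue: np.ndarray

    def __post_init__(self):
        if len(self.donor_atoms) != len(self.donor_h) \
                or len(self.donor_atoms) != len(self.donor_residue):
            raise ValueError("donor arrays must have equal length")


@dataclass
class ChainView:
    """Residue-level view of an atom (or bead) system.

    ``sidechain_atoms[r]`` lists the atoms used for the side-chain contact
    rule of residue ``r``; residues without side-chain atoms (glycine-like)
    get an empty array and are skipped.  ``backbone_atom[r]`` is the single
    trace atom (CG backbone bead / Cα) used for strand-extension geometry.
    """

    n_chains: int
    residues_per_chain: int
    chain_of_residue: np.ndarray           # (n_res_total,)
    sidechain_atoms: list                  # list of int arrays
    backbone_atom: np.ndarray              # (n_res_total,)
    masses: np.ndarray                     # per atom
    radii: np.ndarray                      # per atom, for SASA
    hbond_sites: Optional[HBondSiteSet] = None
    box: Optional[float] = None            # periodic cube edge, or None
    kind: str = "cg"

    @property
    def n_residues_total(self) -> int:
        return self.n_chains * self.residues_per_chain

    @staticmethod
    def from_topology(topology: ChainTopology) -> "ChainView":
        """View of the coarse-grained two-bead model: side-chain bead per
        residue, backbone beads as both H-bond donors and acceptors with no
        explicit hydrogen."""
        ntot = topology.n_residues_total
        bb = np.array([topology.backbone_bead(i % topology.n_residues + 1,
                                              i // topology.n_residues)
                       for i in range(ntot)], dtype=np.int64)
        sc = bb + 1
        res_ids = np.arange(ntot)
        sites = HBondSiteSet(
            donor_atoms=bb.copy(),
            donor_h=np.full(ntot, -1, dtype=np.int64),
            donor_residue=res_ids.copy(),
            acceptor_atoms=bb.copy(),
            acceptor_residue=res_ids.copy(),
        )
        masses = np.ones(topology.n_beads)
        return ChainView(
            n_chains=topology.n_chains,
            residues_per_chain=topology.n_residues,
            chain_of_residue=np.repeat(np.arange(topology.n_chains),
                                       topology.n_residues),
            sidechain_atoms=[np.array([s]) for s in sc],
            backbone_atom=bb,
            masses=masses,
            radii=topology.bead_radii(),
            hbond_sites=sites,
            box=topology.box_edge,
            kind="cg",
        )


def _pair_distances(a: np.ndarray, b: np.ndarray, box: Optional[float]) -> np.ndarray:
    """Distances between two point sets (..., n, 3) x (..., m, 3) with the
    minimum-image convention when a box is given."""
    d = a[..., :, None, :] - b[..., None, :, :]
    if box is not None:
        d = d - box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


# --------------------------------------------------------------------------
# Scalar geometry metrics


def radius_of_gyration(coords: np.ndarray, masses: Optional[np.ndarray] = None) -> np.ndarray:
    """Mass-weighted radius of gyration, nm.

    Accepts a single frame ``(A, 3)`` or a stack ``(F, A, 3)``; returns a
    scalar or per-frame array.  Computed on raw (unwrapped) coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    c = coords[None] if single else coords
    if c.shape[1] == 0:
        raise ValueError("radius_of_gyration needs at least one particle")
    if masses is None:
        m = np.ones(c.shape[1])
    else:
        m = np.asarray(masses, dtype=float)
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    w = m / m.sum()
    com = np.einsum("fad,a->fd", c, w)
    sq = ((c - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("fa,a->f", sq, w))
    return float(rg[0]) if single else rg


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(coords: np.ndarray, radii: np.ndarray,
         config: AnalysisConfig = AnalysisConfig()) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area per particle, nm².

    Points are sampled on each particle's solvent sphere (radius + probe)
    and counted accessible when outside every neighbour's solvent sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    probe = config.sasa_probe_radius
    rs = radii + probe
    pts = sphere_points(config.sasa_points)
    out = np.empty(n)
    for i in range(n):
        p = coords[i] + rs[i] * pts
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.where((d < rs + rs[i]) & (np.arange(n) != i))[0]
        if nb.size:
            dd = np.linalg.norm(p[:, None, :] - coords[nb][None, :, :], axis=2)
            buried = (dd < rs[nb][None, :]).any(axis=1)
        else:
            buried = np.zeros(len(p), dtype=bool)
        out[i] = (~buried).mean() * 4.0 * np.pi * rs[i] ** 2
    return out


def total_sasa(coords: np.ndarray, radii: np.ndarray,
               config: AnalysisConfig = AnalysisConfig()) -> float:
    return float(sasa(coords, radii, config).sum())


# --------------------------------------------------------------------------
# Contacts


def _residue_min_distance(frame: np.ndarray, view: ChainView) -> np.ndarray:
    """(n_res, n_res) matrix of minimum side-chain atom distances; residues
    without side-chain atoms give +inf rows/columns."""
    nres = view.n_residues_total
    atoms = [np.asarray(a, dtype=int) for a in view.sidechain_atoms]
    order = np.concatenate([a for a in atoms if a.size]) if nres else np.array([], int)
    sizes = [a.size for a in atoms]
    keep = [r for r in range(nres) if sizes[r] > 0]
    if not keep:
        return np.full((nres, nres), np.inf)
    coords = frame[order]
    d = _pair_distances(coords, coords, view.box)
    starts = np.cumsum([0] + [sizes[r] for r in keep[:-1]])
    # two-pass segmented min over rows then columns
    rowmin = np.minimum.reduceat(d, starts, axis=0)
    blockmin = np.minimum.reduceat(rowmin, starts, axis=1)
    out = np.full((nres, nres), np.inf)
    idx = np.array(keep)
    out[np.ix_(idx, idx)] = blockmin
    return out


def side_chain_contacts(frame: np.ndarray, view: ChainView,
                        config: AnalysisConfig = AnalysisConfig(),
                        scope: str = "intramolecular") -> np.ndarray:
    """Boolean contact matrix between residues of one frame.

    Intramolecular scope keeps same-chain pairs with sequence separation
    greater than ``adjacency_exclusion``; intermolecular scope keeps
    different-chain pairs with no exclusion.
    """
    if scope not in ("intramolecular", "intermolecular"):
        raise ValueError("scope must be intramolecular or intermolecular")
    dmin = _residue_min_distance(frame, view)
    contact = dmin < config.contact_cutoff
    np.fill_diagonal(contact, False)
    nres = view.n_residues_total
    chain = view.chain_of_residue
    same = chain[:, None] == chain[None, :]
    if scope == "intramolecular":
        pos = np.arange(nres) % view.residues_per_chain
        sep = np.abs(pos[:, None] - pos[None, :])
        contact &= same & (sep > config.adjacency_exclusion)
    else:
        contact &= ~same
    return contact


@dataclass
class ContactMap:
    """Per-pair contact frequencies over the post-equilibration frames."""

    matrix: np.ndarray  # (residues_per_chain, residues_per_chain) in [0, 1]
    n_frames: int
    scope: str
    temperature: float

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("contact map must be symmetric")
        if m.size and (m.min() < -1e-12 or m.max() > 1 + 1e-12):
            raise ValueError("contact frequencies must lie in [0, 1]")


def contact_map(frames: np.ndarray, view: ChainView,
                config: AnalysisConfig = AnalysisConfig(),
                scope: str = "intramolecular",
                temperature: float = float("nan"),
                discard_equilibration: bool = True) -> ContactMap:
    """Accumulate per-residue-pair contact frequencies over frames.

    The matrix is reduced to ``residues_per_chain`` square: intramolecular
    frequencies are averaged over chains; intermolecular frequencies pair
    residue i of one chain with residue j of the other, symmetrized.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    start = int(config.equilibration_fraction * len(frames)) if discard_equilibration else 0
    used = frames[start:]
    if len(used) == 0:
        raise ValueError("no frames left after equilibration discard")
    npc = view.residues_per_chain
    acc = np.zeros((npc, npc))
    for f in used:
        c = side_chain_contacts(f, view, config, scope)
        if scope == "intramolecular":
            per = np.zeros((npc, npc))
            for ch in range(view.n_chains):
                s = ch * npc
                per += c[s:s + npc, s:s + npc]
            acc += per / view.n_chains
        else:
            cross = c[:npc, npc:2 * npc]
            acc += 0.5 * (cross + cross.T)
    return ContactMap(matrix=acc / len(used), n_frames=len(used),
                      scope=scope, temperature=temperature)


# --------------------------------------------------------------------------
# Hydrogen bonds


def count_hbonds(frame: np.ndarray, sites: HBondSiteSet,
                 config: AnalysisConfig = AnalysisConfig(),
                 scope: str = "intramolecular",
                 chain_of_residue: Optional[np.ndarray] = None,
                 residues_per_chain: Optional[int] = None,
                 box: Optional[float] = None):
    """Count D–H…A hydrogen bonds in one frame.

    A bond requires donor–acceptor distance within the cutoff and, when the
    donor has an explicit hydrogen, an acceptor–donor–hydrogen angle (vertex
    at the donor, between the D→A and D→H directions) strictly below the
    angle cutoff.  Returns ``(count, list of (donor_atom, acceptor_atom))``.
    """
    if len(sites.donor_atoms) == 0 or len(sites.acceptor_atoms) == 0:
        return 0, []
    d_xyz = frame[sites.donor_atoms]
    a_xyz = frame[sites.acceptor_atoms]
    dist = _pair_distances(d_xyz, a_xyz, box)
    ok = dist <= config.hbond_distance_cutoff

    dres = sites.donor_residue[:, None]
    ares = sites.acceptor_residue[None, :]
    ok &= dres != ares
    if chain_of_residue is not None:
        same = chain_of_residue[dres] == chain_of_residue[ares]
        if scope == "intramolecular":
            ok &= same
            if residues_per_chain is not None:
                pos_d = sites.donor_residue[:, None] % residues_per_chain
                pos_a = sites.acceptor_residue[None, :] % residues_per_chain
                ok &= np.abs(pos_d - pos_a) >= config.hbond_min_separation
        elif scope == "intermolecular":
            ok &= ~same
    elif scope == "intramolecular":
        ok &= np.abs(dres - ares) >= config.hbond_min_separation

    # angle criterion where a hydrogen exists
    has_h = sites.donor_h >= 0
    if has_h.any():
        hi = np.where(has_h)[0]
        dh = frame[sites.donor_h[hi]] - d_xyz[hi]
        if box is not None:
            dh = dh - box * np.round(dh / box)
        da = a_xyz[None, :, :] - d_xyz[hi][:, None, :]
        if box is not None:
            da = da - box * np.round(da / box)
        nh = np.linalg.norm(dh, axis=1)
        na = np.linalg.norm(da, axis=2)
        cosang = np.einsum("dk,dak->da", dh, da) / \
            np.maximum(nh[:, None] * na, 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok[hi] &= ang < config.hbond_angle_cutoff

    di, ai = np.where(ok)
    bonds = [(int(sites.donor_atoms[d]), int(sites.acceptor_atoms[a]))
             for d, a in zip(di, ai)]
    return len(bonds), bonds


def hbond_series(frames: np.ndarray, view: ChainView,
                 config: AnalysisConfig = AnalysisConfig(),
                 scope: str = "intramolecular") -> np.ndarray:
    """Per-frame hydrogen-bond counts for an ensemble."""
    if view.hbond_sites is None:
        raise ValueError("view has no hydrogen-bond site set")
    frames = np.asarray(frames, dtype=float)
    out = np.empty(len(frames))
    for f in range(len(frames)):
        out[f], _ = count_hbonds(frames[f], view.hbond_sites, config, scope,
                                 chain_of_residue=view.chain_of_residue,
                                 residues_per_chain=view.residues_per_chain,
                                 box=view.box)
    return out


# --------------------------------------------------------------------------
# β-strand probability


def _ladder_bonds(frame: np.ndarray, view: ChainView, config: AnalysisConfig) -> np.ndarray:
    """Boolean matrix of backbone ladder rungs: trace-atom pairs within the
    H-bond distance cutoff, separated by at least ``hbond_min_separation``
    residues in the same chain (inter-segment) or on different chains."""
    bb = frame[view.backbone_atom]
    d = _pair_distances(bb, bb, view.box)
    ok = d <= config.hbond_distance_cutoff
    np.fill_diagonal(ok, False)
    nres = view.n_residues_total
    pos = np.arange(nres) % view.residues_per_chain
    chain = view.chain_of_residue
    same = chain[:, None] == chain[None, :]
    sep = np.abs(pos[:, None] - pos[None, :])
    ok &= (~same) | (sep >= config.hbond_min_separation)
    return ok


def beta_strand_flags(frame: np.ndarray, view: ChainView,
                      config: AnalysisConfig = AnalysisConfig()) -> np.ndarray:
    """Per-residue strand assignment of one frame (ladder rule).

    Residue i is strand iff some partner j forms a rung (i, j) together with
    an adjacent rung ((i±1, j∓1) or (i±1, j±1)) and both partners are
    locally extended (|trace(i-1) - trace(i+1)| above the configured
    minimum).
    """
    if view.residues_per_chain < 5:
        raise ValueError("strand assignment needs chains of >= 5 residues")
    rungs = _ladder_bonds(frame, view, config)
    nres = view.n_residues_total
    bb = frame[view.backbone_atom]

    ext = np.full(nres, np.inf)
    pos = np.arange(nres) % view.residues_per_chain
    inner = (pos > 0) & (pos < view.residues_per_chain - 1)
    prev_bb = bb[np.maximum(np.arange(nres) - 1, 0)]
    next_bb = bb[np.minimum(np.arange(nres) + 1, nres - 1)]
    dv = next_bb - prev_bb
    if view.box is not None:
        dv = dv - view.box * np.round(dv / view.box)
    ext_all = np.linalg.norm(dv, axis=1)
    ext[inner] = ext_all[inner]
    extended = ext >= config.strand_extension_min

    flags = np.zeros(nres, dtype=bool)
    ii, jj = np.where(rungs)
    rset = rungs
    for i, j in zip(ii, jj):
        if not (extended[i] and extended[j]):
            continue
        for di, dj in ((1, -1), (1, 1), (-1, 1), (-1, -1)):
            i2, j2 = i + di, j + dj
            if 0 <= i2 < nres and 0 <= j2 < nres and rset[i2, j2]:
                flags[i] = True
                break
    return flags


def beta_strand_probability(frames: np.ndarray, view: ChainView,
                            config: AnalysisConfig = AnalysisConfig(),
                            discard_equilibration: bool = True) -> np.ndarray:
    """Per-residue strand probability over the retained frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    start = int(config.equilibration_fraction * len(frames)) if discard_equilibration else 0
    used = frames[start:]
    if len(used) == 0:
        raise ValueError("no frames left after equilibration discard")
    acc = np.zeros(view.n_residues_total)
    for f in used:
        acc += beta_strand_flags(f, view, config)
    prob = acc / len(used)
    npc = view.residues_per_chain
    if view.n_chains > 1:
        prob = prob.reshape(view.n_chains, npc).mean(axis=0)
    return prob


# --------------------------------------------------------------------------
# Ensemble averaging


@dataclass
class MetricSeries:
    """A named per-frame metric with its ensemble mean and block-bootstrap
    standard error after equilibration discard."""

    name: str
    values: np.ndarray
    frame_indices: np.ndarray
    mean: float
    se: float
    temperature: float = float("nan")
    n_discarded: int = 0

    def ci(self, z: float = 1.96) -> tuple[float, float]:
        return self.mean - z * self.se, self.mean + z * self.se


def ensemble_average(values: Sequence[float],
                     equilibration_fraction: float = 0.2,
                     block_count: int = 10,
                     name: str = "metric",
                     temperature: float = float("nan"),
                     n_boot: int = 200,
                     seed: int = 0) -> MetricSeries:
    """Discard the leading fraction, then mean and block-bootstrap SE.

    The retained series is split into ``block_count`` contiguous blocks;
    the SE is the standard deviation of means over bootstrap resamples of
    whole blocks (seeded, hence deterministic).
    """
    values = np.asarray(values, dtype=float)
    n_discard = int(equilibration_fraction * len(values))
    kept = values[n_discard:]
    if len(kept) < 2:
        raise ValueError("need at least 2 retained frames")
    if len(kept) < block_count:
        raise ValueError(
            f"{len(kept)} retained frames cannot fill {block_count} blocks")
    mean = float(kept.mean())
    blocks = np.array_split(kept, block_count)
    bmeans = np.array([b.mean() for b in blocks])
    bsizes = np.array([len(b) for b in blocks], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, block_count, size=(n_boot, block_count))
    w = bsizes[idx]
    boot = (bmeans[idx] * w).sum(axis=1) / w.sum(axis=1)
    se = float(boot.std(ddof=1))
    return MetricSeries(name=name, values=kept,
                        frame_indices=np.arange(n_discard, len(values)),
                        mean=mean, se=se, temperature=temperature,
                        n_discarded=n_discard)
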