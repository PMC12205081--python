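"""Coarse-grained energy model for the LCST sticker–spacer lock polymer.

Terms (all kJ/mol, lengths nm, periodic minimum-image convention):

* harmonic backbone and side-chain bonds; harmonic backbone bending angles;
* purely repulsive excluded volume, ``0.5*k_rep*(sigma_ij - r)^2`` for
  ``r < sigma_ij`` with ``sigma_ij`` the sum of bead radii (finite at
  overlap, which keeps Metropolis sampling robust to poor starts);
* side-chain pair attraction, a quartic well
  ``-eps_ij(T) * (1 - (r/rc)^2)^2`` for ``r < rc``.  The well depth combines
  per-residue epsilons geometrically and, for sticker/hydrophobic pairs,
  grows linearly with temperature:
  ``eps_ij(T) = sqrt(eps_i*eps_j) * max(0, 1 + alpha*(T - T_ref)/T_ref)``.
  A positive ``alpha`` encodes LCST behaviour — the solvent-entropy-driven
  strengthening of hydrophobic/aromatic attraction on heating, made explicit
  because solvent is not represented;
* lock pseudo-H-bonds: Gaussian wells between the backbone beads of the
  registry pairs, gated by local strand extension and sharing a small
  cooperative bonus between adjacent intact rungs (see
  :func:`thermolock._kernels.lock_energy`).  The well depth weakens
  linearly with temperature,
  ``eps_lock(T) = eps_lock * max(0, 1 - alpha_lock*(T - T_ref)/T_ref)`` —
  the implicit-solvent counterpart of backbone hydrogen bonds competing
  with solvent on heating, the exact mirror of the LCST strengthening of
  sticker contacts.  Both coefficients are free-energy parameterizations of
  solvent entropy that this model does not represent explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from thermolock.topology import ChainTopology
from thermolock import _kernels


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the coarse-grained Hamiltonian."""

    k_bond: float = 1000.0        # kJ/mol/nm^2
    k_angle: float = 1.0          # kJ/mol/rad^2
    theta0: float = 2.094         # rad (120 deg), backbone bending minimum
    k_repulsion: float = 400.0    # kJ/mol/nm^2
    attraction_cutoff: float = 0.8  # nm
    alpha: float = 10.0            # LCST temperature coefficient, >= 0
    reference_temperature: float = 280.0  # K

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0 (LCST encoding)")
        for name in ("k_bond", "k_repulsion", "attraction_cutoff",
                     "reference_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def temperature_factor(self, temperature: float, sticky: bool = True) -> float:
        """Multiplier applied to sticker/hydrophobic pair well depths.

        Non-decreasing in temperature for ``alpha > 0``; clamped at zero.
        """
        if not sticky:
            return 1.0
        t = 1.0 + self.alpha * (temperature - self.reference_temperature) \
            / self.reference_temperature
        return max(0.0, t)

    def to_dict(self) -> dict:
        return asdict(self)


class SimArrays:
    """Flat array representation of (topology, model) consumed by the
    numerical kernels.  Built once per run; the pairwise well-depth matrix
    is rebuilt per ladder rung via :meth:`eps_matrix`."""

    def __init__(self, topology: ChainTopology, model: EnergyModel):
        self.topology = topology
        self.model = model
        n = topology.n_beads
        nres = topology.n_residues
        bpr = topology.beads_per_residue
        self.n_beads = n

        self.sigma = topology.bead_radii()
        self.chain_of_bead = topology.bead_chain_ids()
        self.res_of_bead = topology.bead_residue_ids()

        # bonds: backbone i-(i+1) within each chain, plus backbone-sidechain
        bi, bj, br0 = [], [], []
        for c in range(topology.n_chains):
            for i in range(1, nres + 1):
                bb = topology.backbone_bead(i, c)
                if bpr == 2:
                    bi.append(bb); bj.append(topology.sidechain_bead(i, c))
                    br0.append(topology.sidechain_bond_length)
                if i < nres:
                    bi.append(bb); bj.append(topology.backbone_bead(i + 1, c))
                    br0.append(topology.backbone_bond_length)
        self.bond_i = np.array(bi, dtype=np.int64)
        self.bond_j = np.array(bj, dtype=np.int64)
        self.bond_r0 = np.array(br0)
        self.bond_k = np.full(len(bi), model.k_bond)

        # backbone bending angles
        ai, aj, ak = [], [], []
        for c in range(topology.n_chains):
            for i in range(2, nres):
                ai.append(topology.backbone_bead(i - 1, c))
                aj.append(topology.backbone_bead(i, c))
                ak.append(topology.backbone_bead(i + 1, c))
        self.ang_i = np.array(ai, dtype=np.int64)
        self.ang_j = np.array(aj, dtype=np.int64)
        self.ang_k = np.array(ak, dtype=np.int64)
        self.ang_th0 = np.full(len(ai), model.theta0)
        self.ang_ka = np.full(len(ai), model.k_angle)

        # nonbonded exclusions: directly bonded pairs only
        excl = np.zeros((n, n), dtype=np.bool_)
        excl[self.bond_i, self.bond_j] = True
        excl[self.bond_j, self.bond_i] = True
        np.fill_diagonal(excl, True)
        self.excl = excl

        # lock wells between backbone beads of registry pairs (intrachain,
        # replicated per chain)
        li, lj, lip, lin, ljp, ljn = [], [], [], [], [], []
        lock = topology.lock

        def _nb(res, c):
            """backbone bead of a neighbouring residue, -1 past chain ends"""
            if res < 1 or res > nres:
                return -1
            return topology.backbone_bead(res, c)

        if lock is not None and (lock.epsilon_lock > 0 or lock.epsilon_coop > 0):
            for c in range(topology.n_chains):
                for (ia, ib) in lock.registry:
                    li.append(topology.backbone_bead(ia, c))
                    lj.append(topology.backbone_bead(ib, c))
                    lip.append(_nb(ia - 1, c)); lin.append(_nb(ia + 1, c))
                    ljp.append(_nb(ib - 1, c)); ljn.append(_nb(ib + 1, c))
        self.lock_i = np.array(li, dtype=np.int64)
        self.lock_j = np.array(lj, dtype=np.int64)
        self.lock_ip = np.array(lip, dtype=np.int64)
        self.lock_in = np.array(lin, dtype=np.int64)
        self.lock_jp = np.array(ljp, dtype=np.int64)
        self.lock_jn = np.array(ljn, dtype=np.int64)
        self.lock_nper = len(lock.registry) if lock is not None else 1
        self.lock_beads = np.unique(np.concatenate(
            [a[a >= 0] for a in (self.lock_i, self.lock_j, self.lock_ip,
                                 self.lock_in, self.lock_jp, self.lock_jn)])) \
            if li else np.zeros(0, dtype=np.int64)
        self.lock_alpha = lock.alpha_lock if lock is not None else 0.0
        if lock is not None:
            self.lock_eps1 = lock.epsilon_lock
            self.lock_eps2 = lock.epsilon_coop
            self.lock_r0, self.lock_w, self.lock_rc = lock.r0, lock.width, lock.cutoff
            self.lock_elo, self.lock_ehi = lock.ext_lo, lock.ext_hi
        else:
            self.lock_eps1 = self.lock_eps2 = 0.0
            self.lock_r0, self.lock_w, self.lock_rc = 0.32, 0.10, 0.8
            self.lock_elo, self.lock_ehi = 0.50, 0.62

        # residue bead lookup tables for the move kernels
        ntot = topology.n_residues_total
        self.res_bb = np.array(
            [topology.backbone_bead(i % nres + 1, i // nres) for i in range(ntot)],
            dtype=np.int64)
        self.res_sc = self.res_bb + (bpr - 1)
        self.chain_of_res = np.repeat(np.arange(topology.n_chains), nres).astype(np.int64)
        self.nres_per_chain = nres
        self.box = topology.box_edge

    def lock_scale(self, temperature: float) -> float:
        """Temperature factor of the lock well depth: backbone pseudo-H-bonds
        weaken linearly on heating (clamped at zero), the implicit-solvent
        counterpart of the LCST strengthening of sticker contacts."""
        t = 1.0 - self.lock_alpha * \
            (temperature - self.model.reference_temperature) \
            / self.model.reference_temperature
        return max(0.0, t)

    def eps_matrix(self, temperature: float) -> np.ndarray:
        """Bead-pair attraction well depths at the given temperature.

        Only side-chain/side-chain entries are non-zero; the geometric-mean
        combining rule is modulated by the LCST factor for pairs where both
        residues are sticky (sticker or hydrophobic spacer).
        """
        topo, model = self.topology, self.model
        eps_res = topo.residue_epsilons()
        sticky = topo.residue_sticky()
        base = np.sqrt(np.outer(eps_res, eps_res))
        factor = model.temperature_factor(temperature)
        both_sticky = np.outer(sticky, sticky)
        depth = base * np.where(both_sticky, factor, 1.0)

        n = topo.n_beads
        mat = np.zeros((n, n))
        sc = self.res_sc
        mat[np.ix_(sc, sc)] = depth
        np.fill_diagonal(mat, 0.0)
        return mat


def potential_energy(topology: ChainTopology, model: EnergyModel,
                     coords: np.ndarray, temperature: float,
                     arrays: SimArrays | None = None,
                     eps_mat: np.ndarray | None = None) -> float:
    """Total potential energy (kJ/mol) of one frame.

    Deterministic sum of bonded + excluded-volume + pair-attraction + lock
    terms under the periodic minimum-image convention.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (topology.n_beads, 3):
        raise ValueError(
            f"coordinate shape {coords.shape} does not match topology "
            f"({topology.n_beads} beads)")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    a = arrays if arrays is not None else SimArrays(topology, model)
    em = eps_mat if eps_mat is not None else a.eps_matrix(temperature)
    ls = a.lock_scale(temperature)
    return float(_kernels.total_energy(
        coords, a.box, a.sigma, em, a.excl,
        a.bond_i, a.bond_j, a.bond_r0, a.bond_k,
        a.ang_i, a.ang_j, a.ang_k, a.ang_th0, a.ang_ka,
        a.lock_i, a.lock_j, a.lock_ip, a.lock_in, a.lock_jp, a.lock_jn,
        a.lock_nper, a.lock_beads, a.lock_eps1 * ls, a.lock_eps2 * ls,
        a.lock_r0, a.lock_w, a.lock_rc, a.lock_elo, a.lock_ehi,
        model.attraction_cutoff, model.k_repulsion))
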