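"""Replica-exchange Metropolis Monte Carlo for the coarse-grained lock polymer.

The sampler stands in for the all-atom replica-exchange molecular dynamics it
emulates: a ladder of temperatures is simulated in parallel, nearest-neighbour
configuration swaps are attempted every ``exchange_interval`` sweeps
(alternating even/odd pairs), and the leading ``equilibration_fraction`` of
each trajectory is flagged for exclusion from ensemble averages.

Because the pair attraction is temperature-dependent (the LCST encoding),
each ladder rung carries its own Hamiltonian; swaps therefore use the
generalized (Hamiltonian-exchange) Metropolis criterion, which reduces to the
classic ``min(1, exp((b_i - b_j)(E_i - E_j)))`` rule when the Hamiltonian is
temperature-independent.  Both preserve the per-rung Boltzmann distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from thermolock import _kernels
from thermolock.constants import KB
from thermolock.energy import EnergyModel, SimArrays, potential_energy
from thermolock.topology import ChainTopology


# --------------------------------------------------------------------------
# Acceptance rules


def metropolis_acceptance(delta_e: float, temperature: float) -> float:
    """min(1, exp(-dE/kT)) for a proposed move with energy change dE."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = -delta_e / (KB * temperature)
    return 1.0 if x >= 0 else float(np.exp(x))

def exchange_probability(beta_i: float, beta_j: float,
                         e_i: float, e_j: float) -> float:
    """Replica-swap acceptance min(1, exp((b_i - b_j)(E_i - E_j))).

    Symmetric under exchanging (i, j); valid when both replicas share one
    Hamiltonian.
    """
    x = (beta_i - beta_j) * (e_i - e_j)
    return 1.0 if x >= 0 else float(np.exp(x))


# --------------------------------------------------------------------------
# Ladder / moves / frames


@dataclass(frozen=True)
class ReplicaLadder:
    """Ordered temperature ladder with a swap-attempt interval in sweeps."""

    temperatures: tuple[float, ...]
    spacing_rule: str = "explicit"
    exchange_interval: int = 10

    def __post_init__(self):
        ts = self.temperatures
        if len(ts) < 1:
            raise ValueError("ladder needs at least one temperature")
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        if min(ts) < 250.0 or max(ts) > 400.0:
            raise ValueError("ladder temperatures must lie within [250, 400] K")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1 sweep")

    @staticmethod
    def geometric(t_min: float, t_max: float, n: int,
                  exchange_interval: int = 10) -> "ReplicaLadder":
        ts = tuple(np.geomspace(t_min, t_max, n).tolist())
        return ReplicaLadder(ts, spacing_rule="geometric",
                             exchange_interval=exchange_interval)

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    def betas(self) -> np.ndarray:
        return 1.0 / (KB * np.asarray(self.temperatures))


@dataclass(frozen=True)
class MoveParams:
    """Relative weights and step sizes of the Monte-Carlo move set.

    ``lattice_step > 0`` switches single-bead displacements to fixed steps
    of that length along a random axis (discretized move set for exactly
    enumerable toy systems); crankshaft/pivot weights should then be zero.
    """

    w_displacement: float = 0.68
    w_crankshaft: float = 0.22
    w_pivot: float = 0.08
    w_translation: float = 0.02
    max_displacement: float = 0.12  # nm
    max_pivot_angle: float = 1.2    # rad
    max_translation: float = 0.4    # nm
    lattice_step: float = 0.0       # nm; 0 = continuous displacements

    def cumulative(self, n_chains: int) -> np.ndarray:
        w = np.array([self.w_displacement, self.w_crankshaft,
                      self.w_pivot, self.w_translation], dtype=float)
        if n_chains < 2:
            w[3] = 0.0
        if w.sum() <= 0:
            raise ValueError("move weights must not all be zero")
        return np.cumsum(w / w.sum())

    @staticmethod
    def lattice(step: float) -> "MoveParams":
        return MoveParams(w_displacement=1.0, w_crankshaft=0.0, w_pivot=0.0,
                          w_translation=0.0, lattice_step=step)


@dataclass
class Frame:
    """One stored configuration with its recomputable potential energy."""

    coordinates: np.ndarray  # (n_beads, 3) nm
    temperature: float       # K
    sweep_index: int
    potential_energy: float  # kJ/mol


@dataclass
class Trajectory:
    """Frame sequence recorded at one ladder rung."""

    coordinates: np.ndarray   # (n_frames, n_beads, 3)
    sweep_indices: np.ndarray
    energies: np.ndarray
    temperature: float

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frames(self):
        for f in range(self.n_frames):
            yield Frame(self.coordinates[f], self.temperature,
                        int(self.sweep_indices[f]), float(self.energies[f]))


@dataclass
class EnsembleSet:
    """Temperature-indexed trajectories plus exchange statistics."""

    topology: ChainTopology
    model: EnergyModel
    temperatures: tuple[float, ...]
    trajectories: list[Trajectory]
    exchange_attempts: np.ndarray  # per neighbour pair
    exchange_accepts: np.ndarray
    replica_walk: np.ndarray       # (n_epochs + 1, n_replicas) rung per replica
    seed: int
    config_digest: str
    equilibration_fraction: float = 0.2

    def trajectory(self, temperature: float) -> Trajectory:
        for t, tr in zip(self.temperatures, self.trajectories):
            if abs(t - temperature) < 1e-9:
                return tr
        raise KeyError(f"no trajectory at {temperature} K "
                       f"(available: {self.temperatures})")

    def mean_exchange_ratio(self) -> float:
        att = self.exchange_attempts.sum()
        return float(self.exchange_accepts.sum() / att) if att else float("nan")

    def digest(self) -> str:
        h = hashlib.sha256()
        for tr in self.trajectories:
            h.update(np.ascontiguousarray(tr.coordinates).tobytes())
            h.update(np.ascontiguousarray(tr.energies).tobytes())
        h.update(self.replica_walk.tobytes())
        return h.hexdigest()


# --------------------------------------------------------------------------
# Initial structures


def _random_walk(start: np.ndarray, n_steps: int, bond: float,
                 rng: np.random.Generator,
                 target: Optional[np.ndarray] = None) -> np.ndarray:
    """Freely jointed walk of ``n_steps`` bonds; when ``target`` is given the
    walk is biased so the final bead lands near it (a discrete bridge)."""
    out = np.empty((n_steps, 3))
    cur = start.astype(float).copy()
    for s in range(n_steps):
        g = rng.normal(size=3)
        if target is not None:
            remaining = n_steps - s
            to_go = target - cur
            dist = np.linalg.norm(to_go)
            if dist > 1e-9:
                pull = min(3.0, 2.0 * dist / (remaining * bond))
                g = 0.6 * g + pull * (to_go / dist)
        nrm = np.linalg.norm(g)
        if nrm < 1e-9:
            g = np.array([1.0, 0.0, 0.0]); nrm = 1.0
        cur = cur + bond * g / nrm
        out[s] = cur
    return out


def initial_coordinates(topology: ChainTopology, rng: np.random.Generator,
                        locked: Optional[bool] = None) -> np.ndarray:
    """Build a starting configuration.

    With a lock present (default), the two lock segments are built as a
    paired antiparallel pair of strands and the remaining stretches as
    biased random walks — the analogue of starting from a predicted folded
    structure.  Without a lock, the chain is a plain random walk.  Chains of
    a two-chain system are placed a fixed offset apart, with retries if the
    placement overlaps.
    """
    if locked is None:
        locked = topology.lock is not None
    n = topology.n_residues
    b = topology.backbone_bond_length
    sc_b = topology.sidechain_bond_length

    def build_single() -> np.ndarray:
        bb = np.empty((n, 3))
        if locked and topology.lock is not None:
            lock = topology.lock
            (a0, a1), (b0, b1) = lock.segment_a, lock.segment_b
            for i in range(a0, a1 + 1):
                bb[i - 1] = ((i - a0) * b, 0.0, 0.0)
            # antiparallel partner strand one pseudo-H-bond away
            for j in range(b0, b1 + 1):
                bb[j - 1] = ((b1 - j) * b, lock.r0, 0.0)
            if a0 > 1:
                walk = _random_walk(bb[a0 - 1], a0 - 1, b, rng)
                bb[a0 - 2::-1] = walk
            bridge = _random_walk(bb[a1 - 1], b0 - a1 - 1, b, rng,
                                  target=bb[b0 - 1])
            if b0 - a1 - 1 > 0:
                bb[a1:b0 - 1] = bridge
            if b1 < n:
                walk = _random_walk(bb[b1 - 1], n - b1, b, rng)
                bb[b1:] = walk
        else:
            bb[0] = (0.0, 0.0, 0.0)
            bb[1:] = _random_walk(bb[0], n - 1, b, rng)

        if topology.beads_per_residue == 1:
            return bb
        coords = np.empty((2 * n, 3))
        coords[0::2] = bb
        for i in range(n):
            d = rng.normal(size=3)
            d[2] = d[2] + (2.0 if i % 2 == 0 else -2.0)  # alternate sides
            coords[2 * i + 1] = bb[i] + sc_b * d / np.linalg.norm(d)
        return coords

    chains = [build_single() for _ in range(topology.n_chains)]
    if topology.n_chains == 1:
        return chains[0] - chains[0].mean(axis=0)

    a = chains[0] - chains[0].mean(axis=0)
    bchain = chains[1] - chains[1].mean(axis=0)
    for attempt in range(8):
        offset = np.array([1.6, 1.3, 1.0]) * (1.0 + 0.25 * attempt)
        cand = bchain + offset
        dmin = np.min(np.linalg.norm(a[:, None, :] - cand[None, :, :], axis=-1))
        if dmin > 0.35:
            return np.concatenate([a, cand], axis=0)
    raise RuntimeError("could not place two chains without overlap")


# --------------------------------------------------------------------------
# Sampling drivers


def _kernel_args(arrays: SimArrays, eps_mat: np.ndarray, temperature: float):
    a = arrays
    ls = a.lock_scale(temperature)
    return (a.box, a.sigma, eps_mat, a.excl,
            a.bond_i, a.bond_j, a.bond_r0, a.bond_k,
            a.ang_i, a.ang_j, a.ang_k, a.ang_th0, a.ang_ka,
            a.lock_i, a.lock_j, a.lock_ip, a.lock_in, a.lock_jp, a.lock_jn,
            a.lock_nper, a.lock_beads, a.lock_eps1 * ls, a.lock_eps2 * ls,
            a.lock_r0, a.lock_w, a.lock_rc, a.lock_elo, a.lock_ehi,
            a.model.attraction_cutoff, a.model.k_repulsion)


def _sweep_args(arrays: SimArrays, moves: MoveParams):
    a = arrays
    return (a.res_bb, a.res_sc, a.chain_of_res, a.nres_per_chain,
            moves.cumulative(a.topology.n_chains),
            moves.max_displacement, moves.max_pivot_angle,
            moves.max_translation, moves.lattice_step)


def mc_sweep(frame: Frame, topology: ChainTopology, model: EnergyModel,
             temperature: float, rng: np.random.Generator,
             moves: Optional[MoveParams] = None, n_sweeps: int = 1,
             arrays: Optional[SimArrays] = None) -> Frame:
    """Advance a frame by ``n_sweeps`` Metropolis sweeps (n_beads attempted
    moves per sweep), each move accepted with min(1, exp(-dE/kT))."""
    if moves is None:
        moves = MoveParams()
    a = arrays if arrays is not None else SimArrays(topology, model)
    eps = a.eps_matrix(temperature)
    pos = np.array(frame.coordinates, dtype=np.float64)
    e0 = potential_energy(topology, model, pos, temperature, a, eps)
    att = np.zeros(4, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    beta = 1.0 / (KB * temperature)
    e = _kernels.run_sweeps(pos, n_sweeps, beta,
                            *_kernel_args(a, eps, temperature),
                            *_sweep_args(a, moves), rng, e0, att, acc)
    return Frame(pos, temperature, frame.sweep_index + n_sweeps, float(e))


def _quench(pos, arrays, eps, moves, rng, n_sweeps=60, temperature=120.0):
    """Short low-temperature relaxation to heal constructed starts.

    Uses small single-bead displacements only: local overlaps from the
    biased-walk construction anneal away without pivot/crankshaft moves
    tearing the built lock apart.
    """
    del moves  # global moves would undo the constructed geometry
    local = MoveParams(w_displacement=1.0, w_crankshaft=0.0, w_pivot=0.0,
                       w_translation=0.0, max_displacement=0.05)
    att = np.zeros(4, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    e0 = _kernels.total_energy(pos, *_kernel_args(arrays, eps, temperature))
    beta = 1.0 / (KB * temperature)
    _kernels.run_sweeps(pos, n_sweeps, beta,
                        *_kernel_args(arrays, eps, temperature),
                        *_sweep_args(arrays, local), rng, e0, att, acc)


def _config_digest(topology, model, ladder_temps, exchange_interval,
                   n_sweeps, frame_stride, equilibration_fraction,
                   seed, moves) -> str:
    payload = json.dumps({
        "topology": topology.to_dict(),
        "model": model.to_dict(),
        "temperatures": list(ladder_temps),
        "exchange_interval": exchange_interval,
        "n_sweeps": n_sweeps,
        "frame_stride": frame_stride,
        "equilibration_fraction": equilibration_fraction,
        "seed": seed,
        "moves": asdict(moves),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_remd(topology: ChainTopology, model: EnergyModel,
             ladder: ReplicaLadder, n_sweeps: int,
             equilibration_fraction: float = 0.2,
             seed: int = 0,
             frame_stride: Optional[int] = None,
             moves: Optional[MoveParams] = None,
             initial_locked: Optional[bool] = None,
             initial_coords: Optional[Sequence[np.ndarray]] = None) -> EnsembleSet:
    """Replica-exchange run over the full ladder.

    Nearest-neighbour swaps are attempted every ``exchange_interval`` sweeps,
    alternating even/odd pairs per attempt epoch.  Frames are recorded every
    ``frame_stride`` sweeps (default: one frame per exchange epoch) with the
    rung temperature; stored energies are freshly recomputed at record time.
    """
    if n_sweeps < ladder.exchange_interval:
        raise ValueError("n_sweeps must be at least one exchange interval")
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    moves = moves if moves is not None else MoveParams()
    interval = ladder.exchange_interval
    if frame_stride is None:
        frame_stride = interval
    record_every = max(1, frame_stride // interval)

    arrays = SimArrays(topology, model)
    temps = ladder.temperatures
    n_rep = ladder.n_replicas
    betas = ladder.betas()
    eps_mats = [arrays.eps_matrix(t) for t in temps]
    same_hamiltonian = all(np.array_equal(eps_mats[0], m) for m in eps_mats[1:])
    if arrays.lock_i.size and arrays.lock_alpha != 0.0 \
            and (arrays.lock_eps1 > 0 or arrays.lock_eps2 > 0):
        same_hamiltonian = same_hamiltonian and len(set(temps)) == 1

    master = np.random.default_rng(seed)
    if initial_coords is not None:
        if len(initial_coords) != n_rep:
            raise ValueError("initial_coords must supply one frame per replica")
        states = [np.array(c, dtype=np.float64) for c in initial_coords]
        for c in states:
            if c.shape != (topology.n_beads, 3):
                raise ValueError("initial coordinate shape mismatch")
    else:
        states = [initial_coordinates(topology, master, locked=initial_locked)
                  for _ in range(n_rep)]
        for r in range(n_rep):
            _quench(states[r], arrays, eps_mats[r], moves, master)
    rep_rngs = master.spawn(n_rep)

    energies = np.array([
        _kernels.total_energy(states[r],
                              *_kernel_args(arrays, eps_mats[r], temps[r]))
        for r in range(n_rep)])

    n_epochs = n_sweeps // interval
    att_pair = np.zeros(max(n_rep - 1, 0), dtype=np.int64)
    acc_pair = np.zeros(max(n_rep - 1, 0), dtype=np.int64)
    walk = np.zeros((n_epochs + 1, n_rep), dtype=np.int64)
    # replica_of_rung[r] = replica identity currently simulated at rung r
    replica_of_rung = np.arange(n_rep)
    walk[0, replica_of_rung] = np.arange(n_rep)

    frames: list[list[tuple[int, np.ndarray, float]]] = [[] for _ in range(n_rep)]
    att = np.zeros(4, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    sweep_args = _sweep_args(arrays, moves)

    for epoch in range(n_epochs):
        for r in range(n_rep):
            energies[r] = _kernels.run_sweeps(
                states[r], interval, betas[r],
                *_kernel_args(arrays, eps_mats[r], temps[r]), *sweep_args,
                rep_rngs[replica_of_rung[r]], energies[r], att, acc)
        sweep_now = (epoch + 1) * interval

        if n_rep > 1:
            for r in range(epoch % 2, n_rep - 1, 2):
                s = r + 1
                if same_hamiltonian:
                    # classic criterion via the public closed form
                    p = exchange_probability(betas[r], betas[s],
                                             energies[r], energies[s])
                else:
                    u_r_xs = _kernels.total_energy(
                        states[s], *_kernel_args(arrays, eps_mats[r], temps[r]))
                    u_s_xr = _kernels.total_energy(
                        states[r], *_kernel_args(arrays, eps_mats[s], temps[s]))
                    d = betas[r] * (u_r_xs - energies[r]) \
                        + betas[s] * (u_s_xr - energies[s])
                    p = 1.0 if d <= 0 else float(np.exp(-d))
                att_pair[r] += 1
                if master.random() < p:
                    acc_pair[r] += 1
                    states[r], states[s] = states[s], states[r]
                    if same_hamiltonian:
                        energies[r], energies[s] = energies[s], energies[r]
                    else:
                        energies[r], energies[s] = u_r_xs, u_s_xr
                    replica_of_rung[r], replica_of_rung[s] = \
                        replica_of_rung[s], replica_of_rung[r]
        for r in range(n_rep):
            walk[epoch + 1, replica_of_rung[r]] = r

        if (epoch + 1) % record_every == 0:
            for r in range(n_rep):
                e_exact = _kernels.total_energy(
                    states[r], *_kernel_args(arrays, eps_mats[r], temps[r]))
                energies[r] = e_exact  # reset incremental drift
                frames[r].append((sweep_now, states[r].copy(), e_exact))

    trajectories = []
    for r in range(n_rep):
        if frames[r]:
            sw = np.array([f[0] for f in frames[r]], dtype=np.int64)
            co = np.stack([f[1] for f in frames[r]])
            en = np.array([f[2] for f in frames[r]])
        else:
            sw = np.zeros(0, dtype=np.int64)
            co = np.zeros((0, topology.n_beads, 3))
            en = np.zeros(0)
        trajectories.append(Trajectory(co, sw, en, temps[r]))

    digest = _config_digest(topology, model, temps, interval, n_sweeps,
                            frame_stride, equilibration_fraction, seed, moves)
    return EnsembleSet(topology=topology, model=model, temperatures=tuple(temps),
                       trajectories=trajectories,
                       exchange_attempts=att_pair, exchange_accepts=acc_pair,
                       replica_walk=walk, seed=seed, config_digest=digest,
                       equilibration_fraction=equilibration_fraction)


def simulate_two_chain(topology: ChainTopology, model: EnergyModel,
                       temperatures: Sequence[float], n_sweeps: int,
                       seed: int = 0,
                       equilibration_fraction: float = 0.2,
                       frame_stride: int = 10,
                       moves: Optional[MoveParams] = None,
                       initial_locked: Optional[bool] = None) -> EnsembleSet:
    """Independent (non-exchanging) runs of a two-chain system, one per
    temperature, in a shared periodic box; frames retain chain identity so
    inter- and intra-molecular metrics can be separated."""
    if topology.n_chains != 2:
        raise ValueError("simulate_two_chain requires a two-chain topology")
    temps = tuple(sorted(float(t) for t in temperatures))
    moves = moves if moves is not None else MoveParams()
    arrays = SimArrays(topology, model)
    master = np.random.default_rng(seed)

    trajectories = []
    for t in temps:
        eps = arrays.eps_matrix(t)
        pos = initial_coordinates(topology, master, locked=initial_locked)
        _quench(pos, arrays, eps, moves, master)
        rng = master.spawn(1)[0]
        beta = 1.0 / (KB * t)
        e = _kernels.total_energy(pos, *_kernel_args(arrays, eps, t))
        att = np.zeros(4, dtype=np.int64)
        acc = np.zeros(4, dtype=np.int64)
        n_chunks = n_sweeps // frame_stride
        sw, co, en = [], [], []
        for c in range(n_chunks):
            e = _kernels.run_sweeps(pos, frame_stride, beta,
                                    *_kernel_args(arrays, eps, t),
                                    *_sweep_args(arrays, moves),
                                    rng, e, att, acc)
            e = _kernels.total_energy(pos, *_kernel_args(arrays, eps, t))
            sw.append((c + 1) * frame_stride)
            co.append(pos.copy())
            en.append(e)
        trajectories.append(Trajectory(np.stack(co), np.array(sw, dtype=np.int64),
                                       np.array(en), t))

    digest = _config_digest(topology, model, temps, 0, n_sweeps, frame_stride,
                            equilibration_fraction, seed, moves)
    return EnsembleSet(topology=topology, model=model, temperatures=temps,
                       trajectories=trajectories,
                       exchange_attempts=np.zeros(0, dtype=np.int64),
                       exchange_accepts=np.zeros(0, dtype=np.int64),
                       replica_walk=np.zeros((1, len(temps)), dtype=np.int64),
                       seed=seed, config_digest=digest,
                       equilibration_fraction=equilibration_fraction)
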