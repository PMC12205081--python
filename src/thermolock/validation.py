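"""Self-validation studies: desk-scale experiments that exercise the whole
pipeline and summarize what it reproduces.

Each function runs one study from scratch — sampler correctness on an
exactly enumerable toy, temperature-direction reproduction on the chain
presets, planted-lock recovery, FRET ordering, planted-truth enrichment
statistics — and returns plain dictionaries of numbers.  The test suite
asserts on these results; the acceptance script serializes them.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from thermolock.analysis import delta_contact_profile, detect_lock, lock_occupancy
from thermolock.constants import KB
from thermolock.energy import EnergyModel, SimArrays, potential_energy
from thermolock.fret import FretParams, predict_lifetime
from thermolock.metrics import (
    AnalysisConfig,
    ChainView,
    contact_map,
    ensemble_average,
    hbond_series,
    radius_of_gyration,
    sasa,
)
from thermolock.sampler import (
    MoveParams,
    ReplicaLadder,
    run_remd,
    simulate_two_chain,
)
from thermolock.topology import ChainTopology, ResidueSpec, build_preset

LADDER_TEMPERATURES = tuple(np.linspace(280.0, 316.0, 8))
PAIR_TEMPERATURES = (280.0, 310.0)


# --------------------------------------------------------------------------
# Enumerable lattice toy (sampler correctness)


def lattice_toy_system() -> tuple[ChainTopology, EnergyModel]:
    """4-bead chain on a 3-site-per-axis periodic lattice.

    The box is 3 lattice steps so no pair separation sits exactly at half
    the box edge; the minimum-image convention is then unambiguous on the
    lattice and the energy is a function of the configuration modulo box
    translations, which the exact enumeration relies on.
    """
    residues = tuple(ResidueSpec(index=i, category="polar_spacer",
                                 sidechain_epsilon=0.25)
                     for i in range(1, 5))
    topology = ChainTopology(residues=residues, backbone_bond_length=0.25,
                             backbone_radius=0.12, box_edge=0.75,
                             beads_per_residue=1)
    model = EnergyModel(k_bond=200.0, k_angle=1.5, alpha=0.0)
    return topology, model


LATTICE_STEP = 0.25
LATTICE_SITES = 3


def enumerate_lattice_states(topology, model, temperature,
                             h=LATTICE_STEP, m=LATTICE_SITES):
    """Exact Boltzmann distribution over relative lattice configurations.

    Bead 0 is the reference; a state is the displacement of beads 1..n-1
    from bead 0, modulo the box.  Energies are translation invariant, so
    state probabilities are exactly exp(-E/kT)/Z.
    """
    arrays = SimArrays(topology, model)
    eps = arrays.eps_matrix(temperature)
    sites = list(product(range(m), repeat=3))
    states = list(product(range(len(sites)), repeat=topology.n_beads - 1))
    energies = np.empty(len(states))
    coords = np.zeros((topology.n_beads, 3))
    for k, st in enumerate(states):
        coords[0] = 0.0
        for b, s in enumerate(st):
            coords[b + 1] = np.array(sites[s], dtype=float) * h
        energies[k] = potential_energy(topology, model, coords, temperature,
                                       arrays=arrays, eps_mat=eps)
    w = np.exp(-(energies - energies.min()) / (KB * temperature))
    return np.array(states), energies, w / w.sum()


def lattice_state_index(frames, h=LATTICE_STEP, m=LATTICE_SITES):
    rel = frames[:, 1:, :] - frames[:, :1, :]
    idx = np.rint(rel / h).astype(int) % m
    site = (idx[..., 0] * m + idx[..., 1]) * m + idx[..., 2]
    n_sites = m ** 3
    state = np.zeros(len(frames), dtype=int)
    for b in range(site.shape[1]):
        state = state * n_sites + site[:, b]
    return state


def enumeration_state_ids(states, m=LATTICE_SITES):
    n_sites = m ** 3
    out = np.zeros(len(states), dtype=int)
    for b in range(states.shape[1]):
        out = out * n_sites + states[:, b]
    return out


def boltzmann_toy_study(seed: int = 11, n_sweeps: int = 60000,
                        temperatures=(280.0, 298.0, 316.0)) -> dict:
    """Sample the toy with replica exchange and compare energy-level
    frequencies against the exact Boltzmann distribution at every rung.

    Returns the worst deviation in units of its Monte-Carlo standard error
    (batch means over 20 batches, which absorbs frame autocorrelation).
    """
    topology, model = lattice_toy_system()
    ladder = ReplicaLadder(tuple(temperatures), exchange_interval=5)
    h = LATTICE_STEP
    init = np.array([[0, 0, 0], [h, 0, 0], [h, h, 0], [0, h, 0]])
    ens = run_remd(topology, model, ladder, n_sweeps=n_sweeps, seed=seed,
                   frame_stride=20, moves=MoveParams.lattice(h),
                   initial_coords=[init.copy() for _ in ladder.temperatures])
    worst = 0.0
    n_frames = 0
    for t in temperatures:
        states, energies, probs = enumerate_lattice_states(topology, model, t)
        ids = enumeration_state_ids(states)
        tr = ens.trajectory(t)
        frames = tr.coordinates[int(0.1 * tr.n_frames):]
        sampled_ids = lattice_state_index(frames)
        n = len(sampled_ids)
        n_frames += n
        levels = np.round(energies, 6)
        id_to_level = dict(zip(ids, levels))
        sample_levels = np.array([id_to_level[s] for s in sampled_ids])
        batches = np.array_split(sample_levels, 20)
        for lv in np.unique(levels):
            p = probs[levels == lv].sum()
            if p < 5e-4:
                continue
            f = (sample_levels == lv).mean()
            bf = np.array([(b == lv).mean() for b in batches])
            se = max(bf.std(ddof=1) / np.sqrt(len(batches)),
                     np.sqrt(p * (1 - p) / n))
            worst = max(worst, abs(f - p) / (se + 1e-12))
    return {"max_abs_z": float(worst), "n": int(n_frames)}


# --------------------------------------------------------------------------
# Metric oracles


def metric_oracle_study(seed: int = 0, n_frames: int = 120) -> dict:
    """Brute-force agreement of contacts, H-bonds and Rg on random frames,
    plus the Shrake–Rupley analytic-sphere error."""
    from thermolock.metrics import count_hbonds, side_chain_contacts

    rng = np.random.default_rng(seed)
    topo = build_preset("no_lock_homopolymer", 25, box_edge=50.0)
    view = ChainView.from_topology(topo)
    cfg = AnalysisConfig()
    contact_mismatch = 0
    hbond_mismatch = 0
    rg_err = 0.0
    for _ in range(n_frames):
        frame = rng.uniform(0, 3.0, (topo.n_beads, 3))
        got = side_chain_contacts(frame, view, cfg)
        for i in range(25):
            for j in range(25):
                want = (i != j and abs(i - j) > cfg.adjacency_exclusion
                        and np.linalg.norm(frame[2 * i + 1] - frame[2 * j + 1])
                        < cfg.contact_cutoff)
                if got[i, j] != want:
                    contact_mismatch += 1
        _, bonds = count_hbonds(frame, view.hbond_sites, cfg,
                                chain_of_residue=view.chain_of_residue,
                                residues_per_chain=view.residues_per_chain,
                                box=view.box)
        want_bonds = set()
        bb = frame[view.backbone_atom]
        for d in range(25):
            for a in range(25):
                if abs(d - a) < cfg.hbond_min_separation:
                    continue
                if np.linalg.norm(bb[d] - bb[a]) <= cfg.hbond_distance_cutoff:
                    want_bonds.add((view.backbone_atom[d],
                                    view.backbone_atom[a]))
        if set(bonds) != want_bonds:
            hbond_mismatch += 1
        masses = rng.uniform(1, 10, topo.n_beads)
        com = (frame * masses[:, None]).sum(0) / masses.sum()
        ref = np.sqrt((masses * ((frame - com) ** 2).sum(1)).sum()
                      / masses.sum())
        rg_err = max(rg_err, abs(radius_of_gyration(frame, masses) - ref)
                     / ref)

    a = sasa(np.zeros((1, 3)), np.array([0.2]), cfg)[0]
    sphere = 4 * np.pi * (0.2 + cfg.sasa_probe_radius) ** 2
    return {
        "contact_mismatches": int(contact_mismatch),
        "hbond_mismatches": int(hbond_mismatch),
        "rg_max_rel_err": float(rg_err),
        "sasa_sphere_rel_err": float(abs(a - sphere) / sphere),
        "n": n_frames,
    }


# --------------------------------------------------------------------------
# Ladder direction study (Rg / SASA / H-bonds / contacts vs temperature)


def _rung_metrics(ens, view, cfg, temperature, sasa_stride=6, hbond_stride=2):
    tr = ens.trajectory(temperature)
    co = tr.coordinates
    eq = cfg.equilibration_fraction
    out = {}
    out["rg"] = ensemble_average(radius_of_gyration(co), eq, cfg.block_count,
                                 name="rg", temperature=temperature)
    sas = [sasa(f, view.radii, cfg).sum() for f in co[::sasa_stride]]
    out["sasa"] = ensemble_average(sas, eq, cfg.block_count, name="sasa",
                                   temperature=temperature)
    hb = hbond_series(co[::hbond_stride], view, cfg)
    out["hbonds"] = ensemble_average(hb, eq, cfg.block_count, name="hbonds",
                                     temperature=temperature)
    cts = []
    from thermolock.metrics import side_chain_contacts
    for f in co[::hbond_stride]:
        cts.append(side_chain_contacts(f, view, cfg).sum() / 2)
    out["contacts"] = ensemble_average(cts, eq, cfg.block_count,
                                       name="contacts",
                                       temperature=temperature)
    return out


def ladder_direction_study(seed: int = 1, n_sweeps: int = 10000,
                           presets=("wt", "y_to_s")) -> dict:
    """8-rung replica-exchange runs of the chain presets with per-rung
    ensemble means and block-bootstrap SEs of the four headline metrics.

    These runs start from unbiased random coils: the temperature trends
    are then governed by the sticker thermodynamics at every rung (the
    wild type locks and compacts, the sticker-weakened variant stays a
    coil), giving monotone metric curves.  The lock-specific studies use
    the folded start instead.
    """
    ladder = ReplicaLadder(LADDER_TEMPERATURES, exchange_interval=10)
    cfg = AnalysisConfig(equilibration_fraction=0.3)
    model = EnergyModel()
    results = {}
    for k, preset in enumerate(presets):
        topo = build_preset(preset, 90)
        ens = run_remd(topo, model, ladder, n_sweeps=n_sweeps,
                       seed=seed * 1000 + k, frame_stride=30,
                       initial_locked=False)
        view = ChainView.from_topology(topo)
        per_rung = {}
        for t in ladder.temperatures:
            ms = _rung_metrics(ens, view, cfg, t)
            per_rung[t] = {name: (m.mean, m.se) for name, m in ms.items()}
        results[preset] = {
            "per_rung": per_rung,
            "exchange_ratio": ens.mean_exchange_ratio(),
        }
    results["temperatures"] = list(ladder.temperatures)
    return results


# --------------------------------------------------------------------------
# Two-chain study


def two_chain_study(seed: int = 1, n_sweeps: int = 10000) -> dict:
    """Intermolecular contacts and H-bonds of a two-chain wt system at the
    study's cold/hot pair, with block-bootstrap CIs."""
    topo = build_preset("wt", 90, n_chains=2)
    model = EnergyModel()
    cfg = AnalysisConfig(equilibration_fraction=0.3)
    ens = simulate_two_chain(topo, model, PAIR_TEMPERATURES, n_sweeps,
                             seed=seed, frame_stride=40)
    view = ChainView.from_topology(topo)
    from thermolock.metrics import side_chain_contacts
    out = {}
    for t in PAIR_TEMPERATURES:
        tr = ens.trajectory(t)
        cts = [side_chain_contacts(f, view, cfg, "intermolecular").sum() / 2
               for f in tr.coordinates]
        hbs = hbond_series(tr.coordinates, view, cfg, "intermolecular")
        mc = ensemble_average(cts, cfg.equilibration_fraction, cfg.block_count)
        mh = ensemble_average(hbs, cfg.equilibration_fraction, cfg.block_count)
        out[t] = {"contacts": (mc.mean, mc.se), "hbonds": (mh.mean, mh.se)}
    return out


# --------------------------------------------------------------------------
# Lock recovery / specificity


def _detection_pair(topo, model, seed, n_sweeps, cfg):
    lo = run_remd(topo, model, ReplicaLadder((PAIR_TEMPERATURES[0],),
                                             exchange_interval=10),
                  n_sweeps=n_sweeps, seed=seed, frame_stride=25)
    hi = run_remd(topo, model, ReplicaLadder((PAIR_TEMPERATURES[1],),
                                             exchange_interval=10),
                  n_sweeps=n_sweeps, seed=seed + 100000, frame_stride=25)
    return lo, hi


def segments_match_planted(segments, planted=((25, 30), (77, 82)),
                           tolerance=1) -> bool:
    if len(segments) != len(planted):
        return False
    for found, want in zip(sorted(segments), sorted(planted)):
        if abs(found[0] - want[0]) > tolerance \
                or abs(found[1] - want[1]) > tolerance:
            return False
    return True


def lock_recovery_study(seed: int = 0, n_seeds: int = 20,
                        n_sweeps: int = 4000,
                        keep_ensembles: bool = False) -> dict:
    """Planted-lock sensitivity (wt) and specificity (lock energy removed).

    Returns recovery and false-positive counts; optionally keeps the first
    wt / no-lock ensemble pair for reuse (e.g., the FRET study).
    """
    cfg = AnalysisConfig(equilibration_fraction=0.3)
    model = EnergyModel()
    wt = build_preset("wt", 90)
    nolock = build_preset("m1", 90)  # wt composition, lock energy removed
    hits = 0
    false_pos = 0
    occ_cold, occ_hot = [], []
    kept = {}
    for k in range(n_seeds):
        run_seed = seed * 1000 + k
        lo, hi = _detection_pair(wt, model, run_seed, n_sweeps, cfg)
        occ_cold.append(lock_occupancy(lo.trajectories[0], wt, 0.3))
        occ_hot.append(lock_occupancy(hi.trajectories[0], wt, 0.3))
        call = detect_lock(delta_contact_profile(lo, hi, cfg), lo, hi, cfg)
        if call.verdict == "lock_detected" \
                and segments_match_planted(call.segments):
            hits += 1
        if keep_ensembles and k < 5:
            kept.setdefault("wt", []).append((lo, hi))
    for k in range(n_seeds):
        run_seed = seed * 1000 + 500 + k
        lo, hi = _detection_pair(nolock, model, run_seed, n_sweeps, cfg)
        call = detect_lock(delta_contact_profile(lo, hi, cfg), lo, hi, cfg)
        if call.verdict != "no_lock":
            false_pos += 1
        if keep_ensembles and k < 5:
            kept.setdefault("no_lock", []).append((lo, hi))
    out = {"recovered": hits, "false_positives": false_pos, "n": n_seeds,
           "occupancy_cold_mean": float(np.mean(occ_cold)),
           "occupancy_hot_mean": float(np.mean(occ_hot))}
    if keep_ensembles:
        out["ensembles"] = kept
    return out


# --------------------------------------------------------------------------
# FRET ordering


def fret_ordering_study(seed: int = 3, n_sweeps: int = 4000,
                        n_pairs: int = 5,
                        wt_pairs=None, m1_pairs=None) -> dict:
    """Predicted donor lifetimes for wt/m1/m2 at the cold/hot pair,
    averaged over ``n_pairs`` replicate simulation pairs.

    Averaging over replicates matters: the hot wild-type ensemble samples
    the post-melt transient, whose end-to-end spread varies run to run.
    Pre-generated lists of (cold, hot) pairs can be passed to reuse the
    lock study's simulations.
    """
    cfg = AnalysisConfig(equilibration_fraction=0.3)
    model = EnergyModel()
    params = FretParams()
    out = {}
    pairs = {"wt": wt_pairs, "m1": m1_pairs, "m2": None}
    for offset, (preset, plist) in enumerate(pairs.items()):
        topo = build_preset(preset, 90)
        if plist is None:
            plist = [_detection_pair(topo, model,
                                     seed * 1000 + 71 * offset + k,
                                     n_sweeps, cfg)
                     for k in range(n_pairs)]
        cold = [predict_lifetime(lo, params, discard_fraction=0.3).lifetime
                for lo, _ in plist[:n_pairs]]
        hot = [predict_lifetime(hi, params, discard_fraction=0.3).lifetime
               for _, hi in plist[:n_pairs]]
        out[preset] = {PAIR_TEMPERATURES[0]: float(np.mean(cold)),
                       PAIR_TEMPERATURES[1]: float(np.mean(hot))}
    return out


# --------------------------------------------------------------------------
# Proteomics statistics


def proteomics_study(seed: int = 0, n_seeds: int = 20) -> dict:
    """Planted-truth recall/FDP at the reference simulation settings and
    the empirical null FDR of the moderated-test arm."""
    from thermolock.proteomics import (SyntheticProteomeSpec,
                                       enrichment_pipeline,
                                       simulate_protein_table)

    recalls, fdps, null_rates = [], [], []
    for k in range(n_seeds):
        spec = SyntheticProteomeSpec(seed=seed * 1000 + k)
        quant, truth = simulate_protein_table(spec)
        table = enrichment_pipeline(quant, "ipms")
        called = table["enriched"].to_numpy()
        recalls.append((called & truth).sum() / truth.sum())
        fdps.append((called & ~truth).sum() / max(called.sum(), 1))

        null_spec = SyntheticProteomeSpec(n_proteins=2000, n_enriched=0,
                                          missing_rate=0.0,
                                          seed=seed * 1000 + 500 + k)
        quant0, _ = simulate_protein_table(null_spec)
        table0 = enrichment_pipeline(quant0, "ipms")
        null_rates.append(float((table0["adjusted_p"] < 0.05).mean()))
    return {
        "recall_mean": float(np.mean(recalls)),
        "recall_min": float(np.min(recalls)),
        "fdp_mean": float(np.mean(fdps)),
        "fdp_max": float(np.max(fdps)),
        "null_fdr_mean": float(np.mean(null_rates)),
        "n": n_seeds,
    }
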