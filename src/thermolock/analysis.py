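"""Thermo-switch inference: Δcontact profiles, group heatmaps, lock detection.

The central object is the per-residue Δcontact profile between a high- and a
low-temperature ensemble: residues that *gain* intramolecular contacts on
heating trace the global LCST compaction, while runs of residues that *lose*
contacts against that background are candidates for a β-strand lock that
melts.  :func:`detect_lock` formalizes the lock call with three criteria:
a sufficiently long run of contact-losing residues, strong inter-segment
contact at the low temperature, and a drop in β-strand probability on
heating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from thermolock.metrics import (
    AnalysisConfig,
    ChainView,
    ContactMap,
    beta_strand_probability,
    contact_map,
    ensemble_average,
    radius_of_gyration,
)
from thermolock.sampler import EnsembleSet, Trajectory


# --------------------------------------------------------------------------
# Δcontact profile


@dataclass
class DeltaContactProfile:
    """Per-residue summed contact-frequency change, hot minus cold."""

    values: np.ndarray        # (residues_per_chain,)
    t_lo: float
    t_hi: float
    ci_lo: np.ndarray         # bootstrap CI bounds per residue
    ci_hi: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.values)

    def global_mean(self) -> float:
        return float(self.values.mean())


def _per_frame_contact_rows(frames: np.ndarray, view: ChainView,
                            config: AnalysisConfig) -> np.ndarray:
    """(F_retained, n_res) per-frame row sums of the intramolecular contact
    matrix — the bootstrap unit for profile CIs."""
    from thermolock.metrics import side_chain_contacts
    start = int(config.equilibration_fraction * len(frames))
    used = frames[start:]
    npc = view.residues_per_chain
    rows = np.zeros((len(used), npc))
    for f in range(len(used)):
        c = side_chain_contacts(used[f], view, config, "intramolecular")
        per = np.zeros(npc)
        for ch in range(view.n_chains):
            s = ch * npc
            per += c[s:s + npc, s:s + npc].sum(axis=1)
        rows[f] = per / view.n_chains
    return rows


def delta_contact_profile(ensemble_lo, ensemble_hi,
                          config: AnalysisConfig = AnalysisConfig(),
                          view: Optional[ChainView] = None,
                          n_boot: int = 200, seed: int = 0) -> DeltaContactProfile:
    """Per-residue Δcontact between two ensembles (hot minus cold).

    Each residue's value is the change in its summed intramolecular contact
    frequency; positive means contacts gained on heating.  Accepts
    (Trajectory, Trajectory) plus an explicit view, or two single-rung
    :class:`~thermolock.sampler.EnsembleSet` objects.
    """
    tr_lo, view_lo = _as_traj_view(ensemble_lo, view)
    tr_hi, view_hi = _as_traj_view(ensemble_hi, view)
    if view_lo.residues_per_chain != view_hi.residues_per_chain:
        raise ValueError("ensembles have different chain lengths")

    rows_lo = _per_frame_contact_rows(tr_lo.coordinates, view_lo, config)
    rows_hi = _per_frame_contact_rows(tr_hi.coordinates, view_hi, config)
    values = rows_hi.mean(axis=0) - rows_lo.mean(axis=0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(values)))
    for b in range(n_boot):
        i_lo = rng.integers(0, len(rows_lo), len(rows_lo))
        i_hi = rng.integers(0, len(rows_hi), len(rows_hi))
        boots[b] = rows_hi[i_hi].mean(axis=0) - rows_lo[i_lo].mean(axis=0)
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return DeltaContactProfile(values=values, t_lo=tr_lo.temperature,
                               t_hi=tr_hi.temperature,
                               ci_lo=ci_lo, ci_hi=ci_hi)


def _as_traj_view(obj, view: Optional[ChainView]):
    """Normalize (EnsembleSet | Trajectory) inputs to (Trajectory, ChainView)."""
    if isinstance(obj, EnsembleSet):
        if len(obj.temperatures) != 1:
            raise ValueError(
                "pass a single-temperature ensemble or an explicit Trajectory")
        return obj.trajectories[0], ChainView.from_topology(obj.topology)
    if isinstance(obj, Trajectory):
        if view is None:
            raise ValueError("a ChainView is required with a bare Trajectory")
        return obj, view
    raise TypeError(f"cannot interpret {type(obj)!r} as an ensemble")


# --------------------------------------------------------------------------
# Group heatmap


@dataclass
class ContactHeatmap:
    """Group × group mean contact frequencies at each temperature."""

    groups: tuple[tuple[int, int], ...]   # 1-based inclusive residue ranges
    temperatures: tuple[float, ...]
    values: np.ndarray                    # (n_temps, n_groups, n_groups)

    def value(self, temperature: float, gi: int, gj: int) -> float:
        t = self.temperatures.index(temperature)
        return float(self.values[t, gi, gj])


def group_contact_heatmap(ensembles: Sequence, groups: Sequence[tuple[int, int]],
                          config: AnalysisConfig = AnalysisConfig(),
                          view: Optional[ChainView] = None) -> ContactHeatmap:
    """Mean pairwise contact frequency between residue groups per ensemble.

    Each entry (gi, gj) is the mean of the contact-map sub-block spanned by
    the two groups (1-based inclusive residue ranges).
    """
    if not groups:
        raise ValueError("need at least one residue group")
    temps, grids = [], []
    for ens in ensembles:
        tr, v = _as_traj_view(ens, view)
        for lo, hi in groups:
            if lo < 1 or hi > v.residues_per_chain or lo > hi:
                raise ValueError(f"group {lo}-{hi} outside chain")
        cm = contact_map(tr.coordinates, v, config, "intramolecular",
                         temperature=tr.temperature)
        g = np.empty((len(groups), len(groups)))
        for a, (lo_a, hi_a) in enumerate(groups):
            for b, (lo_b, hi_b) in enumerate(groups):
                block = cm.matrix[lo_a - 1:hi_a, lo_b - 1:hi_b]
                g[a, b] = block.mean()
        temps.append(tr.temperature)
        grids.append(g)
    return ContactHeatmap(groups=tuple(tuple(g) for g in groups),
                          temperatures=tuple(temps),
                          values=np.stack(grids))


# --------------------------------------------------------------------------
# Lock detection


@dataclass(frozen=True)
class LockDetectionConfig:
    """Thresholds of the three-criterion lock call."""

    #: residues qualify when their Δcontact falls below -delta_threshold;
    #: calibrated on the synthetic generator so lock-adjacent residues
    #: (which lose a little contact when the duplex melts) do not smear the
    #: segment boundaries
    delta_threshold: float = 0.6
    min_run: int = 3               # minimum consecutive residues per segment
    contact_floor: float = 0.3     # inter-segment contact frequency at T_lo
    strand_drop: float = 0.2       # required drop in mean strand probability


@dataclass
class LockCall:
    """Outcome of lock detection with the supporting evidence."""

    verdict: str                                  # lock_detected | no_lock
    segments: tuple[tuple[int, int], ...]         # detected residue ranges
    segment_pairs: tuple[tuple[int, int], ...]    # indices into segments
    inter_segment_contact: dict
    strand_probability: dict
    global_mean_delta: float
    thresholds: LockDetectionConfig
    candidate_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.verdict == "lock_detected" and not self.segments:
            raise ValueError("lock_detected verdict requires segments")


def _negative_runs(values: np.ndarray, threshold: float, min_run: int):
    """Maximal runs of consecutive residues with value < -threshold."""
    below = values < -threshold
    runs = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= min_run:
                runs.append((start + 1, i))  # 1-based inclusive
            start = None
    if start is not None and len(below) - start >= min_run:
        runs.append((start + 1, len(below)))
    return runs


def detect_lock(profile: DeltaContactProfile, ensemble_lo, ensemble_hi,
                config: AnalysisConfig = AnalysisConfig(),
                thresholds: LockDetectionConfig = LockDetectionConfig(),
                view: Optional[ChainView] = None) -> LockCall:
    """Algorithmic lock call from a Δcontact profile and the two ensembles.

    A lock is reported iff (1) at least two maximal runs of ``min_run`` or
    more consecutive residues fall below ``-delta_threshold`` while the
    global mean Δcontact is positive, (2) a pair of such segments shows
    inter-segment contact frequency of at least ``contact_floor`` in the
    cold ensemble, and (3) the mean β-strand probability over that pair
    drops by at least ``strand_drop`` from cold to hot.
    """
    tr_lo, v = _as_traj_view(ensemble_lo, view)
    tr_hi, _ = _as_traj_view(ensemble_hi, view)

    gmean = profile.global_mean()
    candidates = _negative_runs(profile.values, thresholds.delta_threshold,
                                thresholds.min_run) if gmean > 0 else []

    evidence_contact: dict = {}
    evidence_strand: dict = {}
    detected: list[tuple[int, int]] = []
    pairs: list[tuple[int, int]] = []

    if len(candidates) >= 2:
        cm_lo = contact_map(tr_lo.coordinates, v, config, "intramolecular",
                            temperature=tr_lo.temperature)
        cm_hi = contact_map(tr_hi.coordinates, v, config, "intramolecular",
                            temperature=tr_hi.temperature)
        p_lo = beta_strand_probability(tr_lo.coordinates, v, config)
        p_hi = beta_strand_probability(tr_hi.coordinates, v, config)
        for a in range(len(candidates)):
            for b in range(a + 1, len(candidates)):
                (la, ha), (lb, hb) = candidates[a], candidates[b]
                block_lo = cm_lo.matrix[la - 1:ha, lb - 1:hb]
                block_hi = cm_hi.matrix[la - 1:ha, lb - 1:hb]
                # strongest registry signal: max pair frequency in the block
                inter_lo = float(block_lo.max())
                inter_hi = float(block_hi.max())
                sel = np.r_[la - 1:ha, lb - 1:hb]
                strand_lo = float(p_lo[sel].mean())
                strand_hi = float(p_hi[sel].mean())
                key = (candidates[a], candidates[b])
                evidence_contact[key] = {"t_lo": inter_lo, "t_hi": inter_hi}
                evidence_strand[key] = {"t_lo": strand_lo, "t_hi": strand_hi}
                if inter_lo >= thresholds.contact_floor \
                        and strand_lo - strand_hi >= thresholds.strand_drop:
                    for seg in (candidates[a], candidates[b]):
                        if seg not in detected:
                            detected.append(seg)
                    pairs.append((a, b))

    verdict = "lock_detected" if pairs else "no_lock"
    return LockCall(verdict=verdict, segments=tuple(detected),
                    segment_pairs=tuple(pairs),
                    inter_segment_contact=evidence_contact,
                    strand_probability=evidence_strand,
                    global_mean_delta=gmean,
                    thresholds=thresholds,
                    candidate_segments=tuple(candidates))


# --------------------------------------------------------------------------
# Rg trend over a ladder


@dataclass
class TrendReport:
    """Monotone-trend summary of a per-rung ensemble mean."""

    classification: str          # decreasing | increasing | flat
    spearman_rho: float
    means: np.ndarray
    ses: np.ndarray
    temperatures: np.ndarray


def rg_trend(ensemble: EnsembleSet,
             config: AnalysisConfig = AnalysisConfig()) -> TrendReport:
    """Direction of ensemble-mean Rg across the ladder.

    Classified ``decreasing``/``increasing`` when the top and bottom rungs
    differ by more than twice their combined standard error and Spearman ρ
    on the rung means has the matching sign; ``flat`` otherwise.
    """
    temps = np.asarray(ensemble.temperatures, dtype=float)
    if len(temps) < 3:
        raise ValueError("trend classification needs at least 3 ladder rungs")
    means, ses = [], []
    for tr in ensemble.trajectories:
        rgs = radius_of_gyration(tr.coordinates)
        ms = ensemble_average(rgs, ensemble.equilibration_fraction,
                              config.block_count, name="rg",
                              temperature=tr.temperature)
        means.append(ms.mean)
        ses.append(ms.se)
    means = np.array(means)
    ses = np.array(ses)
    rho = float(sstats.spearmanr(temps, means).statistic)
    gap = means[-1] - means[0]
    sep = 2.0 * float(np.hypot(ses[0], ses[-1]))
    if gap < -sep and rho < 0:
        cls = "decreasing"
    elif gap > sep and rho > 0:
        cls = "increasing"
    else:
        cls = "flat"
    return TrendReport(classification=cls, spearman_rho=rho,
                       means=means, ses=ses, temperatures=temps)


# --------------------------------------------------------------------------
# Lock occupancy (generator instrumentation)


def lock_occupancy(trajectory: Trajectory, topology,
                   discard_fraction: float = 0.2,
                   formed_cutoff: float = 0.45,
                   extension_min: float = 0.56) -> float:
    """Fraction of retained frames in which at least half of the lock
    registry rungs are formed (pair distance below ``formed_cutoff`` with
    both strands locally extended)."""
    if topology.lock is None:
        raise ValueError("topology has no lock")
    reg = topology.lock.registry
    co = trajectory.coordinates
    co = co[int(discard_fraction * len(co)):]
    bbA = [topology.backbone_bead(i) for i, _ in reg]
    bbB = [topology.backbone_bead(j) for _, j in reg]
    d = np.linalg.norm(co[:, bbA] - co[:, bbB], axis=2)
    formed = d < formed_cutoff
    n = topology.n_residues

    def ext_ok(res_list):
        prev = [topology.backbone_bead(max(r - 1, 1)) for r in res_list]
        nxt = [topology.backbone_bead(min(r + 1, n)) for r in res_list]
        e = np.linalg.norm(co[:, prev] - co[:, nxt], axis=2)
        return e > extension_min

    formed &= ext_ok([i for i, _ in reg]) & ext_ok([j for _, j in reg])
    return float((formed.mean(axis=1) >= 0.5).mean())
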