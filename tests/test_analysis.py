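"""Δcontact / heatmap / lock-detection logic on constructed fixtures."""

import numpy as np
import pytest

from thermolock.analysis import (
    ContactHeatmap,
    DeltaContactProfile,
    LockDetectionConfig,
    TrendReport,
    delta_contact_profile,
    detect_lock,
    group_contact_heatmap,
    rg_trend,
)
from thermolock.energy import EnergyModel
from thermolock.metrics import AnalysisConfig, ChainView, contact_map
from thermolock.sampler import EnsembleSet, Trajectory
from thermolock.topology import build_preset

CFG0 = AnalysisConfig(equilibration_fraction=0.0)


def straight_chain_frame(topo, spacing=0.38):
    """Backbone on a line, side chains displaced in z; no contacts."""
    n = topo.n_residues
    frame = np.zeros((topo.n_beads, 3))
    for i in range(1, n + 1):
        frame[topo.backbone_bead(i)] = ((i - 1) * spacing, 0, 0)
        frame[topo.sidechain_bead(i)] = ((i - 1) * spacing, 0, 0.25)
    return frame


def pair_segments(frame, topo, seg_a, seg_b):
    """Move segment B to pair antiparallel with segment A (rungs at 0.32 nm,
    side chains facing so the cross-strand contact rule fires)."""
    (a0, a1), (b0, b1) = seg_a, seg_b
    out = frame.copy()
    for k, j in enumerate(range(b1, b0 - 1, -1)):
        x = out[topo.backbone_bead(a0 + k), 0]
        out[topo.backbone_bead(j)] = (x, 0.32, 0)
        out[topo.sidechain_bead(j)] = (x, 0.32, 0.25)
    # keep partner-strand neighbours extended (antiparallel: residue number
    # increases toward -x)
    out[topo.backbone_bead(b0 - 1)] = out[topo.backbone_bead(b0)] + (0.38, 0, 0)
    if b1 + 1 <= topo.n_residues:
        out[topo.backbone_bead(b1 + 1)] = out[topo.backbone_bead(b1)] - (0.38, 0, 0)
    return out


def cluster_residues(frame, topo, residues):
    """Pack the given residues' side chains into a tight ball (gains)."""
    out = frame.copy()
    rng = np.random.default_rng(0)
    center = np.array([30.0, 5.0, 0.0])
    for k, i in enumerate(residues):
        offset = 0.45 * rng.normal(size=3)
        out[topo.backbone_bead(i)] = center + offset
        out[topo.sidechain_bead(i)] = center + offset + (0, 0, 0.2)
    return out


def as_ensemble(frames, topo, temperature):
    frames = np.asarray(frames)
    tr = Trajectory(coordinates=frames,
                    sweep_indices=np.arange(len(frames), dtype=np.int64),
                    energies=np.zeros(len(frames)), temperature=temperature)
    return EnsembleSet(topology=topo, model=EnergyModel(),
                       temperatures=(temperature,), trajectories=[tr],
                       exchange_attempts=np.zeros(0, dtype=np.int64),
                       exchange_accepts=np.zeros(0, dtype=np.int64),
                       replica_walk=np.zeros((1, 1), dtype=np.int64),
                       seed=0, config_digest="fixture",
                       equilibration_fraction=0.0)


@pytest.fixture(scope="module")
def planted_two_lock_fixture():
    """Cold ensemble with two independent locked pairs; hot ensemble open
    with a dense nonspecific cluster (so the global mean Δcontact is
    positive)."""
    topo = build_preset("no_lock_homopolymer", 90, box_edge=60.0)
    base = straight_chain_frame(topo)
    cold = pair_segments(base, topo, (5, 9), (20, 24))
    cold = pair_segments(cold, topo, (35, 39), (50, 54))
    hot = cluster_residues(base, topo, range(60, 85))
    cold_frames = np.repeat(cold[None], 12, axis=0)
    hot_frames = np.repeat(hot[None], 12, axis=0)
    return (topo, as_ensemble(cold_frames, topo, 280.0),
            as_ensemble(hot_frames, topo, 310.0))


class TestDeltaContactProfile:
    def test_self_difference_is_zero(self, planted_two_lock_fixture):
        _, cold, _ = planted_two_lock_fixture
        prof = delta_contact_profile(cold, cold, CFG0)
        assert np.allclose(prof.values, 0.0)

    def test_antisymmetry(self, planted_two_lock_fixture):
        _, cold, hot = planted_two_lock_fixture
        ab = delta_contact_profile(cold, hot, CFG0)
        ba = delta_contact_profile(hot, cold, CFG0)
        assert np.allclose(ab.values, -ba.values)

    def test_single_pair_gain_localizes(self):
        topo = build_preset("no_lock_homopolymer", 30, box_edge=60.0)
        base = straight_chain_frame(topo)
        gained = base.copy()
        # bring side chains of residues 5 and 20 into contact, offset in y so
        # residue 20 stays clear of residues 4 and 6
        gained[topo.sidechain_bead(20)] = gained[topo.sidechain_bead(5)] \
            + np.array([0.0, 0.55, 0])
        gained[topo.backbone_bead(20)] = gained[topo.sidechain_bead(20)] \
            + np.array([0.0, 0.3, 0])
        cold = as_ensemble(np.repeat(base[None], 10, axis=0), topo, 280.0)
        # 4 of 10 hot frames have the contact: expected gain +0.4
        hot_frames = np.concatenate([np.repeat(gained[None], 4, axis=0),
                                     np.repeat(base[None], 6, axis=0)])
        hot = as_ensemble(hot_frames, topo, 310.0)
        prof = delta_contact_profile(cold, hot, CFG0)
        expected = np.zeros(30)
        expected[4] = expected[19] = 0.4
        assert np.allclose(prof.values, expected)

    def test_mismatched_chain_lengths_rejected(self):
        t1 = build_preset("no_lock_homopolymer", 20)
        t2 = build_preset("no_lock_homopolymer", 25)
        e1 = as_ensemble(np.zeros((3, t1.n_beads, 3)), t1, 280.0)
        e2 = as_ensemble(np.zeros((3, t2.n_beads, 3)), t2, 310.0)
        with pytest.raises(ValueError):
            delta_contact_profile(e1, e2, CFG0)


class TestGroupHeatmap:
    def test_no_cross_contacts_gives_zero(self, planted_two_lock_fixture):
        topo, cold, hot = planted_two_lock_fixture
        hm = group_contact_heatmap([hot], [(5, 9), (20, 24)], CFG0)
        assert hm.value(310.0, 0, 1) == 0.0

    def test_saturated_groups_give_unit_cross_frequency(self):
        # every cross pair of the two groups in contact in every frame
        topo = build_preset("no_lock_homopolymer", 20, box_edge=60.0)
        frame = straight_chain_frame(topo)
        rng = np.random.default_rng(1)
        center = np.array([20.0, 0, 0])
        for i in list(range(2, 5)) + list(range(10, 13)):
            p = center + 0.2 * rng.normal(size=3)
            frame[topo.backbone_bead(i)] = p + (0, 0.3, 0)
            frame[topo.sidechain_bead(i)] = p
        ens = as_ensemble(np.repeat(frame[None], 5, axis=0), topo, 280.0)
        hm = group_contact_heatmap([ens], [(2, 4), (10, 12)], CFG0)
        assert hm.value(280.0, 0, 1) == pytest.approx(1.0)

    def test_heatmap_equals_contact_map_subblock(self, planted_two_lock_fixture):
        topo, cold, _ = planted_two_lock_fixture
        groups = [(5, 9), (35, 39)]
        hm = group_contact_heatmap([cold], groups, CFG0)
        view = ChainView.from_topology(topo)
        cm = contact_map(cold.trajectories[0].coordinates, view, CFG0,
                         discard_equilibration=False)
        for a, (la, ha) in enumerate(groups):
            for b, (lb, hb) in enumerate(groups):
                block = cm.matrix[la - 1:ha, lb - 1:hb].mean()
                assert hm.values[0, a, b] == pytest.approx(block)

    def test_empty_group_rejected(self, planted_two_lock_fixture):
        topo, cold, _ = planted_two_lock_fixture
        with pytest.raises(ValueError):
            group_contact_heatmap([cold], [(8, 5)], CFG0)


class TestDetectLock:
    def test_two_planted_pairs_both_reported(self, planted_two_lock_fixture):
        topo, cold, hot = planted_two_lock_fixture
        prof = delta_contact_profile(cold, hot, CFG0)
        call = detect_lock(prof, cold, hot, CFG0)
        assert call.verdict == "lock_detected"
        assert len(call.segment_pairs) == 2
        segs = sorted(call.segments)
        for found, planted in zip(segs, [(5, 9), (20, 24), (35, 39), (50, 54)]):
            assert abs(found[0] - planted[0]) <= 1
            assert abs(found[1] - planted[1]) <= 1

    def test_flat_profile_no_lock(self, planted_two_lock_fixture):
        topo, cold, _ = planted_two_lock_fixture
        prof = delta_contact_profile(cold, cold, CFG0)
        call = detect_lock(prof, cold, cold, CFG0)
        assert call.verdict == "no_lock"
        assert call.segments == ()

    def test_negative_global_mean_blocks_candidates(self, planted_two_lock_fixture):
        topo, cold, hot = planted_two_lock_fixture
        # hot->cold direction: global mean negative, so no lock is called
        prof = delta_contact_profile(hot, cold, CFG0)
        call = detect_lock(prof, hot, cold, CFG0)
        assert call.verdict == "no_lock"

    def test_verdict_requires_strand_drop(self, planted_two_lock_fixture):
        topo, cold, hot = planted_two_lock_fixture
        prof = delta_contact_profile(cold, hot, CFG0)
        strict = LockDetectionConfig(strand_drop=1.5)  # unattainable
        call = detect_lock(prof, cold, hot, CFG0, strict)
        assert call.verdict == "no_lock"
        assert call.candidate_segments  # candidates found, evidence failed


class TestRgTrend:
    def _ensemble_with_rgs(self, rg_per_rung, temps, jitter=1e-3):
        topo = build_preset("no_lock_homopolymer", 4)
        rng = np.random.default_rng(0)
        trajectories = []
        for rg, t in zip(rg_per_rung, temps):
            frames = np.zeros((40, topo.n_beads, 3))
            frames[:, 0, 0] = rg + jitter * rng.normal(size=40)
            frames[:, 1, 0] = -(rg + jitter * rng.normal(size=40))
            # remaining beads at the origin: Rg ~ rg * sqrt(2/n_beads)
            trajectories.append(Trajectory(
                coordinates=frames,
                sweep_indices=np.arange(40, dtype=np.int64),
                energies=np.zeros(40), temperature=t))
        return EnsembleSet(topology=topo, model=EnergyModel(),
                           temperatures=tuple(temps),
                           trajectories=trajectories,
                           exchange_attempts=np.zeros(0, dtype=np.int64),
                           exchange_accepts=np.zeros(0, dtype=np.int64),
                           replica_walk=np.zeros((1, len(temps)), dtype=np.int64),
                           seed=0, config_digest="fixture",
                           equilibration_fraction=0.0)

    def test_strictly_ordered_means_decreasing(self):
        ens = self._ensemble_with_rgs([2.0, 1.8, 1.6], [280.0, 298.0, 316.0])
        rep = rg_trend(ens)
        assert rep.classification == "decreasing"
        assert rep.spearman_rho < 0

    def test_constant_means_flat(self):
        ens = self._ensemble_with_rgs([1.8, 1.8, 1.8], [280.0, 298.0, 316.0])
        assert rg_trend(ens).classification == "flat"

    def test_too_few_rungs_rejected(self):
        ens = self._ensemble_with_rgs([2.0, 1.8], [280.0, 316.0])
        with pytest.raises(ValueError):
            rg_trend(ens)
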