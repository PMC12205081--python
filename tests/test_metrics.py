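"""Metric suite checks against closed forms and brute-force oracles."""

import numpy as np
import pytest

from thermolock.metrics import (
    AnalysisConfig,
    ChainView,
    HBondSiteSet,
    beta_strand_flags,
    beta_strand_probability,
    contact_map,
    count_hbonds,
    ensemble_average,
    hbond_series,
    radius_of_gyration,
    sasa,
    side_chain_contacts,
    sphere_points,
)
from thermolock.topology import build_preset


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestRadiusOfGyration:
    def test_coincident_particles_zero(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_two_equal_masses_half_separation(self):
        c = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        assert radius_of_gyration(c) == pytest.approx(0.6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(30, 3))
        m = rng.uniform(1, 12, 30)
        com = (c * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((c - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(c, m) == pytest.approx(expected, rel=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(20, 3))
        r0 = radius_of_gyration(c)
        moved = c @ random_rotation(rng).T + np.array([3.0, -1.0, 2.0])
        assert radius_of_gyration(moved) == pytest.approx(r0, rel=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)))


class TestSasa:
    def test_isolated_sphere_analytic(self):
        cfg = AnalysisConfig(sasa_points=960)
        a = sasa(np.zeros((1, 3)), np.array([0.2]), cfg)
        expected = 4 * np.pi * (0.2 + cfg.sasa_probe_radius) ** 2
        assert a[0] == pytest.approx(expected, rel=1e-6)

    def test_distant_spheres_additive(self):
        cfg = AnalysisConfig()
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        radii = np.array([0.2, 0.3])
        a = sasa(coords, radii, cfg)
        for i in range(2):
            expected = 4 * np.pi * (radii[i] + cfg.sasa_probe_radius) ** 2
            assert a[i] == pytest.approx(expected, rel=1e-6)

    def test_overlapping_dimer_against_denser_sampling(self):
        coords = np.array([[0.0, 0, 0], [0.35, 0, 0]])
        radii = np.array([0.2, 0.2])
        coarse = sasa(coords, radii, AnalysisConfig(sasa_points=960)).sum()
        fine = sasa(coords, radii, AnalysisConfig(sasa_points=9600)).sum()
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_buried_particle_zero(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        radii = np.array([0.1, 0.5])
        a = sasa(coords, radii, AnalysisConfig())
        assert a[0] == 0.0


class TestContacts:
    @pytest.fixture()
    def view(self):
        return ChainView.from_topology(build_preset("no_lock_homopolymer", 25,
                                                    box_edge=50.0))

    def test_below_cutoff_distant_in_sequence_is_contact(self, view):
        frame = np.zeros((50, 3))
        frame[0::2] = np.arange(25)[:, None] * np.array([2.0, 0, 0])
        frame[1::2] = frame[0::2] + np.array([0, 0.25, 0])
        # bring side chains of residues 3 and 14 within 0.5 nm
        frame[2 * 14 + 1] = frame[2 * 3 + 1] + np.array([0.5, 0, 0])
        c = side_chain_contacts(frame, view)
        assert c[3, 14] and c[14, 3]

    def test_adjacent_residues_excluded(self, view):
        frame = np.zeros((50, 3))
        frame[0::2] = np.arange(25)[:, None] * np.array([0.19, 0, 0])
        frame[1::2] = frame[0::2] + np.array([0, 0.25, 0])
        c = side_chain_contacts(frame, view)
        # neighbours at |i-j| <= 3 are all within 0.6 nm yet excluded
        assert not c.any()
        cfg = AnalysisConfig(adjacency_exclusion=2)
        c2 = side_chain_contacts(frame, view, cfg)
        assert c2[0, 3]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, view, seed):
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 3.0, (50, 3))
        cfg = AnalysisConfig()
        c = side_chain_contacts(frame, view, cfg)
        for i in range(25):
            for j in range(25):
                expected = (abs(i - j) > cfg.adjacency_exclusion and i != j
                            and np.linalg.norm(frame[2 * i + 1] - frame[2 * j + 1])
                            < cfg.contact_cutoff)
                assert c[i, j] == expected

    def test_contact_map_symmetric_bounded(self, view):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 2.0, (10, 50, 3))
        cm = contact_map(frames, view, discard_equilibration=False)
        assert np.allclose(cm.matrix, cm.matrix.T)
        assert cm.matrix.min() >= 0 and cm.matrix.max() <= 1
        band = [cm.matrix[i, j] for i in range(25) for j in range(25)
                if 0 < abs(i - j) <= 3]
        assert np.all(np.array(band) == 0)

    def test_intermolecular_scope_no_adjacency_exclusion(self):
        topo = build_preset("no_lock_homopolymer", 10, n_chains=2,
                            box_edge=50.0)
        view = ChainView.from_topology(topo)
        frame = np.zeros((40, 3))
        frame[0::2] = np.arange(20)[:, None] * np.array([2.0, 0, 0])
        frame[1::2] = frame[0::2] + np.array([0, 0.25, 0])
        # residue 1 of chain A touching residue 1 of chain B
        frame[2 * 10 + 1] = frame[1] + np.array([0.3, 0, 0])
        c = side_chain_contacts(frame, view, scope="intermolecular")
        assert c[0, 10]
        assert not side_chain_contacts(frame, view, scope="intramolecular")[0, 10]


class TestHBonds:
    def _sites(self):
        # one donor with hydrogen (atoms 0: D, 1: H), one acceptor (atom 2)
        return HBondSiteSet(donor_atoms=np.array([0]), donor_h=np.array([1]),
                            donor_residue=np.array([0]),
                            acceptor_atoms=np.array([2]),
                            acceptor_residue=np.array([5]))

    def _frame(self, da, angle_deg):
        ang = np.radians(angle_deg)
        frame = np.zeros((3, 3))
        frame[1] = [0.1 * np.cos(ang), 0.1 * np.sin(ang), 0]  # H
        frame[2] = [da, 0, 0]                                  # A along x
        return frame

    def test_inside_both_cutoffs_is_bond(self):
        n, bonds = count_hbonds(self._frame(0.30, 10.0), self._sites())
        assert n == 1 and bonds == [(0, 2)]

    def test_distance_fails(self):
        n, _ = count_hbonds(self._frame(0.36, 5.0), self._sites())
        assert n == 0

    def test_angle_fails(self):
        n, _ = count_hbonds(self._frame(0.30, 40.0), self._sites())
        assert n == 0

    def test_missing_hydrogen_distance_only(self):
        sites = self._sites()
        sites.donor_h = np.array([-1])
        n, _ = count_hbonds(self._frame(0.30, 170.0), sites)
        assert n == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_random_triples_match_per_triple_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nd, na = 10, 10
        frame = rng.uniform(0, 1.0, (nd * 2 + na, 3))
        sites = HBondSiteSet(
            donor_atoms=np.arange(nd),
            donor_h=np.arange(nd, 2 * nd),
            donor_residue=np.arange(nd),
            acceptor_atoms=np.arange(2 * nd, 2 * nd + na),
            acceptor_residue=np.arange(100, 100 + na))
        cfg = AnalysisConfig()
        n, bonds = count_hbonds(frame, sites, cfg, scope="intramolecular")
        expected = set()
        for d in range(nd):
            for a in range(na):
                dxyz, hxyz, axyz = frame[d], frame[nd + d], frame[2 * nd + a]
                if np.linalg.norm(axyz - dxyz) > cfg.hbond_distance_cutoff:
                    continue
                v1, v2 = hxyz - dxyz, axyz - dxyz
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if ang < cfg.hbond_angle_cutoff:
                    expected.add((d, 2 * nd + a))
        assert set(bonds) == expected


class TestBetaStrand:
    def _paired_frame(self, topo):
        """Two straight antiparallel strands joined at the lock registry."""
        frame = np.zeros((topo.n_beads, 3))
        b = topo.backbone_bond_length
        n = topo.n_residues
        for i in range(1, n + 1):
            frame[topo.backbone_bead(i)] = ((i - 1) * b, 0, 0)
            frame[topo.sidechain_bead(i)] = ((i - 1) * b, 0, 0.25)
        lock = topo.lock
        for (ia, ib) in lock.registry:
            x = frame[topo.backbone_bead(ia), 0]
            frame[topo.backbone_bead(ib)] = (x, 0.32, 0)
            frame[topo.sidechain_bead(ib)] = (x, 0.32, -0.25)
        # keep segment-b neighbours extended: the partner strand is
        # antiparallel, so residue number increases toward -x
        (b0, b1) = lock.segment_b
        frame[topo.backbone_bead(b0 - 1)] = \
            frame[topo.backbone_bead(b0)] + (b, 0, 0)
        frame[topo.backbone_bead(b1 + 1)] = \
            frame[topo.backbone_bead(b1)] - (b, 0, 0)
        return frame

    def test_saturated_lock_gives_probability_one(self):
        topo = build_preset("wt", 90)
        view = ChainView.from_topology(topo)
        frame = self._paired_frame(topo)
        frames = np.repeat(frame[None], 5, axis=0)
        prob = beta_strand_probability(frames, view,
                                       discard_equilibration=False)
        (a0, a1) = topo.lock.segment_a
        (b0, b1) = topo.lock.segment_b
        assert np.all(prob[a0 - 1:a1] == 1.0)
        assert np.all(prob[b0 - 1:b1] == 1.0)

    def test_generated_coil_has_low_probability(self):
        # attraction-free chain at high temperature: excluded volume keeps
        # trace beads off the rung distance, so strand calls are rare
        from thermolock.energy import EnergyModel
        from thermolock.sampler import ReplicaLadder, run_remd

        topo = build_preset("no_lock_homopolymer", 30)
        model = EnergyModel(alpha=0.0)
        ens = run_remd(topo, model, ReplicaLadder((316.0,)), n_sweeps=1500,
                       seed=4, frame_stride=20)
        view = ChainView.from_topology(topo)
        prob = beta_strand_probability(ens.trajectory(316.0).coordinates, view)
        assert np.all(prob < 0.05)

    def test_short_chain_rejected(self):
        topo = build_preset("no_lock_homopolymer", 4)
        view = ChainView.from_topology(topo)
        with pytest.raises(ValueError):
            beta_strand_flags(np.zeros((8, 3)), view)


class TestEnsembleAverage:
    def test_constant_series(self):
        ms = ensemble_average(np.full(100, 3.5), 0.2, 10)
        assert ms.mean == 3.5 and ms.se == 0.0

    def test_discard_fraction_keeps_trailing_frames(self):
        vals = np.arange(500, dtype=float)
        ms = ensemble_average(vals, 0.2, 10)
        assert len(ms.values) == 400
        assert ms.values[0] == 100.0  # frames 101..500 retained

    def test_iid_gaussian_se_scale(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 2.0, 1000)
        ms = ensemble_average(vals, 0.0, 10)
        theory = 2.0 / np.sqrt(1000)
        assert ms.se < 3 * theory
        assert ms.se > theory / 3

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average(np.arange(5.0), 0.0, 10)
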