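import numpy as np
import pytest

from accommodate import dynamics
from accommodate.containers import ObservableSeries
from accommodate.dynamics import (
    EventRecord,
    detect_accommodation_events,
    detect_dissociation,
    energy,
    forces,
    run_langevin,
    run_nve,
)
from accommodate.errors import (
    IntegrityError,
    ParameterError,
    SingularityError,
)
from accommodate.forcefield import Topology, build_bonded_terms
from accommodate.structures import Structure

from conftest import make_chain, single_bond_topology


def series(values, times=None):
    values = np.asarray(values, float)
    t = np.arange(len(values), dtype=float) if times is None else times
    return ObservableSeries("probe", values, t)


class TestEnergy:
    def test_stretched_bond(self):
        """V = eps_r/2 (r - r0)^2: a 1 A stretch at eps_r = 50 costs 25."""
        top, s = single_bond_topology(r0=3.8)
        coord = s.coord.copy()
        coord[1, 0] += 1.0
        assert energy(top, coord).bonds == pytest.approx(25.0)

    def test_dihedral_rotated_by_pi_costs_three_eps(self):
        """F_D(pi) = (1 - cos pi) + 1/2 (1 - cos 3pi) = 3."""
        s, conn = make_chain(4, jitter=0.7, seed=5)
        bt = build_bonded_terms(s, conn, classify=lambda names: "backbone",
                                eps_backbone=1.0)
        top = Topology(n_atoms=4, bonded=bt, contacts=[])
        # rotate the last atom about the 1-2 bond axis by pi
        axis = s.coord[2] - s.coord[1]
        axis = axis / np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec(np.pi * axis)
        coord = s.coord.copy()
        coord[3] = rot.apply(coord[3] - coord[2]) + coord[2]
        e = energy(top, coord)
        assert e.backbone_dihedrals == pytest.approx(3.0, abs=1e-9)

    def test_noncontact_pair_at_sigma(self):
        """Two non-contact atoms at r = sigma_NC = 2.5 A cost eps_NC = 0.1."""
        s = Structure(["A", "B"], [1, 1], ["X", "X"], ["C1", "C1"],
                      ["C", "C"], [[0, 0, 0], [2.5, 0, 0]])
        from accommodate.forcefield import BondedTerms
        top = Topology(n_atoms=2, bonded=BondedTerms.empty(), contacts=[])
        assert energy(top, s.coord).noncontacts == pytest.approx(0.1)

    @pytest.mark.parametrize("fixture", ["arm_topology_v1", "arm_topology_v2"])
    def test_reference_energy(self, request, arm_system, fixture):
        """At the reference all bonded terms vanish and the contact term is
        minus the summed weighted contact strengths (every pair at sigma for
        the 6-12 flavor; the Gaussian flavor adds only its tiny
        excluded-volume core)."""
        top = request.getfixturevalue(fixture)
        e = energy(top, arm_system.state_A.coord)
        assert e.bonds == pytest.approx(0.0, abs=1e-12)
        assert e.angles == pytest.approx(0.0, abs=1e-12)
        expected = -sum(c.eps * c.weight for c in top.contacts
                        if c.basin in ("AT", "shared"))
        contrib_aa = sum(
            c.eps * c.weight for c in top.contacts if c.basin == "AA"
        )
        assert e.contacts < 0
        assert e.contacts == pytest.approx(expected, abs=max(0.05, 0.2 * contrib_aa))

    def test_total_is_sum_of_components(self, arm_topology_v1, arm_system):
        rng = np.random.default_rng(0)
        coord = arm_system.state_A.coord + rng.normal(0, 0.2, (arm_topology_v1.n_atoms, 3))
        e = energy(arm_topology_v1, coord)
        parts = [e.bonds, e.angles, e.impropers, e.planar,
                 e.backbone_dihedrals, e.sidechain_dihedrals, e.contacts,
                 e.noncontacts]
        assert e.total == pytest.approx(sum(parts), rel=1e-9)

    def test_roster_mismatch_rejected(self, arm_topology_v1):
        with pytest.raises(IntegrityError):
            energy(arm_topology_v1, np.zeros((3, 3)))

    def test_overlapping_atoms_rejected(self, arm_topology_v1, arm_system):
        coord = arm_system.state_A.coord.copy()
        coord[1] = coord[0]
        with pytest.raises(SingularityError):
            energy(arm_topology_v1, coord)


class TestForces:
    @pytest.mark.parametrize("fixture", ["arm_topology_v1", "arm_topology_v2"])
    def test_matches_finite_differences(self, request, arm_system, fixture):
        top = request.getfixturevalue(fixture)
        rng = np.random.default_rng(3)
        coord = arm_system.state_A.coord + rng.normal(0, 0.25, (top.n_atoms, 3))
        f = forces(top, coord)
        h = 1e-5
        fd = np.zeros_like(f)
        for i in range(top.n_atoms):
            for d in range(3):
                cp, cm = coord.copy(), coord.copy()
                cp[i, d] += h
                cm[i, d] -= h
                fd[i, d] = -(energy(top, cp).total - energy(top, cm).total) / (2 * h)
        assert np.abs(f - fd).max() / np.abs(f).max() < 1e-5

    def test_zero_at_bonded_reference(self):
        s, conn = make_chain(5, jitter=0.5, seed=8)
        bt = build_bonded_terms(s, conn)
        top = Topology(n_atoms=5, bonded=bt, contacts=[],
                       eps_nc=0.0)  # bonded-only system
        f = forces(top, s.coord)
        assert np.abs(f).max() < 1e-8

    def test_net_force_and_torque_vanish(self, arm_topology_v1, arm_system):
        rng = np.random.default_rng(9)
        coord = arm_system.state_A.coord + rng.normal(0, 0.3, (arm_topology_v1.n_atoms, 3))
        f = forces(arm_topology_v1, coord)
        assert np.abs(f.sum(axis=0)).max() < 1e-8
        assert np.abs(np.cross(coord, f).sum(axis=0)).max() < 1e-8


class TestLangevin:
    def test_same_seed_bitwise_identical(self, arm_topology_v1, arm_system):
        a = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=2000,
                         seed=42, stride=100)
        b = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=2000,
                         seed=42, stride=100)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self, arm_topology_v1, arm_system):
        a = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=2000,
                         seed=1, stride=100)
        b = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=2000,
                         seed=2, stride=100)
        assert not np.array_equal(a.frames, b.frames)

    def test_recording_schedule(self, arm_topology_v1, arm_system):
        traj = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=1000,
                            seed=0, stride=250, dt=0.002)
        np.testing.assert_allclose(traj.times,
                                   [0.0, 0.5, 1.0, 1.5, 2.0], atol=1e-12)

    def test_harmonic_bond_variance_short(self):
        """Equipartition sanity at reduced sampling: var(r - r0) ~ T/eps_r."""
        top, s = single_bond_topology()
        traj = run_langevin(top, s, n_steps=200_000, temperature=0.5,
                            seed=3, stride=20)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        assert np.var(d - 3.8) == pytest.approx(0.01, rel=0.25)

    def test_parameter_validation(self, arm_topology_v1, arm_system):
        with pytest.raises(ParameterError):
            run_langevin(arm_topology_v1, arm_system.state_A, n_steps=0)
        with pytest.raises(ParameterError):
            run_langevin(arm_topology_v1, arm_system.state_A, n_steps=10,
                         temperature=-1.0)


class TestNVE:
    def test_zero_velocity_at_reference_stays_put(self):
        top, s = single_bond_topology()
        traj, eseries = run_nve(top, s, n_steps=1000, stride=100)
        np.testing.assert_allclose(eseries.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.frames[-1], s.coord, atol=1e-9)

    def test_harmonic_period_matches_analytic(self):
        """omega = sqrt(k / mu) with k = eps_r = 50 and reduced mass 1/2."""
        top, s = single_bond_topology()
        coord = s.coord.copy()
        coord[1, 0] += 0.3
        traj, _ = run_nve(top, coord, n_steps=80_000, dt=0.002, stride=1)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1) - 3.8
        sign = np.sign(d)
        crossings = np.where(np.diff(sign) > 0)[0]
        t = traj.times
        # linear interpolation of upward zero crossings
        tc = t[crossings] + (t[crossings + 1] - t[crossings]) * (
            -d[crossings] / (d[crossings + 1] - d[crossings]))
        period = np.diff(tc).mean()
        omega = np.sqrt(50.0 / 0.5)
        assert period == pytest.approx(2 * np.pi / omega, rel=1e-3)

    def test_energy_drift_bound(self, arm_topology_v1, arm_system):
        rng = np.random.default_rng(5)
        vel = rng.normal(0, np.sqrt(0.5), arm_system.state_A.coord.shape)
        traj, eseries = run_nve(arm_topology_v1, arm_system.state_A,
                                n_steps=20_000, dt=0.002, stride=100,
                                velocities=vel)
        dof = 3 * arm_topology_v1.n_atoms
        drift = np.abs(eseries.values - eseries.values[0]).max() / dof
        assert drift < 1e-4

    def test_drift_scales_as_dt_squared(self):
        """Velocity Verlet is second order: doubling dt grows the energy
        error roughly fourfold."""
        top, s = single_bond_topology()
        coord = s.coord.copy()
        coord[1, 0] += 0.5

        def err(dt):
            _, es = run_nve(top, coord, n_steps=int(8.0 / dt), dt=dt, stride=10)
            return np.abs(es.values - es.values[0]).max()

        r = err(0.004) / err(0.002)
        assert 2.5 < r < 7.0


class TestEventDetection:
    def test_single_crossing(self):
        evs = detect_accommodation_events(series([40, 33, 31, 30, 40]),
                                          threshold=32.5, release=35)
        assert len(evs) == 1
        assert evs[0].entry_time == 2.0
        assert evs[0].exit_time == 4.0

    def test_no_crossing(self):
        assert detect_accommodation_events(series([40, 36, 38, 50])) == []

    def test_square_wave_counts_each_opening(self):
        vals = ([40] * 5 + [30] * 5 + [40] * 5 + [30] * 5 + [40] * 5
                + [30] * 5 + [40] * 5)
        evs = detect_accommodation_events(series(vals))
        assert len(evs) == 3

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        vals = 35 + np.cumsum(rng.normal(0, 1.5, 500))
        vals = np.clip(vals, 20, 60)
        got = detect_accommodation_events(series(vals), 32.5, 35.0)
        # independent scan
        expected = 0
        armed = True
        for v in vals:
            if armed and v < 32.5:
                expected += 1
                armed = False
            elif not armed and v > 35.0:
                armed = True
        assert len(got) == expected

    def test_hysteresis_suppresses_boundary_jitter(self):
        vals = [40, 32, 33, 32, 33, 32, 40]  # jitter around threshold
        evs = detect_accommodation_events(series(vals), 32.5, 35.0)
        assert len(evs) == 1

    def test_prepending_high_frames_is_invariant(self):
        vals = [40, 33, 31, 30, 40]
        a = detect_accommodation_events(series(vals))
        b = detect_accommodation_events(series([50] * 10 + vals))
        assert len(a) == len(b)

    def test_release_below_threshold_rejected(self):
        with pytest.raises(ParameterError):
            detect_accommodation_events(series([40]), 32.5, 30.0)

    def test_event_record_ordering_enforced(self):
        with pytest.raises(IntegrityError):
            EventRecord("accommodation", 5.0, 3.0, 32.5)


class TestDissociation:
    def test_monotone_increase_flagged(self):
        ev = detect_dissociation(series(np.linspace(40, 90, 50)),
                                 threshold=60, window=5)
        assert ev is not None and ev.kind == "dissociation"

    def test_accommodation_first_returns_none(self):
        vals = [40, 30, 40, 70, 70, 70, 70, 70, 70]
        assert detect_dissociation(series(vals), 60, 3) is None

    def test_borderline_matches_window_scan(self):
        rng = np.random.default_rng(4)
        vals = 55 + np.cumsum(rng.normal(0.1, 2.0, 300))
        got = detect_dissociation(series(vals), threshold=60, window=10,
                                  accommodation_threshold=0.0)
        run = 0
        expected = None
        for k, v in enumerate(vals):
            run = run + 1 if v > 60 else 0
            if run >= 10:
                expected = k - 9
                break
        if expected is None:
            assert got is None
        else:
            assert got is not None and got.entry_time == float(expected)


class TestTrajectoryIO:
    def test_tsv_round_trip(self, tmp_path, arm_topology_v1, arm_system):
        traj = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=500,
                            seed=1, stride=100)
        path = tmp_path / "traj.tsv"
        dynamics.write_trajectory_tsv(traj, str(path))
        back = dynamics.read_trajectory(str(path))
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-5)
        np.testing.assert_allclose(back.times, traj.times, atol=1e-9)

    def test_multimodel_pdb_round_trip(self, tmp_path, arm_topology_v1,
                                       arm_system):
        traj = run_langevin(arm_topology_v1, arm_system.state_A, n_steps=300,
                            seed=1, stride=100)
        path = tmp_path / "traj.pdb"
        dynamics.write_trajectory_pdb(traj, arm_system.state_A, str(path))
        back = dynamics.read_trajectory(str(path))
        assert back.frames.shape == traj.frames.shape
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-2)
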