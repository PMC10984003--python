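import numpy as np
import pytest

import fibrilcg as fc
from fibrilcg.dynamics import kinetic_temperature, minimize, run_tensile
from fibrilcg.forcefield import total_energy
from fibrilcg.units import MVV2E


def total_E(model, vel, ff):
    mass = ff.mass_by_species()[model.species]
    ke = 0.5 * MVV2E * float((mass[:, None] * vel * vel).sum())
    return total_energy(model, ff)["E_total"] + ke


class TestNVE:
    def test_rest_state_stays_at_rest(self, ff):
        m = fc.two_particle_model(14.0)
        m2, v = fc.step_nve(m, dt=1.0, n=100, forcefield=ff)
        np.testing.assert_allclose(m2.positions, m.positions, atol=1e-12)
        assert np.all(v == 0.0)

    def test_harmonic_dimer_energy_drift(self, ff):
        """Stretched dimer oscillates 1e4 steps with < 1e-4 relative drift."""
        m = fc.two_particle_model(15.0)
        e0 = total_E(m, np.zeros((2, 3)), ff)
        m2, v = fc.step_nve(m, dt=1.0, n=10_000, forcefield=ff)
        e1 = total_E(m2, v, ff)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_momentum_conserved_without_steering(self, ff):
        m = fc.two_particle_model(15.5)
        rng = np.random.default_rng(1)
        v0 = rng.standard_normal((2, 3)) * 1e-4
        mass = ff.mass_by_species()[m.species][:, None]
        p0 = (mass * v0).sum(axis=0)
        _, v1 = fc.step_nve(m, dt=1.0, n=5000, velocities=v0, forcefield=ff)
        p1 = (mass * v1).sum(axis=0)
        np.testing.assert_allclose(p1, p0, atol=1e-10)


class TestThermostat:
    def test_reaches_and_holds_target_temperature(self, ff, mini7):
        """Mean kinetic temperature within 10% of 300 K on a mini fibril."""
        proto = fc.TensileProtocol(dt=10.0, T=300.0, damping=500.0,
                                   v_pull=0.0, sample_every=100,
                                   rebuild_every=50)
        m = fc.equilibrate(mini7, proto, seed=2, n_steps=2000, forcefield=ff)
        tr = run_tensile(m, proto, seed=3, forcefield=ff, n_steps=3000)
        t_mean = tr.temperature[len(tr.temperature) // 2:].mean()
        assert t_mean == pytest.approx(300.0, rel=0.10)

    def test_zero_steps_is_identity(self, ff, mini7):
        proto = fc.TensileProtocol()
        m = fc.equilibrate(mini7, proto, seed=0, n_steps=0, forcefield=ff)
        np.testing.assert_array_equal(m.positions, mini7.positions)

    def test_divergence_raises_instability_error(self, ff):
        m = fc.two_particle_model(15.0)
        # absurd time step on a stiff bond, no damping to absorb it
        proto = fc.TensileProtocol(dt=1e5, T=300.0, damping=0.0,
                                   sample_every=100, rebuild_every=20)
        with pytest.raises(fc.InstabilityError, match="dt"):
            fc.equilibrate(m, proto, seed=0, n_steps=200, forcefield=ff,
                           minimize_first=False)


class TestMinimize:
    def test_reduces_energy_and_max_force(self, ff, mini7):
        m = fc.mineralize(mini7, fc.MineralPattern("reference_edge", 60.0), ff)
        e0 = total_energy(m, ff)["E_total"]
        m2 = minimize(m, ff, max_iter=200)
        e1 = total_energy(m2, ff)["E_total"]
        assert e1 < e0


class TestSteering:
    def test_grip_separation_follows_exact_kinematics(self, ff, mini7):
        """Grip separation increases by v_pull * n * dt, force-independent."""
        proto = fc.TensileProtocol(dt=10.0, T=10.0, damping=1000.0,
                                   v_pull=1e-3, sample_every=100,
                                   rebuild_every=50, stop_at_rupture=False)
        n = 500
        sep0 = (mini7.positions[mini7.grip_right, 0].mean()
                - mini7.positions[mini7.grip_left, 0].mean())
        tr = run_tensile(mini7, proto, seed=0, forcefield=ff, n_steps=n)
        # reconstruct final separation from the stored frames clock
        assert tr.strains[-1] == pytest.approx(
            1e-3 * n * 10.0 / tr.gauge, rel=1e-12)

    def test_null_pull_force_is_noise(self, ff, mini7):
        """v_pull = 0: the force trace is thermal noise around zero."""
        proto = fc.TensileProtocol(dt=10.0, T=300.0, damping=500.0,
                                   v_pull=0.0, sample_every=100,
                                   rebuild_every=50)
        m = fc.equilibrate(mini7, proto, seed=4, n_steps=1000, forcefield=ff)
        tr = run_tensile(m, proto, seed=5, forcefield=ff, n_steps=2000)
        f = tr.force[2:]
        assert abs(f.mean()) < 3.0 * f.std() / np.sqrt(len(f)) + 5.0

    def test_single_bond_quasistatic_force_matches_bond_law(self, ff):
        """A slowly pulled dimer traces the trilinear force curve within 2%."""
        m = fc.two_particle_model(14.0)
        m.grip_left = np.array([0])
        m.grip_right = np.array([1])
        m.meta["gauge"] = [0.0, 14.0]
        proto = fc.TensileProtocol(dt=5.0, T=0.0, damping=0.0, v_pull=2e-4,
                                   sample_every=100, rebuild_every=100,
                                   stop_at_rupture=False, max_strain=0.55)
        tr = run_tensile(m, proto, seed=0, forcefield=ff)
        r = 14.0 + tr.strains * 14.0
        spec = ff.bonds["collagen"]
        intact = r < spec.rbreak
        expect = np.array([abs(fc.bond_force(spec, ri)[0]) for ri in r])
        meas = tr.force
        sel = intact & (r > 14.5)
        rel = np.abs(meas[sel] - expect[sel]) / expect[sel]
        assert np.max(rel) < 0.02
        # and the bond ends up broken past rbreak + a
        assert tr.break_step[0] >= 0

    def test_pull_requires_grips(self, ff):
        m = fc.two_particle_model(14.0)
        with pytest.raises(ValueError, match="grip"):
            run_tensile(m, fc.TensileProtocol(), seed=0, forcefield=ff)

    def test_broken_counts_non_decreasing(self, ff):
        m = fc.two_particle_model(14.0, bond_type=2)
        m.grip_left = np.array([0])
        m.grip_right = np.array([1])
        m.meta["gauge"] = [0.0, 14.0]
        proto = fc.TensileProtocol(dt=5.0, T=0.0, damping=0.0, v_pull=5e-4,
                                   sample_every=100, rebuild_every=100,
                                   stop_at_rupture=False, max_strain=1.5)
        tr = run_tensile(m, proto, seed=0, forcefield=ff)
        for c in range(3):
            assert np.all(np.diff(tr.n_broken[:, c]) >= 0)
        assert tr.n_broken[-1, 2] == 1  # the AGE dimer parted

    def test_timestamps_strictly_increasing(self, ff, mini7):
        proto = fc.TensileProtocol(dt=10.0, T=100.0, damping=500.0,
                                   v_pull=1e-3, sample_every=100,
                                   rebuild_every=50, stop_at_rupture=False)
        tr = run_tensile(mini7, proto, seed=0, forcefield=ff, n_steps=400)
        assert np.all(np.diff(tr.times) > 0)


def test_same_seed_reproduces_trajectory(ff, mini7):
    proto = fc.TensileProtocol(dt=10.0, T=300.0, damping=500.0, v_pull=1e-3,
                               sample_every=100, rebuild_every=50,
                               stop_at_rupture=False)
    t1 = run_tensile(mini7, proto, seed=11, forcefield=ff, n_steps=300)
    t2 = run_tensile(mini7, proto, seed=11, forcefield=ff, n_steps=300)
    np.testing.assert_array_equal(t1.force, t2.force)
    t3 = run_tensile(mini7, proto, seed=12, forcefield=ff, n_steps=300)
    assert not np.array_equal(t1.force, t3.force)
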