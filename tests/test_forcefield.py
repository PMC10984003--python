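import numpy as np
import pytest

import fibrilcg as fc
from fibrilcg.forcefield import compute_forces
from fibrilcg.parameters import BOND_AGE


class TestParameterTable:
    """Every tabulated constant is loaded verbatim from the parameter file."""

    def test_collagen_bond_row(self, ff):
        b = ff.bonds["collagen"]
        assert (b.r0, b.r1, b.rbreak) == (14.00, 18.20, 21.00)
        assert (b.k0, b.k1, b.z) == (17.13, 97.66, 0.05)

    def test_end_particles_differ_only_in_break_distance(self, ff):
        b, e = ff.bonds["collagen"], ff.bonds["end"]
        assert e.rbreak == 70.00
        assert (e.r0, e.r1, e.k0, e.k1, e.z) == (b.r0, b.r1, b.k0, b.k1, b.z)

    def test_age_bond_row(self, ff):
        a = ff.bonds["age"]
        assert (a.r0, a.r1, a.rbreak) == (18.52, 22.72, 31.72)
        assert (a.k0, a.k1) == (0.1, 8.00)

    def test_angle_row(self, ff):
        assert ff.angle.kb == 14.98
        assert tuple(ff.angle.phi0_range) == (170.0, 180.0)

    def test_pair_rows_and_masses(self, ff):
        cc, hh, ch = (ff.pairs[k] for k in ("col_col", "hap_hap", "col_hap"))
        assert (cc.epsilon, cc.sigma, cc.lam) == (6.87, 14.72, 0.9)
        assert (hh.epsilon, hh.sigma, hh.lam, hh.cutoff) == (106.7, 10.28, 0.9, 13.85)
        assert (ch.epsilon, ch.sigma, ch.lam, ch.cutoff) == (137.1, 9.88, 0.9, 20.00)
        assert ff.masses["collagen"] == 1548
        assert ff.masses["mineral"] == 1324

    def test_regularization_width(self, ff):
        assert ff.bonds["collagen"].a == pytest.approx(0.05 * (21.0 - 18.2))
        assert ff.bonds["age"].a == pytest.approx(0.05 * (31.72 - 22.72))


class TestBondForce:
    def test_zero_at_equilibrium(self, ff):
        f, broken = fc.bond_force(ff.bonds["collagen"], 14.0)
        assert f == 0.0 and not broken

    def test_first_regime_linear(self, ff):
        f, _ = fc.bond_force(ff.bonds["collagen"], 15.0)
        assert f == pytest.approx(-17.13)

    def test_second_regime_slope_is_k1(self, ff):
        r = np.linspace(18.3, 20.9, 27)
        f, _ = fc.bond_force(ff.bonds["collagen"], r)
        slopes = np.diff(np.abs(f)) / np.diff(r)
        assert np.allclose(slopes, 97.66, atol=1e-9)

    def test_force_continuous_at_r1(self, ff):
        s = ff.bonds["collagen"]
        f_lo, _ = fc.bond_force(s, s.r1 - 1e-9)
        f_hi, _ = fc.bond_force(s, s.r1 + 1e-9)
        assert f_lo == pytest.approx(f_hi, abs=1e-5)

    def test_break_latch_is_permanent(self, ff):
        s = ff.bonds["collagen"]
        f, broken = fc.bond_force(s, s.rbreak + s.a + 0.01)
        assert broken and f == 0.0
        f2, still = fc.bond_force(s, s.r0, broken=True)
        assert still and f2 == 0.0

    def test_regularization_ramp_sign_as_printed(self, ff):
        """Past rbreak the printed branch +z*k1*(r-r0) pushes outward."""
        s = ff.bonds["collagen"]
        f, broken = fc.bond_force(s, s.rbreak + 0.5 * s.a)
        assert not broken
        assert f == pytest.approx(s.z * s.k1 * (s.rbreak + 0.5 * s.a - s.r0))


class TestBondCapacity:
    def test_triangle_closed_form(self):
        """Uniform-stiffness spring with vanishing ramp: W = k d^2 / 2."""
        s = fc.BondSpec(r0=10.0, r1=12.0, rbreak=15.0, k0=5.0, k1=5.0, z=1e-9)
        assert fc.bond_energy_capacity(s) == pytest.approx(
            0.5 * 5.0 * (15.0 - 10.0) ** 2, rel=1e-6)

    def test_matches_quadrature(self, ff):
        s = ff.bonds["collagen"]
        r = np.arange(s.r0, s.rbreak + s.a, 1e-3)
        f, _ = fc.bond_force(s, r)
        w = np.trapezoid(np.abs(f), r)
        assert fc.bond_energy_capacity(s) == pytest.approx(w, rel=1e-3)

    def test_monotone_in_stiffness_scale(self, ff):
        age = ff.bonds["age"]
        assert (fc.bond_energy_capacity(age.scaled(2.0))
                > fc.bond_energy_capacity(age))


class TestAngle:
    def test_zero_at_equilibrium(self, ff):
        ri, rj, rk = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        fi, fj, fk = fc.angle_forces(ff.angle, ri, rj, rk, 90.0)
        assert np.allclose([fi, fj, fk], 0.0, atol=1e-12)

    def test_quadratic_energy_near_minimum(self, ff):
        delta = np.degrees(1e-3)
        e = fc.angle_energy(ff.angle, 170.0 + delta, 170.0)
        assert e == pytest.approx(0.5 * ff.angle.kb * 1e-6, rel=1e-9)

    def test_three_body_forces_sum_to_zero(self, ff):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ri, rj, rk = rng.standard_normal((3, 3)) * 5
            fi, fj, fk = fc.angle_forces(ff.angle, ri, rj, rk, 175.0)
            assert np.allclose(fi + fj + fk, 0.0, atol=1e-10)

    def test_degenerate_triplet_rejected(self, ff):
        with pytest.raises(ValueError, match="degenerate"):
            fc.angle_forces(ff.angle, [0, 0, 0], [0, 0, 0], [1, 0, 0], 175.0)


class TestPair:
    def test_zero_force_at_minimum(self, ff):
        cc = ff.pairs["col_col"]
        assert fc.pair_force(cc, 2 ** (1 / 6) * cc.sigma) == pytest.approx(
            0.0, abs=1e-10)

    def test_potential_zero_crossing_at_sigma(self, ff):
        """The raw LJ potential crosses zero exactly at sigma = 14.72 A."""
        from scipy.optimize import brentq

        cc = ff.pairs["col_col"]
        root = brentq(lambda r: fc.pair_energy(cc, r, shifted=False),
                      0.95 * cc.sigma, 1.05 * cc.sigma)
        assert root == pytest.approx(14.72, abs=1e-9)

    def test_soft_core_plateau(self, ff):
        cc = ff.pairs["col_col"]
        f_at_lam = fc.pair_force(cc, cc.lam * cc.sigma)
        assert fc.pair_force(cc, 0.5 * cc.sigma) == pytest.approx(f_at_lam)
        assert fc.pair_force(cc, 0.2 * cc.sigma) == pytest.approx(f_at_lam)

    def test_hap_well_depth(self, ff):
        hh = ff.pairs["hap_hap"]
        e = fc.pair_energy(hh, hh.r_min, shifted=False)
        assert e == pytest.approx(-106.7, rel=1e-12)

    def test_force_energy_consistency(self, ff):
        ch = ff.pairs["col_hap"]
        r = np.linspace(0.5 * ch.sigma, ch.cutoff * 0.99, 200)
        h = 1e-6
        fd = -(fc.pair_energy(ch, r + h) - fc.pair_energy(ch, r - h)) / (2 * h)
        assert np.allclose(fd, fc.pair_force(ch, r), atol=1e-4)


class TestSystemEnergy:
    def test_hap_dimer_nonbonded_minimum(self, ff):
        """Two isolated mineral beads at the LJ minimum: E ~ -epsilon_HAP."""
        m = fc.two_particle_model(2 ** (1 / 6) * 10.28)
        m.species[:] = 2
        m.bonds = np.empty((0, 2), dtype=np.int64)
        m.bond_type = np.empty(0, dtype=np.int64)
        m.broken = np.empty(0, dtype=np.uint8)
        m.break_step = np.empty(0, dtype=np.int64)
        e = fc.total_energy(m, ff)
        raw = fc.pair_energy(ff.pairs["hap_hap"], 2 ** (1 / 6) * 10.28,
                             shifted=False)
        assert raw == pytest.approx(-106.7)
        # the short tabulated HAP cutoff (13.85 A) makes the cut-and-shift
        # offset substantial; the system energy reflects it exactly
        sr6 = (10.28 / 13.85) ** 6
        shift = 4.0 * 106.7 * (sr6 * sr6 - sr6)
        assert e["E_nonbonded"] == pytest.approx(-106.7 - shift, rel=1e-9)

    def test_gradient_matches_finite_differences(self, ff):
        """Analytic forces agree with central differences of the energy."""
        lay = fc.FibrilLayout(n_molecules=2, n_periods=5)
        m = fc.build_fibril(lay, forcefield=ff)
        m = fc.mineralize(m, fc.MineralPattern("reference_edge", 40.0), ff)
        m = fc.insert_crosslinks(m, fc.CrossLinkConfig(2, seed=1), ff)
        F, _ = compute_forces(m, ff)
        rng = np.random.default_rng(0)
        idx = rng.choice(m.n_particles, size=12, replace=False)
        h = 1e-5
        for i in idx:
            for d in range(3):
                p = m.copy()
                p.positions[i, d] += h
                _, e1 = compute_forces(p, ff)
                p.positions[i, d] -= 2 * h
                _, e2 = compute_forces(p, ff)
                fd = -(e1["E_total"] - e2["E_total"]) / (2 * h)
                assert fd == pytest.approx(F[i, d], abs=1e-5)

    def test_newtons_third_law(self, ff, mini7x5):
        m = fc.mineralize(mini7x5, fc.MineralPattern("center_nucleated", 30.0),
                          ff)
        F, _ = compute_forces(m, ff)
        assert np.abs(F.sum(axis=0)).max() < 1e-8

    def test_age_bond_contributes_with_scaled_stiffness(self, ff):
        m = fc.two_particle_model(25.0, bond_type=BOND_AGE)
        e1 = fc.total_energy(m, ff)["E_bond"]
        m2 = m.copy()
        m2.meta["age_stiffness_scale"] = 2.0
        e2 = fc.total_energy(m2, ff)["E_bond"]
        assert e2 > e1 > 0
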