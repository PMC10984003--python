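import numpy as np
import pandas as pd
import pytest

from fibrilcg.analysis import (
    StressStrainCurve,
    initial_modulus,
    peak_and_postfailure,
    sawtooth_metrics,
    stress_strain,
)
from fibrilcg.dynamics import Trajectory
from fibrilcg.units import KCAL_PER_MOL_A3_IN_MPA


def _traj(force, gauge=100.0, area=1.0, dt=10.0, v=1e-3):
    """Minimal synthetic trajectory carrying a prescribed force trace."""
    n = len(force)
    times = np.arange(n, dtype=float) * 100 * dt
    strains = v * times / gauge
    z = np.zeros(n)
    return Trajectory(
        times=times, strains=strains, force=np.asarray(force, dtype=float),
        force_left=z, force_right=z, temperature=z,
        energies=np.zeros((n, 3)), gap_mean=z,
        n_broken=np.zeros((n, 3), dtype=np.int64),
        break_step=np.empty(0, dtype=np.int64),
        bond_type=np.empty(0, dtype=np.int64),
        frames_t=np.empty(0), frames=np.empty((0, 0, 3)),
        gauge=gauge, area=area, meta={"dt": dt},
    )


class TestStressStrain:
    def test_constant_force_gives_flat_curve(self):
        tr = _traj(np.full(50, 2.0), area=4.0)
        c = stress_strain(tr)
        assert np.allclose(c.stress, 2.0 / 4.0 * KCAL_PER_MOL_A3_IN_MPA)

    def test_unit_conversion_constant(self):
        """1 kcal/mol/A over 1 A^2 is 6947.7 MPa (= 6.9477 GPa)."""
        tr = _traj(np.ones(10), area=1.0)
        assert stress_strain(tr).stress[0] == pytest.approx(6947.695, rel=1e-4)
        assert stress_strain(tr, units="GPa").stress[0] == pytest.approx(
            6.947695, rel=1e-4)

    def test_doubling_area_halves_stress(self):
        tr = _traj(np.linspace(0, 5, 20))
        s1 = stress_strain(tr, area=2.0).stress
        s2 = stress_strain(tr, area=4.0).stress
        assert np.allclose(s1, 2 * s2)

    def test_invalid_area_or_gauge(self):
        tr = _traj(np.ones(5))
        with pytest.raises(ValueError):
            stress_strain(tr, area=0.0)
        with pytest.raises(ValueError):
            stress_strain(tr, gauge=-1.0)

    def test_strain_clock_is_exact(self):
        tr = _traj(np.ones(30), gauge=200.0, v=2e-3, dt=10.0)
        c = stress_strain(tr)
        expect = 2e-3 * tr.times / 200.0
        np.testing.assert_allclose(c.strain, expect[np.concatenate(
            [[True], np.diff(expect) > 0])])


class TestPeakAndPostfailure:
    def test_triangle_curve(self):
        """Rise to (0.2, 1.0) then linear to (0.4, 0): W_PF = 0.1."""
        eps = np.linspace(0, 0.4, 401)
        sig = np.where(eps <= 0.2, eps / 0.2, (0.4 - eps) / 0.2)
        out = peak_and_postfailure(
            StressStrainCurve(eps, sig), smooth_window=1)
        assert out["sigma_peak"] == pytest.approx(1.0)
        assert out["eps_peak"] == pytest.approx(0.2)
        assert out["w_pf"] == pytest.approx(0.1, rel=2e-2)

    def test_brittle_step_to_zero(self):
        eps = np.linspace(0, 0.4, 201)
        sig = np.where(eps <= 0.2, eps / 0.2, 0.0)
        out = peak_and_postfailure(StressStrainCurve(eps, sig),
                                   smooth_window=1)
        assert out["w_pf"] < 5e-3

    def test_sine_bump_matches_analytic_integral(self):
        """Half-sine over the post-peak window integrates to 2 A / pi."""
        eps = np.linspace(0, 1.0, 1001)
        sig = np.sin(np.pi * eps)
        out = peak_and_postfailure(StressStrainCurve(eps, sig),
                                   floor_frac=1e-9, smooth_window=1)
        # peak at 0.5; integral of sin(pi x) from 0.5 to 1 = 1/pi
        assert out["w_pf"] == pytest.approx(1.0 / np.pi, rel=1e-3)

    def test_never_exceeds_floor_gives_zero_report(self):
        eps = np.linspace(0, 0.1, 20)
        out = peak_and_postfailure(StressStrainCurve(eps, np.zeros(20)))
        assert out == dict(sigma_peak=0.0, eps_peak=0.0, eps_pf0=0.0, w_pf=0.0)

    def test_w_pf_invariant_under_resampling(self):
        for n in (500, 2000, 8000):
            eps = np.linspace(0, 1.0, n + 1)
            sig = np.sin(np.pi * eps)
            out = peak_and_postfailure(StressStrainCurve(eps, sig),
                                       floor_frac=1e-9, smooth_window=1)
            assert out["w_pf"] == pytest.approx(1.0 / np.pi, rel=1e-3)


class TestModulus:
    def test_linear_curve_recovers_slope(self):
        eps = np.linspace(0, 0.2, 100)
        c = StressStrainCurve(eps, 123.0 * eps)
        assert initial_modulus(c) == pytest.approx(123.0, rel=1e-9)


class TestSawtooth:
    def test_monotone_curve_has_no_drops(self):
        eps = np.linspace(0, 1, 200)
        assert sawtooth_metrics(StressStrainCurve(eps, eps),
                                smooth_window=1)["n_drops"] == 0

    def test_three_inserted_drops_detected(self):
        eps = np.linspace(0, 1.0, 1000)
        sig = eps.copy()
        for start in (0.3, 0.5, 0.7):
            sel = (eps >= start) & (eps < start + 0.02)
            sig[sel] -= 0.12  # 12% of the later peak
        out = sawtooth_metrics(StressStrainCurve(eps, sig), drop_frac=0.05,
                               smooth_window=1)
        assert out["n_drops"] == 3

    def test_raising_threshold_never_increases_count(self):
        rng = np.random.default_rng(0)
        eps = np.linspace(0, 1, 500)
        sig = np.clip(eps + 0.2 * rng.standard_normal(500), 0, None)
        counts = [sawtooth_metrics(StressStrainCurve(eps, sig), f,
                                   smooth_window=1)["n_drops"]
                  for f in (0.02, 0.05, 0.1, 0.2, 0.5)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_strictly_increasing_strain_enforced():
    with pytest.raises(ValueError):
        StressStrainCurve(np.array([0.0, 0.1, 0.1]), np.zeros(3))
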