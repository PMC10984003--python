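"""Mechanical observables from tensile trajectories.

Engineering stress is grip force over the *initial* cross-sectional
area; engineering strain is the exact steering clock (grip displacement
over initial gauge length).  Scalars derived from the curve: peak
stress and strain, the post-failure strain where stress first drops to
(almost) zero, the post-failure work

    W_PF = integral of sigma d eps from eps_peak to eps_PF0,

the initial elastic modulus, cumulative broken-bond counts per bond
class, the average gap length series, and sawtooth stress-drop
statistics.  Force traces are median-filtered for peak *detection*
only; raw data are never modified.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .dynamics import Trajectory
from .units import KCAL_PER_MOL_A3_IN_MPA

__all__ = [
    "StressStrainCurve",
    "MechanicsReport",
    "stress_strain",
    "peak_and_postfailure",
    "initial_modulus",
    "broken_bond_series",
    "gap_length_series",
    "sawtooth_metrics",
    "analyze",
]

_BOND_CLASS = {0: "collagen", 1: "end", 2: "age"}


@dataclasses.dataclass
class StressStrainCurve:
    """Engineering stress-strain curve; stress in MPa unless noted."""

    strain: np.ndarray
    stress: np.ndarray
    units: str = "MPa"

    def __post_init__(self) -> None:
        if len(self.strain) == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")

    def smoothed(self, window: int = 5) -> np.ndarray:
        if len(self.stress) < window:
            return self.stress.copy()
        return medfilt(self.stress, window | 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain": self.strain,
                             f"stress_{self.units}": self.stress})


def stress_strain(traj: Trajectory, area: float | None = None,
                  gauge: float | None = None,
                  units: str = "MPa") -> StressStrainCurve:
    """Engineering stress-strain curve from a tensile trajectory.

    ``area`` (A^2) and ``gauge`` (A) default to the values recorded at
    build time.  Stress conversion: kcal/mol/A / A^2 -> MPa or GPa.
    """
    area = traj.area if area is None else area
    gauge = traj.gauge if gauge is None else gauge
    if area <= 0 or gauge <= 0:
        raise ValueError("area and gauge must be positive")
    scale = KCAL_PER_MOL_A3_IN_MPA
    if units == "GPa":
        scale /= 1.0e3
    elif units != "MPa":
        raise ValueError("units must be 'MPa' or 'GPa'")
    # recompute strain against the requested gauge from the exact clock
    strain = traj.strains * (traj.gauge / gauge)
    stress = traj.force / area * scale
    # drop duplicate leading sample if the clock starts flat
    keep = np.concatenate([[True], np.diff(strain) > 0])
    return StressStrainCurve(strain=strain[keep], stress=stress[keep],
                             units=units)


def peak_and_postfailure(curve: StressStrainCurve,
                         floor_frac: float = 0.01,
                         smooth_window: int = 5) -> dict[str, float]:
    """Peak stress/strain, post-failure zero crossing, and W_PF (Eq.-style).

    ``eps_pf0`` is the first strain after the peak where the (smoothed)
    stress falls below ``floor_frac * sigma_peak``; W_PF integrates the
    raw curve over [eps_peak, eps_pf0] by the trapezoid rule.  If the
    curve never exceeds the floor an all-zero report is returned.
    """
    eps = curve.strain
    sig = curve.stress
    det = curve.smoothed(smooth_window)
    ipeak = int(np.argmax(det))
    sigma_peak = float(sig[ipeak])
    if sigma_peak <= 0:
        return dict(sigma_peak=0.0, eps_peak=0.0, eps_pf0=0.0, w_pf=0.0)
    eps_peak = float(eps[ipeak])
    floor = floor_frac * det[ipeak]
    below = np.flatnonzero(det[ipeak:] < floor)
    if below.size:
        ipf = ipeak + int(below[0])
    else:
        ipf = len(eps) - 1
    eps_pf0 = float(eps[ipf])
    w_pf = float(np.trapezoid(sig[ipeak:ipf + 1], eps[ipeak:ipf + 1]))
    return dict(sigma_peak=sigma_peak, eps_peak=eps_peak,
                eps_pf0=eps_pf0, w_pf=max(w_pf, 0.0))


def initial_modulus(curve: StressStrainCurve,
                    eps_range: tuple[float, float] = (0.0, 0.05)) -> float:
    """Least-squares slope of the curve on the initial strain window."""
    lo, hi = eps_range
    m = (curve.strain >= lo) & (curve.strain <= hi)
    if m.sum() < 2:
        raise ValueError("not enough samples in the modulus window")
    A = np.vstack([curve.strain[m], np.ones(int(m.sum()))]).T
    slope, _ = np.linalg.lstsq(A, curve.stress[m], rcond=None)[0]
    return float(slope)


def broken_bond_series(traj: Trajectory) -> pd.DataFrame:
    """Cumulative broken-bond counts and fractions per class vs strain."""
    out = {"strain": traj.strains}
    for c, name in _BOND_CLASS.items():
        total = int(np.sum(traj.bond_type == c))
        counts = traj.n_broken[:, c]
        out[f"n_broken_{name}"] = counts
        out[f"frac_broken_{name}"] = (counts / total if total else
                                      np.zeros(len(counts)))
    df = pd.DataFrame(out)
    return df


def recount_broken_from_steps(traj: Trajectory) -> np.ndarray:
    """Replay per-frame cumulative counts from the final break steps.

    Cross-check for the counts sampled during the run.
    """
    dt = float(traj.meta.get("dt", 10.0))
    steps = np.round(traj.times / dt).astype(np.int64)
    out = np.zeros((len(steps), 3), dtype=np.int64)
    for f, s in enumerate(steps):
        fired = (traj.break_step >= 0) & (traj.break_step <= s)
        for c in range(3):
            out[f, c] = int(np.sum(fired & (traj.bond_type == c)))
    return out


def gap_length_series(traj: Trajectory) -> pd.DataFrame:
    """Mean axial gap-terminal distance vs strain (sampled during run)."""
    return pd.DataFrame({"strain": traj.strains, "gap_length": traj.gap_mean})


def sawtooth_metrics(curve: StressStrainCurve,
                     drop_frac: float = 0.05,
                     smooth_window: int = 5) -> dict:
    """Count post-yield stress drops larger than ``drop_frac * sigma_peak``.

    Drops are measured between successive local maxima and the minima
    that follow them on the (peak-detection-smoothed) curve.
    """
    sig = curve.smoothed(smooth_window)
    peak = float(sig.max())
    if peak <= 0:
        return dict(n_drops=0, drop_sizes=np.empty(0))
    thresh = drop_frac * peak
    drops = []
    i = 0
    n = len(sig)
    while i < n - 1:
        # ascend to a local max
        while i < n - 1 and sig[i + 1] >= sig[i]:
            i += 1
        top = sig[i]
        j = i
        while j < n - 1 and sig[j + 1] <= sig[j]:
            j += 1
        drop = top - sig[j]
        if drop > thresh:
            drops.append(float(drop))
        if j == i:
            i += 1
        else:
            i = j
    return dict(n_drops=len(drops), drop_sizes=np.array(drops))


@dataclasses.dataclass
class MechanicsReport:
    """Scalar summary plus tabular series of one tensile test."""

    sigma_peak: float
    eps_peak: float
    eps_pf0: float
    w_pf: float
    modulus: float
    units: str
    area: float
    gauge: float
    n_drops: int
    broken_final: dict[str, int]
    curve: StressStrainCurve
    breaks: pd.DataFrame
    gaps: pd.DataFrame

    def scalars(self) -> dict:
        return dict(sigma_peak=self.sigma_peak, eps_peak=self.eps_peak,
                    eps_pf0=self.eps_pf0, w_pf=self.w_pf,
                    modulus=self.modulus, units=self.units,
                    area_A2=self.area, gauge_A=self.gauge,
                    n_drops=self.n_drops, broken_final=self.broken_final)


def analyze(traj: Trajectory, units: str = "MPa",
            floor_frac: float = 0.01, drop_frac: float = 0.05
            ) -> MechanicsReport:
    """Full mechanics report for one tensile trajectory."""
    curve = stress_strain(traj, units=units)
    pk = peak_and_postfailure(curve, floor_frac=floor_frac)
    try:
        mod = initial_modulus(curve)
    except ValueError:
        mod = float("nan")
    saw = sawtooth_metrics(curve, drop_frac=drop_frac)
    final = {name: int(traj.n_broken[-1, c]) for c, name in _BOND_CLASS.items()}
    return MechanicsReport(
        sigma_peak=pk["sigma_peak"], eps_peak=pk["eps_peak"],
        eps_pf0=pk["eps_pf0"], w_pf=pk["w_pf"], modulus=mod, units=units,
        area=traj.area, gauge=traj.gauge, n_drops=saw["n_drops"],
        broken_final=final, curve=curve,
        breaks=broken_bond_series(traj), gaps=gap_length_series(traj),
    )
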