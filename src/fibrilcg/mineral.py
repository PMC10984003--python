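"""Mineralization of the gap zones.

Hydroxyapatite-like mineral particles are placed along each lane's gap
segment — on the continuation of the molecule's undulating backbone
curve, so that mineral keeps the same lateral clearance from
neighboring lanes as the collagen beads do — at the equilibrium HAP
spacing ``2^(1/6)*sigma_HAP``.  The first particle of each nucleation
front sits at the collagen/mineral equilibrium distance
``2^(1/6)*sigma_col-HAP`` from the gap-terminal collagen bead, so the
freshly mineralized model is force-free.  Mineral carries no bonds or
angles: it is held purely by nonbonded interactions, which is what lets
it act as a compressive/adhesive "glue" inside the gap.

Morphologies:

* ``reference_edge`` — fronts grow inward from both gap edges.
* ``center_nucleated`` — a single symmetric grid grows outward from the
  gap center.
* ``sparse_alternate`` — every second particle of the reference
  positions (axially sorted): half the count, same occupied span.
* ``double_row`` — the reference positions duplicated on two parallel
  rows at +-spacing/2 about the gap line (row separation one
  equilibrium spacing), oriented between hexagonal neighbor directions
  to keep clearance from neighboring lanes.

The mineral content ``c_mineral`` is the percentage of gap length
occupied: with n particles at spacing s in a gap of length l,
c = n*s/l*100.  The particle count for a requested c is
``floor(c/100 * l/s) + 1`` for c > 0, capped so that opposing fronts
never collide and mineral never leaves the gap.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .model import FibrilModel
from .parameters import ForceField, SPECIES_MINERAL, default_forcefield

__all__ = ["MineralPattern", "mineralize", "mineral_content"]

_MORPHOLOGIES = ("reference_edge", "center_nucleated", "sparse_alternate",
                 "double_row")


@dataclasses.dataclass(frozen=True)
class MineralPattern:
    morphology: str = "reference_edge"
    c_mineral: float = 0.0        # percent of gap length occupied, 0..100
    spacing: float | None = None  # default 2^(1/6)*sigma_HAP

    def __post_init__(self) -> None:
        if self.morphology not in _MORPHOLOGIES:
            raise ValueError(
                f"unknown morphology '{self.morphology}'; "
                f"choose from {_MORPHOLOGIES}"
            )
        if not (0.0 <= self.c_mineral <= 100.0):
            raise ValueError("c_mineral must be within [0, 100]")


class _GapCurve:
    """The lane's backbone curve continued through one gap.

    y(x) = y_base + amp*sin(2 pi (x + x_off) / wavelength); straight
    line for amp == 0 (imported straight traces).  z is constant along
    a lane.
    """

    def __init__(self, amp: float, wavelength: float, x_off: float,
                 y_base: float, z: float):
        self.amp = amp
        self.wavelength = wavelength
        self.x_off = x_off
        self.y_base = y_base
        self.z = z

    def y(self, x: float) -> float:
        if self.amp == 0.0:
            return self.y_base
        return self.y_base + self.amp * np.sin(
            2.0 * np.pi * (x + self.x_off) / self.wavelength)

    def march(self, x0: float, chords: list[float], sign: float) -> np.ndarray:
        """Successive points with exact chord distances, advancing in x."""
        pts = []
        x, y = x0, self.y(x0)
        slope = (0.0 if self.amp == 0.0
                 else 2.0 * np.pi * self.amp / self.wavelength)
        for c in chords:
            if self.amp == 0.0:
                x = x + sign * c
            else:
                def f(dx: float) -> float:
                    xn = x + sign * dx
                    return dx * dx + (self.y(xn) - y) ** 2 - c * c
                lo = 0.4 * c / np.sqrt(1.0 + slope * slope)
                dx = brentq(f, lo, c * 1.0000001, xtol=1e-12)
                x = x + sign * dx
            y = self.y(x)
            pts.append((x, y, self.z))
        return np.array(pts) if pts else np.empty((0, 3))


def _count(c: float, l: float, s: float) -> int:
    if c <= 0.0:
        return 0
    return int(np.floor(c / 100.0 * l / s)) + 1


def _edge_fronts(curve: _GapCurve, x1: float, x2: float, n: int,
                 s: float, edge: float) -> np.ndarray:
    """Two fronts growing inward from both gap edges, collision-capped."""
    n_left = (n + 1) // 2
    n_right = n - n_left
    left = curve.march(x1, [edge] + [s] * (n_left - 1), +1.0)
    right = curve.march(x2, [edge] + [s] * max(n_right - 1, 0), -1.0)
    if n_right == 0:
        right = np.empty((0, 3))
    while len(right) and (
        right[-1, 0] <= left[-1, 0]
        or np.linalg.norm(right[-1] - left[-1]) < 0.8 * s
    ):
        right = right[:-1]
    pts = np.vstack([left, right[::-1]]) if len(right) else left
    return pts


def _center_grid(curve: _GapCurve, x1: float, x2: float, n: int,
                 s: float, edge: float) -> np.ndarray:
    """Symmetric grid nucleated at the gap center, growing outward."""
    xc = 0.5 * (x1 + x2)
    if n <= 0:
        return np.empty((0, 3))
    if n % 2 == 1:
        center = np.array([[xc, curve.y(xc), curve.z]])
        half = (n - 1) // 2
        lefts = curve.march(xc, [s] * half, -1.0)
        rights = curve.march(xc, [s] * half, +1.0)
    else:
        half = n // 2
        lefts = curve.march(xc, [0.5 * s] + [s] * (half - 1), -1.0)
        rights = curve.march(xc, [0.5 * s] + [s] * (half - 1), +1.0)
        center = np.empty((0, 3))
    pts = np.vstack([lefts[::-1], center, rights])
    # keep clear of both terminals
    p1 = np.array([x1, curve.y(x1), curve.z])
    p2 = np.array([x2, curve.y(x2), curve.z])
    keep = (np.linalg.norm(pts - p1, axis=1) >= 0.8 * edge) & (
        np.linalg.norm(pts - p2, axis=1) >= 0.8 * edge)
    return pts[keep]


def mineralize(
    model: FibrilModel,
    pattern: MineralPattern,
    forcefield: ForceField | None = None,
) -> FibrilModel:
    """Return a copy of ``model`` with mineral inserted into every gap."""
    ff = forcefield or default_forcefield()
    s = pattern.spacing if pattern.spacing is not None else ff.r0_hap
    edge = ff.r0_col_hap
    out = model.copy()
    out.meta["mineral"] = dataclasses.asdict(pattern)
    if pattern.c_mineral <= 0.0 or len(model.gap_pairs) == 0:
        return out

    meta = model.meta
    amp = float(meta.get("wave_amplitude", 0.0))
    wavelength = float(meta.get("wave_length", 0.0)) or 1.0
    x_off = float(meta.get("wave_x_offset", 0.0))
    box_l = model.box.lx if model.box.periodic_x else 0.0

    # perpendicular direction for double rows: midway between the two
    # hexagonal lattice directions closest to +y
    perp = np.array([0.0, np.sqrt(3.0) / 2.0, 0.5])

    new_pos = []
    new_lane = []
    for ia, ib in model.gap_pairs:
        p1 = model.positions[ia].astype(float)
        p2 = model.positions[ib].astype(float)
        d = p2 - p1
        if box_l > 0.0:
            d[0] -= box_l * np.round(d[0] / box_l)
        x1 = p1[0]
        x2 = p1[0] + d[0]  # unwrapped
        l = float(np.linalg.norm(d))
        n = _count(pattern.c_mineral, l, s)
        if n == 0:
            continue
        curve = _GapCurve(
            amp, wavelength, x_off,
            y_base=p1[1] - (amp * np.sin(2.0 * np.pi * (x1 + x_off) / wavelength)
                            if amp else 0.0),
            z=p1[2],
        )
        if pattern.morphology == "center_nucleated":
            pts = _center_grid(curve, x1, x2, n, s, edge)
        else:
            pts = _edge_fronts(curve, x1, x2, n, s, edge)
            if pattern.morphology == "sparse_alternate":
                pts = pts[np.argsort(pts[:, 0])][::2]
        if len(pts) == 0:
            continue
        if pattern.morphology == "double_row":
            pts = np.vstack([pts + 0.5 * s * perp, pts - 0.5 * s * perp])
        new_pos.append(pts)
        new_lane.append(np.full(len(pts), model.lane_id[ia], dtype=np.int64))

    if new_pos:
        add = np.vstack(new_pos)
        if box_l > 0.0:
            lo = model.box.lo[0]
            add[:, 0] = lo + np.mod(add[:, 0] - lo, box_l)
        n_add = len(add)
        out.positions = np.vstack([out.positions, add])
        out.species = np.concatenate(
            [out.species, np.full(n_add, SPECIES_MINERAL, dtype=np.int64)])
        out.mol_id = np.concatenate(
            [out.mol_id, np.full(n_add, -1, dtype=np.int64)])
        out.lane_id = np.concatenate([out.lane_id, np.concatenate(new_lane)])
        out.mol_index = np.concatenate(
            [out.mol_index, np.full(n_add, -1, dtype=np.int64)])
    return out


def mineral_content(model: FibrilModel, forcefield: ForceField | None = None
                    ) -> float:
    """Achieved c_mineral (%): mineral count times spacing over gap length."""
    ff = forcefield or default_forcefield()
    patt = model.meta.get("mineral") or {}
    s = patt.get("spacing") or ff.r0_hap
    n_mineral = float(np.sum(model.species == SPECIES_MINERAL))
    if len(model.gap_pairs) == 0 or n_mineral == 0:
        return 0.0
    if patt.get("morphology") == "double_row":
        n_mineral /= 2.0
    box_l = model.box.lx if model.box.periodic_x else 0.0
    total_l = 0.0
    for ia, ib in model.gap_pairs:
        d = (model.positions[ib] - model.positions[ia]).astype(float)
        if box_l > 0.0:
            d[0] -= box_l * np.round(d[0] / box_l)
        total_l += float(np.linalg.norm(d))
    return 100.0 * n_mineral * s / total_l
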