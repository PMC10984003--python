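"""Energy and force evaluation.

Three interaction classes act in the model:

* breakable trilinear bonds (collagen backbone, strengthened end
  segments, AGE cross-links) with an irreversible break latch at
  ``rbreak + a``;
* harmonic angle bending with per-triplet equilibrium angles read from
  the initial geometry;
* soft-core, cut-and-shifted Lennard-Jones pairs (col-col, HAP-HAP,
  col-HAP), force capped below ``lam*sigma``.

The hot loops are numba kernels operating on packed parameter tables
(:meth:`ForceField.bond_table` / :meth:`ForceField.pair_table`); the
module-level functions are thin, array-friendly wrappers used by tests
and analysis.  Scalar force sign convention: negative = restoring
(pulling the pair together), so the vector force on particle i is
``f * (ri - rj) / r``.
"""
from __future__ import annotations

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .model import FibrilModel
from .parameters import (
    PAIR_TABLE,
    BondSpec,
    AngleSpec,
    PairSpec,
    ForceField,
    default_forcefield,
)

__all__ = [
    "bond_force",
    "bond_energy",
    "bond_energy_capacity",
    "angle_energy",
    "angle_forces",
    "pair_force",
    "pair_energy",
    "NeighborList",
    "compute_forces",
    "total_energy",
]


# ------------------------------------------------------------------ bonds
@njit(cache=True)
def _bond_scalar(r, r0, r1, rbreak, k0, k1, z, a):
    """Scalar bond force (negative = restoring) and energy for intact bonds."""
    if r < r1:
        f = -k0 * (r - r0)
        e = 0.5 * k0 * (r - r0) ** 2
    elif r < rbreak:
        f = -(k0 * (r1 - r0) + k1 * (r - r1))
        e = (0.5 * k0 * (r1 - r0) ** 2
             + k0 * (r1 - r0) * (r - r1)
             + 0.5 * k1 * (r - r1) ** 2)
    elif r < rbreak + a:
        # regularization ramp past breaking, as printed: +z*k1*(r - r0)
        f = z * k1 * (r - r0)
        e_rb = (0.5 * k0 * (r1 - r0) ** 2
                + k0 * (r1 - r0) * (rbreak - r1)
                + 0.5 * k1 * (rbreak - r1) ** 2)
        e = e_rb - 0.5 * z * k1 * ((r - r0) ** 2 - (rbreak - r0) ** 2)
    else:
        f = 0.0
        e = 0.0
    return f, e


def bond_force(spec: BondSpec, r, broken=False):
    """Bond force (kcal/mol/A) at distance r; returns (force, now_broken).

    ``broken`` bonds give zero force; a bond latches broken the first
    time r reaches ``rbreak + a`` and never recovers.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    f = np.empty_like(r)
    now_broken = np.broadcast_to(np.asarray(broken, dtype=bool), r.shape).copy()
    for i, ri in enumerate(r):
        if now_broken[i]:
            f[i] = 0.0
            continue
        if ri >= spec.rbreak + spec.a:
            now_broken[i] = True
            f[i] = 0.0
        else:
            f[i], _ = _bond_scalar(ri, spec.r0, spec.r1, spec.rbreak,
                                   spec.k0, spec.k1, spec.z, spec.a)
    if scalar:
        return float(f[0]), bool(now_broken[0])
    return f, now_broken


def bond_energy(spec: BondSpec, r, broken=False):
    """Bond potential energy (kcal/mol); zero for broken bonds."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    e = np.empty_like(r)
    brk = np.broadcast_to(np.asarray(broken, dtype=bool), r.shape)
    for i, ri in enumerate(r):
        if brk[i] or ri >= spec.rbreak + spec.a:
            e[i] = 0.0
        else:
            _, e[i] = _bond_scalar(ri, spec.r0, spec.r1, spec.rbreak,
                                   spec.k0, spec.k1, spec.z, spec.a)
    return e if e.size > 1 else float(e[0])


def bond_energy_capacity(spec: BondSpec) -> float:
    """Loading energy capacity: integral of |force| from r0 to zero force.

    This is the area under the trilinear force-extension curve up to the
    end of the regularization ramp at ``rbreak + a``.
    """
    d1 = spec.r1 - spec.r0
    d2 = spec.rbreak - spec.r1
    w = 0.5 * spec.k0 * d1 * d1
    w += spec.k0 * d1 * d2 + 0.5 * spec.k1 * d2 * d2
    w += 0.5 * spec.z * spec.k1 * (
        (spec.rbreak + spec.a - spec.r0) ** 2 - (spec.rbreak - spec.r0) ** 2
    )
    return float(w)


# ------------------------------------------------------------------ angles
def angle_energy(spec: AngleSpec, phi, phi0):
    """Harmonic bending energy (kcal/mol), angles in degrees."""
    dphi = np.deg2rad(np.asarray(phi, dtype=float) - np.asarray(phi0, dtype=float))
    return 0.5 * spec.kb * dphi * dphi


def angle_forces(spec: AngleSpec, ri, rj, rk, phi0_deg):
    """Force vectors (Fi, Fj, Fk) for one triplet; phi0 in degrees."""
    ri, rj, rk = (np.asarray(v, dtype=float) for v in (ri, rj, rk))
    rij = ri - rj
    rkj = rk - rj
    nij = np.linalg.norm(rij)
    nkj = np.linalg.norm(rkj)
    if nij < 1e-12 or nkj < 1e-12:
        raise ValueError("degenerate angle triplet (zero-length arm)")
    uij = rij / nij
    ukj = rkj / nkj
    c = float(np.clip(uij @ ukj, -1.0, 1.0))
    phi = np.arccos(c)
    s = max(np.sqrt(1.0 - c * c), 1e-10)
    dedphi = spec.kb * (phi - np.deg2rad(float(phi0_deg)))
    fi = (dedphi / s) * (ukj - c * uij) / nij
    fk = (dedphi / s) * (uij - c * ukj) / nkj
    return fi, -(fi + fk), fk


# ------------------------------------------------------------------ pairs
@njit(cache=True)
def _pair_scalar(r, eps, sigma, lam, cutoff, eshift):
    """Scalar soft-core LJ force (positive = repulsive) and shifted energy."""
    if r >= cutoff:
        return 0.0, 0.0
    rc = lam * sigma
    if r >= rc:
        sr6 = (sigma / r) ** 6
        f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
        e = 4.0 * eps * (sr6 * sr6 - sr6) - eshift
    else:
        sr6 = (sigma / rc) ** 6
        f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / rc
        e_rc = 4.0 * eps * (sr6 * sr6 - sr6) - eshift
        e = e_rc + f * (rc - r)
    return f, e


def pair_force(spec: PairSpec, r):
    """Soft-core LJ force (kcal/mol/A); positive = repulsive."""
    sr6c = (spec.sigma / spec.cutoff) ** 6
    eshift = 4.0 * spec.epsilon * (sr6c * sr6c - sr6c)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.array([
        _pair_scalar(ri, spec.epsilon, spec.sigma, spec.lam, spec.cutoff,
                     eshift)[0]
        for ri in r
    ])
    return out if out.size > 1 else float(out[0])


def pair_energy(spec: PairSpec, r, shifted: bool = True):
    """Soft-core LJ potential; ``shifted=False`` gives the raw LJ form."""
    sr6c = (spec.sigma / spec.cutoff) ** 6
    eshift = 4.0 * spec.epsilon * (sr6c * sr6c - sr6c) if shifted else 0.0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.empty_like(r)
    for i, ri in enumerate(r):
        if not shifted and ri >= spec.cutoff:
            out[i] = 0.0
            continue
        out[i] = _pair_scalar(ri, spec.epsilon, spec.sigma, spec.lam,
                              1e30 if not shifted else spec.cutoff, eshift)[1]
    return out if out.size > 1 else float(out[0])


# ----------------------------------------------------------- system kernel
@njit(cache=True, fastmath=True)
def _forces_kernel(pos, forces, bonds, bond_type, broken, break_step,
                   bond_tab, step, angles, phi0, kb,
                   pairs, pair_type, pair_tab, box_l):
    """Accumulate all forces; returns (e_bond, e_angle, e_pair, virial_xx).

    ``box_l > 0`` enables minimum-image convention along x.  Latches
    ``broken``/``break_step`` the first time a bond passes rbreak + a.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_pair = 0.0
    w_xx = 0.0

    for b in range(bonds.shape[0]):
        if broken[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if box_l > 0.0:
            dx -= box_l * np.rint(dx / box_l)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        t = bond_type[b]
        if r >= bond_tab[t, 2] + bond_tab[t, 6]:
            broken[b] = 1
            break_step[b] = step
            continue
        f, e = _bond_scalar(r, bond_tab[t, 0], bond_tab[t, 1], bond_tab[t, 2],
                            bond_tab[t, 3], bond_tab[t, 4], bond_tab[t, 5],
                            bond_tab[t, 6])
        e_bond += e
        fr = f / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
        w_xx += fr * dx * dx

    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        xij = pos[i, 0] - pos[j, 0]
        yij = pos[i, 1] - pos[j, 1]
        zij = pos[i, 2] - pos[j, 2]
        xkj = pos[k, 0] - pos[j, 0]
        ykj = pos[k, 1] - pos[j, 1]
        zkj = pos[k, 2] - pos[j, 2]
        if box_l > 0.0:
            xij -= box_l * np.rint(xij / box_l)
            xkj -= box_l * np.rint(xkj / box_l)
        nij = np.sqrt(xij * xij + yij * yij + zij * zij)
        nkj = np.sqrt(xkj * xkj + ykj * ykj + zkj * zkj)
        c = (xij * xkj + yij * ykj + zij * zkj) / (nij * nkj)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-10:
            s = 1e-10
        dphi = phi - phi0[a]
        e_angle += 0.5 * kb * dphi * dphi
        coef = kb * dphi / s
        fix = coef * (xkj / nkj - c * xij / nij) / nij
        fiy = coef * (ykj / nkj - c * yij / nij) / nij
        fiz = coef * (zkj / nkj - c * zij / nij) / nij
        fkx = coef * (xij / nij - c * xkj / nkj) / nkj
        fky = coef * (yij / nij - c * ykj / nkj) / nkj
        fkz = coef * (zij / nij - c * zkj / nkj) / nkj
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        w_xx += fix * xij + fkx * xkj

    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        t = pair_type[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if box_l > 0.0:
            dx -= box_l * np.rint(dx / box_l)
        cutoff = pair_tab[t, 3]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        eps = pair_tab[t, 0]
        sig = pair_tab[t, 1]
        rc_soft = pair_tab[t, 2] * sig
        if r2 >= rc_soft * rc_soft:
            s2 = sig * sig / r2
            sr6 = s2 * s2 * s2
            fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2  # f/r
            e_pair += 4.0 * eps * (sr6 * sr6 - sr6) - pair_tab[t, 4]
        else:
            r = np.sqrt(r2)
            s2 = sig * sig / (rc_soft * rc_soft)
            sr6 = s2 * s2 * s2
            f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / rc_soft
            e_rc = 4.0 * eps * (sr6 * sr6 - sr6) - pair_tab[t, 4]
            e_pair += e_rc + f * (rc_soft - r)
            fr = f / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
        w_xx += fr * dx * dx

    return e_bond, e_angle, e_pair, w_xx


class NeighborList:
    """Verlet pair list with a skin, periodic-x aware.

    Pairs directly connected by a bond (including AGE cross-links,
    broken or not) are excluded permanently.
    """

    def __init__(self, model_like, forcefield: ForceField, skin: float = 6.0):
        self.skin = skin
        self.max_cut = forcefield.max_cutoff + skin
        n = model_like.positions.shape[0]
        self._n = n
        b = model_like.bonds
        if len(b):
            lo = np.minimum(b[:, 0], b[:, 1]).astype(np.int64)
            hi = np.maximum(b[:, 0], b[:, 1]).astype(np.int64)
            self._excl_keys = np.unique(lo * n + hi)
        else:
            self._excl_keys = np.empty(0, dtype=np.int64)
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self.pair_type = np.empty(0, dtype=np.int64)

    def rebuild(self, positions: np.ndarray, species: np.ndarray,
                box_lo, box_l: float) -> None:
        if box_l > 0.0:
            shifted = positions - np.asarray(box_lo)
            shifted[:, 0] = np.mod(shifted[:, 0], box_l)
            shifted[:, 1] -= shifted[:, 1].min()
            shifted[:, 2] -= shifted[:, 2].min()
            pad = 10.0 * self.max_cut
            tree = cKDTree(
                shifted,
                boxsize=(box_l, shifted[:, 1].max() + pad,
                         shifted[:, 2].max() + pad),
            )
        else:
            tree = cKDTree(positions)
        raw = tree.query_pairs(self.max_cut, output_type="ndarray").astype(np.int64)
        if len(raw) and len(self._excl_keys):
            keys = (np.minimum(raw[:, 0], raw[:, 1]) * self._n
                    + np.maximum(raw[:, 0], raw[:, 1]))
            raw = raw[~np.isin(keys, self._excl_keys, assume_unique=False)]
        self.pairs = raw
        self.pair_type = PAIR_TABLE[
            species[self.pairs[:, 0]], species[self.pairs[:, 1]]
        ] if len(self.pairs) else np.empty(0, dtype=np.int64)


def compute_forces(model: FibrilModel, forcefield: ForceField | None = None,
                   neighbor: NeighborList | None = None, step: int = 0):
    """One-shot force/energy evaluation on a model.

    Returns ``(forces, info)`` where info has keys E_bond, E_angle,
    E_nonbonded, E_total, virial_xx.
    """
    ff = forcefield or default_forcefield()
    if neighbor is None:
        neighbor = NeighborList(model, ff, skin=0.5)
        box_l = model.box.lx if model.box.periodic_x else 0.0
        neighbor.rebuild(model.positions, model.species, model.box.lo, box_l)
    box_l = model.box.lx if model.box.periodic_x else 0.0
    forces = np.zeros_like(model.positions)
    scale = float(model.meta.get("age_stiffness_scale", 1.0))
    eb, ea, ep, wxx = _forces_kernel(
        model.positions, forces, model.bonds, model.bond_type, model.broken,
        model.break_step, ff.bond_table(scale), step,
        model.angles, model.phi0, ff.angle.kb,
        neighbor.pairs, neighbor.pair_type, ff.pair_table(), box_l,
    )
    info = dict(E_bond=eb, E_angle=ea, E_nonbonded=ep,
                E_total=eb + ea + ep, virial_xx=wxx)
    return forces, info


def total_energy(model: FibrilModel, forcefield: ForceField | None = None
                 ) -> dict[str, float]:
    """Total potential energy decomposition of a model configuration."""
    _, info = compute_forces(model, forcefield)
    return {k: float(info[k]) for k in
            ("E_bond", "E_angle", "E_nonbonded", "E_total")}
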