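"""Time integration and the two-phase tensile protocol.

Integration is velocity-Verlet; the NVT thermostat is Langevin in the
BAOAB splitting (one force evaluation per step).  Steering is
displacement-controlled: the strengthened end particles ("grips") move
as rigid sets at +-v_pull/2 along the fibril axis and the force needed
to hold each grip — minus the sum of internal forces on its particles —
is recorded.  Axial periodic equilibration supports a weak Berendsen
box rescale toward zero axial virial stress.

All hot loops are numba kernels; the python layer owns neighbor-list
rebuilds, sampling, and bookkeeping.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .forcefield import NeighborList, _forces_kernel
from .model import FibrilModel
from .parameters import ForceField, default_forcefield
from .units import FTM2V, KB, MVV2E

__all__ = [
    "TensileProtocol",
    "Trajectory",
    "InstabilityError",
    "minimize",
    "step_nve",
    "equilibrate",
    "run_tensile",
    "kinetic_temperature",
    "axial_stress",
]


class InstabilityError(RuntimeError):
    """Raised when the kinetic temperature diverges (reduce dt)."""


@dataclasses.dataclass(frozen=True)
class TensileProtocol:
    """Equilibration + pulling schedule (defaults: full-scale protocol)."""

    dt: float = 10.0            # fs
    T: float = 300.0            # K
    P_axial: float = 0.0        # target axial stress, kcal/mol/A^3
    t_equil: float = 20.0       # ns
    v_pull: float = 1.0e-4      # A/fs (relative grip separation rate)
    max_strain: float = 0.6
    damping: float = 1000.0     # Langevin damping time, fs
    sample_every: int = 100     # steps between observable samples
    pos_every: int = 2000       # steps between stored position frames
    rebuild_every: int = 20     # steps between neighbor-list rebuilds
    baro_beta: float = 2.0e-6   # Berendsen gain, (kcal/mol/A^3)^-1 per step
    stop_at_rupture: bool = True
    rupture_floor: float = 0.01  # fraction of peak force
    #: thermostat coupling during steered runs.  'streaming' (default)
    #: couples axial velocity *fluctuations about each molecule's mean
    #: drift* plus the full transverse components, so sliding molecules
    #: feel no axial Langevin drag while slip-generated heat is still
    #: removed.  'transverse' couples y/z only; 'full' couples all
    #: components in the lab frame (also used for equilibration).
    pull_thermostat: str = "streaming"
    #: weak damping time (fs) of each molecule's mean axial velocity
    #: toward the affine strain field; drains bond-scission recoil
    #: energy that the fluctuation coupling cannot see.  Much longer
    #: than `damping`, so steady sliding is essentially unbiased.
    stream_damping: float = 10000.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.v_pull < 0:
            raise ValueError("v_pull must be >= 0")
        if self.sample_every % self.rebuild_every != 0:
            raise ValueError("sample_every must be a multiple of rebuild_every")

    @property
    def n_equil_steps(self) -> int:
        return int(round(self.t_equil * 1.0e6 / self.dt))


@dataclasses.dataclass
class Trajectory:
    """Sampled time series of one run plus final bond state."""

    times: np.ndarray           # fs, strictly increasing
    strains: np.ndarray         # engineering strain clock (exact kinematics)
    force: np.ndarray           # mean grip holding force, kcal/mol/A
    force_left: np.ndarray
    force_right: np.ndarray
    temperature: np.ndarray     # K
    energies: np.ndarray        # (n, 3): bond, angle, nonbonded
    gap_mean: np.ndarray        # mean axial gap-terminal distance, A
    n_broken: np.ndarray        # (n, 3): cumulative per bond class
    break_step: np.ndarray      # (M,) final per-bond break step, -1 intact
    bond_type: np.ndarray
    frames_t: np.ndarray        # fs
    frames: np.ndarray          # (nf, N, 3) stored positions
    gauge: float                # A
    area: float                 # A^2
    meta: dict

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            for name in ("times", "strains", "force", "force_left",
                         "force_right", "temperature", "energies", "gap_mean",
                         "n_broken", "break_step", "bond_type", "frames_t"):
                h5.create_dataset(name, data=getattr(self, name))
            h5.create_dataset("frames", data=self.frames,
                              chunks=True, compression="gzip")
            h5.attrs["gauge"] = self.gauge
            h5.attrs["area"] = self.area
            import json

            h5.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py
        import json

        with h5py.File(path, "r") as h5:
            kw = {name: h5[name][...] for name in
                  ("times", "strains", "force", "force_left", "force_right",
                   "temperature", "energies", "gap_mean", "n_broken",
                   "break_step", "bond_type", "frames_t", "frames")}
            return cls(gauge=float(h5.attrs["gauge"]),
                       area=float(h5.attrs["area"]),
                       meta=json.loads(h5.attrs["meta"]), **kw)


@njit(cache=True)
def _seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _integrate_chunk(pos, vel, forces, inv_mass_f, sig_v, free,
                     bonds, bond_type, broken, break_step, bond_tab,
                     angles, phi0, kb, pairs, pair_type, pair_tab,
                     box_l, dt, c1, c2, axial_mode, group, ngroups,
                     c1s, vaff_slope, x_mid, nsteps, step0):
    """BAOAB Langevin velocity-Verlet for ``nsteps`` steps.

    Grip particles (``free == 0``) keep their preset velocities: they
    drift but receive no kicks and no noise.  ``axial_mode`` selects the
    x-coupling: 0 none, 1 lab frame, 2 streaming (fluctuations about
    each group's mean axial velocity, with the mean itself weakly
    damped toward the affine field ``vaff_slope*(x - x_mid)``).
    Returns the energy terms, axial virial, and per-grip force sums
    from the last force evaluation.
    """
    n = pos.shape[0]
    eb = ea = ep = wxx = 0.0
    gsum = np.zeros(ngroups)
    gxsum = np.zeros(ngroups)
    gnew = np.zeros(ngroups)
    gcnt = np.zeros(ngroups)
    for s in range(nsteps):
        for i in range(n):
            if free[i] == 1:
                vx = vel[i, 0] + 0.5 * dt * forces[i, 0] * inv_mass_f[i]
                vy = vel[i, 1] + 0.5 * dt * forces[i, 1] * inv_mass_f[i]
                vz = vel[i, 2] + 0.5 * dt * forces[i, 2] * inv_mass_f[i]
                vel[i, 0] = vx
                vel[i, 1] = vy
                vel[i, 2] = vz
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        if c2 > 0.0:
            noise = np.random.standard_normal(3 * n)
            if axial_mode == 2:
                for g in range(ngroups):
                    gsum[g] = 0.0
                    gxsum[g] = 0.0
                    gcnt[g] = 0.0
                for i in range(n):
                    if free[i] == 1 and group[i] >= 0:
                        gsum[group[i]] += vel[i, 0]
                        gxsum[group[i]] += pos[i, 0]
                        gcnt[group[i]] += 1.0
                for g in range(ngroups):
                    if gcnt[g] > 0:
                        gsum[g] /= gcnt[g]
                        v_aff = vaff_slope * (gxsum[g] / gcnt[g] - x_mid)
                        gnew[g] = v_aff + c1s * (gsum[g] - v_aff)
            for i in range(n):
                if free[i] == 1:
                    if axial_mode == 1:
                        vel[i, 0] = c1 * vel[i, 0] + c2 * sig_v[i] * noise[3 * i]
                    elif axial_mode == 2 and group[i] >= 0:
                        vbar = gsum[group[i]]
                        vel[i, 0] = (gnew[group[i]] + c1 * (vel[i, 0] - vbar)
                                     + c2 * sig_v[i] * noise[3 * i])
                    vel[i, 1] = c1 * vel[i, 1] + c2 * sig_v[i] * noise[3 * i + 1]
                    vel[i, 2] = c1 * vel[i, 2] + c2 * sig_v[i] * noise[3 * i + 2]
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        eb, ea, ep, wxx = _forces_kernel(
            pos, forces, bonds, bond_type, broken, break_step, bond_tab,
            step0 + s + 1, angles, phi0, kb, pairs, pair_type, pair_tab, box_l)
        for i in range(n):
            if free[i] == 1:
                vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_mass_f[i]
                vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_mass_f[i]
                vel[i, 2] += 0.5 * dt * forces[i, 2] * inv_mass_f[i]
    return eb, ea, ep, wxx


class _Runner:
    """Shared state for one dynamics run on a model."""

    def __init__(self, model: FibrilModel, ff: ForceField,
                 protocol: TensileProtocol, seed: int,
                 grips_move: bool, axial_mode: int = 1):
        self.model = model
        self.ff = ff
        self.protocol = protocol
        rng = np.random.default_rng(seed)
        _seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
        n = model.n_particles
        self.mass = ff.mass_by_species()[model.species]
        self.inv_mass_f = (FTM2V / self.mass).astype(np.float64)
        self.sig_v = np.sqrt(KB * protocol.T / (self.mass * MVV2E))
        self.free = np.ones(n, dtype=np.int8)
        self.free[model.grip_left] = 0
        self.free[model.grip_right] = 0
        self.vel = rng.standard_normal((n, 3)) * self.sig_v[:, None]
        self.vel[self.free == 0] = 0.0
        if grips_move:
            half = 0.5 * protocol.v_pull
            self.vel[model.grip_left, 0] = -half
            self.vel[model.grip_right, 0] = +half
        self.forces = np.zeros((n, 3))
        self.box_l = model.box.lx if model.box.periodic_x else 0.0
        self.neigh = NeighborList(model, ff, skin=6.0)
        self.bond_tab = ff.bond_table(float(model.meta.get("age_stiffness_scale", 1.0)))
        self.pair_tab = ff.pair_table()
        self.step = 0
        gamma = 1.0 / protocol.damping if protocol.damping > 0 else 0.0
        self.c1 = float(np.exp(-gamma * protocol.dt))
        self.c2 = float(np.sqrt(max(1.0 - self.c1 * self.c1, 0.0))) if gamma > 0 else 0.0
        self.axial_mode = axial_mode
        self._t_recent: list[float] = []
        gs = (1.0 / protocol.stream_damping
              if protocol.stream_damping > 0 else 0.0)
        self.c1s = float(np.exp(-gs * protocol.dt))
        self.vaff_slope = 0.0
        self.x_mid = 0.0
        # streaming groups: one per molecule, one per lane's mineral column
        from .parameters import SPECIES_MINERAL

        group = model.mol_id.copy()
        n_mol_groups = int(group.max()) + 1 if group.size else 0
        is_min = model.species == SPECIES_MINERAL
        group[is_min] = n_mol_groups + model.lane_id[is_min]
        self.group = group.astype(np.int64)
        self.ngroups = int(group.max()) + 1 if group.size else 0
        self.last = self._eval()

    def _eval(self):
        self.neigh.rebuild(self.model.positions, self.model.species,
                           self.model.box.lo, self.box_l)
        m = self.model
        return _forces_kernel(
            m.positions, self.forces, m.bonds, m.bond_type, m.broken,
            m.break_step, self.bond_tab, self.step, m.angles, m.phi0,
            self.ff.angle.kb, self.neigh.pairs, self.neigh.pair_type,
            self.pair_tab, self.box_l)

    def advance(self, nsteps: int):
        """Advance in neighbor-rebuild chunks; returns last energy tuple."""
        p = self.protocol
        m = self.model
        done = 0
        while done < nsteps:
            chunk = min(p.rebuild_every, nsteps - done)
            self.last = _integrate_chunk(
                m.positions, self.vel, self.forces, self.inv_mass_f,
                self.sig_v, self.free, m.bonds, m.bond_type, m.broken,
                m.break_step, self.bond_tab, m.angles, m.phi0,
                self.ff.angle.kb, self.neigh.pairs, self.neigh.pair_type,
                self.pair_tab, self.box_l, p.dt, self.c1, self.c2,
                self.axial_mode, self.group, self.ngroups,
                self.c1s, self.vaff_slope, self.x_mid,
                chunk, self.step)
            done += chunk
            self.step += chunk
            self.neigh.rebuild(m.positions, m.species, m.box.lo, self.box_l)
        return self.last

    def temperature(self) -> float:
        return kinetic_temperature(self.vel, self.mass, self.free == 1)

    def grip_forces(self) -> tuple[float, float]:
        fl = float(self.forces[self.model.grip_left, 0].sum())
        fr = float(self.forces[self.model.grip_right, 0].sum())
        return fl, fr

    def check_stability(self) -> None:
        """Trip on temperature divergence (not on decaying transients).

        Bond-scission cascades dump recoil energy into whole-molecule
        axial motion, which the streaming thermostat drains only
        indirectly; single-sample spikes of a few thousand kelvin decay
        within picoseconds.  Divergence is therefore judged on a short
        running average at 10x the target, with an immediate trip at
        50x or non-finite values.
        """
        t = self.temperature()
        t_ref = max(self.protocol.T, 30.0)
        if not np.isfinite(t) or t > 50.0 * t_ref:
            raise InstabilityError(
                f"kinetic temperature {t:.0f} K diverged (target "
                f"{self.protocol.T} K); reduce the time step dt")
        self._t_recent.append(t)
        if len(self._t_recent) > 5:
            self._t_recent.pop(0)
        if len(self._t_recent) == 5 and np.mean(self._t_recent) > 10.0 * t_ref:
            raise InstabilityError(
                f"kinetic temperature sustained at "
                f"{np.mean(self._t_recent):.0f} K (target {self.protocol.T} "
                f"K); reduce the time step dt")


def kinetic_temperature(vel: np.ndarray, mass: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Instantaneous kinetic temperature (K) of the selected particles."""
    if mask is not None:
        vel = vel[mask]
        mass = mass[mask]
    if len(vel) == 0:
        return 0.0
    ke = 0.5 * MVV2E * float((mass[:, None] * vel * vel).sum())
    dof = 3 * len(vel)
    return 2.0 * ke / (dof * KB)


def axial_stress(model: FibrilModel, forcefield: ForceField | None = None,
                 vel: np.ndarray | None = None,
                 volume: float | None = None) -> float:
    """Virial estimate of axial stress (kcal/mol/A^3), tension positive."""
    from .forcefield import compute_forces

    ff = forcefield or default_forcefield()
    _, info = compute_forces(model, ff)
    if volume is None:
        lo, hi = model.gauge_bounds()
        volume = (hi - lo) * model.cross_section_area()
    kin = 0.0
    if vel is not None:
        mass = ff.mass_by_species()[model.species]
        kin = MVV2E * float((mass * (vel[:, 0] ** 2)).sum())
    return -(kin + info["virial_xx"]) / volume


def minimize(model: FibrilModel, forcefield: ForceField | None = None,
             ftol: float = 5.0, max_iter: int = 600,
             dt0: float = 2.0, dmax: float = 0.1) -> FibrilModel:
    """FIRE energy minimization (grip particles held fixed).

    Removes the potential-energy excess of freshly assembled models —
    mainly mineral settling into the strong cross-lane col-HAP wells —
    so that thermostatted dynamics starts without a thermal shock.
    Stops when the largest force component drops below ``ftol``
    (kcal/mol/A) or after ``max_iter`` evaluations.
    """
    ff = forcefield or default_forcefield()
    out = model.copy()
    proto = TensileProtocol(dt=dt0, damping=0.0, v_pull=0.0)
    runner = _Runner(out, ff, proto, seed=0, grips_move=False)
    n = out.n_particles
    vel = np.zeros((n, 3))
    free = runner.free[:, None].astype(bool)
    dt = dt0
    alpha = 0.1
    n_pos = 0
    for _ in range(max_iter):
        runner.last = runner._eval()
        F = runner.forces * free
        fmax = np.abs(F).max()
        if fmax < ftol:
            break
        P = float((F * vel).sum())
        if P > 0:
            n_pos += 1
            fnorm = np.linalg.norm(F)
            vnorm = np.linalg.norm(vel)
            if fnorm > 0:
                vel = (1 - alpha) * vel + alpha * vnorm * F / fnorm
            if n_pos > 5:
                dt = min(dt * 1.1, 10.0 * dt0)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt = max(dt * 0.5, 0.02 * dt0)
            alpha = 0.1
            n_pos = 0
        vel += dt * F * runner.inv_mass_f[:, None]
        dx = dt * vel
        step_len = np.abs(dx).max()
        if step_len > dmax:
            dx *= dmax / step_len
        out.positions += dx * free
    return out


def step_nve(model: FibrilModel, dt: float, n: int,
             velocities: np.ndarray | None = None,
             forcefield: ForceField | None = None
             ) -> tuple[FibrilModel, np.ndarray]:
    """Plain velocity-Verlet (no thermostat, no steering); validation use.

    Returns the advanced model and velocities.
    """
    ff = forcefield or default_forcefield()
    out = model.copy()
    proto = TensileProtocol(dt=dt, damping=0.0, v_pull=0.0,
                            sample_every=100, rebuild_every=20)
    runner = _Runner(out, ff, proto, seed=0, grips_move=False)
    runner.free[:] = 1  # no grips in NVE validation runs
    runner.vel[:] = 0.0 if velocities is None else velocities
    runner.advance(n)
    return out, runner.vel.copy()


def equilibrate(model: FibrilModel, protocol: TensileProtocol, seed: int = 0,
                n_steps: int | None = None,
                forcefield: ForceField | None = None,
                minimize_first: bool = True) -> FibrilModel:
    """NVT (finite fibril, grips pinned) or NPT-like (periodic) relaxation.

    Runs a FIRE minimization first (freshly assembled mineral releases
    substantial potential energy otherwise), then thermostatted
    dynamics.  For a periodic model the axial box length is rescaled
    toward the target axial stress (Berendsen-style); lateral
    directions stay open.  Deterministic under a fixed seed.
    """
    ff = forcefield or default_forcefield()
    steps = protocol.n_equil_steps if n_steps is None else int(n_steps)
    if steps == 0:
        return model.copy()
    out = minimize(model, ff) if minimize_first else model.copy()
    runner = _Runner(out, ff, protocol, seed, grips_move=False)
    area = out.cross_section_area()
    done = 0
    while done < steps:
        n = min(protocol.sample_every, steps - done)
        runner.advance(n)
        done += n
        runner.check_stability()
        if out.box.periodic_x:
            p_xx = _instant_axial_stress(runner, area)
            scale = 1.0 - protocol.baro_beta * n * (protocol.P_axial - p_xx)
            scale = float(np.clip(scale, 0.999, 1.001))
            lo = out.box.lo[0]
            out.positions[:, 0] = lo + (out.positions[:, 0] - lo) * scale
            out.box.hi[0] = lo + (out.box.hi[0] - lo) * scale
            runner.box_l = out.box.lx
    out.meta["equilibrated_steps"] = int(out.meta.get("equilibrated_steps", 0) + steps)
    return out


def _instant_axial_stress(runner: _Runner, area: float) -> float:
    m = runner.model
    if m.box.periodic_x:
        volume = m.box.lx * area
    else:
        lo, hi = m.gauge_bounds()
        volume = (hi - lo) * area
    kin = MVV2E * float((runner.mass * runner.vel[:, 0] ** 2)[runner.free == 1].sum())
    return -(kin + runner.last[3]) / volume


def run_tensile(model: FibrilModel, protocol: TensileProtocol, seed: int = 0,
                forcefield: ForceField | None = None,
                n_steps: int | None = None) -> Trajectory:
    """Constant-velocity destructive tensile test.

    The grip sets move apart at a relative rate ``v_pull`` (each at
    v_pull/2); the holding force is sampled every ``sample_every``
    steps.  Ends at ``max_strain`` or, with ``stop_at_rupture``, when
    the mean grip force falls below ``rupture_floor`` of its running
    peak after the peak.
    """
    ff = forcefield or default_forcefield()
    if len(model.grip_left) == 0 or len(model.grip_right) == 0:
        raise ValueError("tensile run needs grip particles at both ends "
                         "(build with strengthen_ends=True)")
    out = model.copy()
    mode = {"transverse": 0, "full": 1, "streaming": 2}[protocol.pull_thermostat]
    runner = _Runner(out, ff, protocol, seed, grips_move=True,
                     axial_mode=mode)
    lo, hi = out.gauge_bounds()
    gauge = hi - lo
    runner.x_mid = 0.5 * (lo + hi)
    runner.vaff_slope = protocol.v_pull / gauge
    area = out.cross_section_area()
    if n_steps is not None:
        total_steps = int(n_steps)
    elif protocol.v_pull > 0:
        total_steps = int(np.ceil(protocol.max_strain * gauge
                                  / protocol.v_pull / protocol.dt))
    else:
        raise ValueError("v_pull = 0 requires an explicit n_steps")

    rec: dict[str, list] = {k: [] for k in
                            ("t", "eps", "fl", "fr", "T", "E", "gap", "nb")}
    frames = []
    frames_t = []
    box_l = runner.box_l

    def gap_mean() -> float:
        if len(out.gap_pairs) == 0:
            return np.nan
        d = (out.positions[out.gap_pairs[:, 1], 0]
             - out.positions[out.gap_pairs[:, 0], 0])
        if box_l > 0.0:
            d -= box_l * np.round(d / box_l)
        return float(np.abs(d).mean())

    def sample() -> None:
        t = runner.step * protocol.dt
        fl, fr = runner.grip_forces()
        rec["t"].append(t)
        rec["eps"].append(protocol.v_pull * t / gauge)
        rec["fl"].append(fl)
        rec["fr"].append(fr)
        rec["T"].append(runner.temperature())
        rec["E"].append(runner.last[:3])
        rec["gap"].append(gap_mean())
        counts = [int(np.sum((out.break_step >= 0) & (out.bond_type == c)))
                  for c in range(3)]
        rec["nb"].append(counts)
        if runner.step % protocol.pos_every == 0:
            frames.append(out.positions.copy())
            frames_t.append(t)

    sample()
    peak = 0.0
    eps_at_peak = 0.0
    while runner.step < total_steps:
        runner.advance(min(protocol.sample_every, total_steps - runner.step))
        sample()
        runner.check_stability()
        # keep the affine reference field consistent with the growing gauge
        runner.vaff_slope = protocol.v_pull / (gauge * (1.0 + rec["eps"][-1]))
        if protocol.stop_at_rupture and protocol.v_pull > 0:
            f_now = 0.5 * (abs(rec["fl"][-1]) + abs(rec["fr"][-1]))
            eps_now = rec["eps"][-1]
            if f_now > peak:
                peak = f_now
                eps_at_peak = eps_now
            if (eps_now > 0.05 and peak > 0
                    and eps_now > eps_at_peak + 0.02
                    and f_now < protocol.rupture_floor * peak):
                break

    force_left = np.array(rec["fl"])
    force_right = np.array(rec["fr"])
    # under tension the interior pulls both grips inward: the internal
    # x-force is positive on the left grip, negative on the right; the
    # tensile (holding) force averaged over both ends is (fl - fr)/2
    force = 0.5 * (force_left - force_right)
    return Trajectory(
        times=np.array(rec["t"]),
        strains=np.array(rec["eps"]),
        force=force,
        force_left=force_left,
        force_right=force_right,
        temperature=np.array(rec["T"]),
        energies=np.array(rec["E"]),
        gap_mean=np.array(rec["gap"]),
        n_broken=np.array(rec["nb"], dtype=np.int64),
        break_step=out.break_step.copy(),
        bond_type=out.bond_type.copy(),
        frames_t=np.array(frames_t),
        frames=np.array(frames) if frames else np.empty((0, out.n_particles, 3)),
        gauge=float(gauge),
        area=float(area),
        meta=dict(model.meta) | dict(
            seed=seed, dt=protocol.dt, T=protocol.T,
            v_pull=protocol.v_pull, sample_every=protocol.sample_every),
    )
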