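# Methods

`fibrilcg` simulates destructive tensile tests on coarse-grained models
of mineralized, AGE-cross-linked collagen fibrils.  This note records
the model, the numerical choices, and the places where the geometry or
protocol was genuinely open and a design decision had to be made.

## The model

A tropocollagen (TC) molecule is a chain of 218 beads connected by
breakable springs (equilibrium length r0 = 14.00 Å, bead mass
1548 amu).  Molecules sit on a hexagonal lateral lattice and are
staggered axially by multiples of the D-period (D = 67 nm) in the
classic 5-stagger pattern, producing alternating overlap (0.4·D) and
gap (0.6·D) bands.  Gap zones can be mineralized with bonded-free
hydroxyapatite-like beads (1324 amu) held purely by nonbonded forces,
and molecules can be cross-linked by AGE (glucosepane-parameterized)
breakable springs inserted at random between neighboring molecules.

### Interactions

* **Bonds** (collagen backbone, strengthened end segments, AGE
  cross-links): trilinear breakable springs.  The force is
  `-k0·(r-r0)` up to the critical distance r1, continues with slope
  `k1` (continuously) up to the breaking distance `rbreak`, then
  follows a short regularization ramp `+z·k1·(r-r0)` of width
  `a = z·(rbreak - r1)`, after which the bond is permanently broken
  (zero force and energy; the broken flag never clears).  The sign
  change at `rbreak` is kept as the model defines it; the ramp is
  traversed at most once per bond because of the latch.
* **Angles**: harmonic bending `½·kB·(φ-φ0)²` on every consecutive
  bead triplet, with per-triplet equilibrium angles φ0 *read from the
  built geometry*, so a freshly built model has exactly zero bond and
  angle energy.
* **Pairs**: Lennard-Jones with a soft core — below `λσ` the force is
  capped at its value at `λσ` (the potential continues linearly) — for
  col–col, HAP–HAP and col–HAP species pairs, cut and shifted to zero
  at the cutoff.  Only directly bonded pairs (1–2, including AGE
  pairs) are excluded, permanently.

All parameter values live in one YAML table
(`src/fibrilcg/data/forcefield_default.yaml`), loaded and
schema-validated at run time; a test asserts every entry verbatim.
The col–col cutoff is not tabulated anywhere; the package uses 2.5·σ.

### Units

LAMMPS-style "real" units: kcal/mol, Å, fs, amu.  The only conversion
constants are in `fibrilcg/units.py`; stress reported in MPa uses
1 kcal·mol⁻¹·Å⁻³ = 6947.7 MPa.

## Geometry construction

Three printed facts are mutually inconsistent for a straight chain:
218 beads at 14.00 Å spacing (contour 3038 Å), a 5-staggered lattice
with D = 670 Å, and a 0.6·D gap — the last two force an axial
molecular span of 4.4·D = 2948 Å.  The package reconciles them the way
the tabulated equilibrium-angle range (170–180°) suggests: the default
backbone is a gentle sinusoid with *exact* 14.00 Å chords whose
amplitude is root-found so the axial span is exactly 2948 Å
(amplitude ≈ 18.6 Å at wavelength D/2).  All molecules share one
global undulation phase (stagger offsets are multiples of the
wavelength), so lateral bead–bead distances equal the lattice spacing
everywhere.  A user-supplied backbone trace (plain-text x y z table)
can replace the idealized one; its span must match the layout.

**Cross-section.**  The lateral lattice spacing defaults to
2^(1/6)·σ_col = 16.52 Å, the col–col pair equilibrium — this is what
gives neighboring molecules the LJ contact that intermolecular
friction, sliding and mineral bridging all depend on.  The printed
correspondence "155 molecules ↔ 200 nm diameter" is therefore treated
as a *count* specification: a nominal cross-section radius maps to
`n = round(155·(r/1000 Å)²)` molecules (the bead lattice itself is
~21 nm across).  The stagger index is assigned as `k = (i + 2j) mod 5`
on the lattice coordinates, which guarantees all six nearest neighbors
of a site differ in offset.

**Finite fibrils and grips.**  A pullable fibril is cut from the
infinite tiling at a window offset of 0.2·D.  Any offset u with
0 < u < (1 − gap_fraction)·D cuts *every* lane's molecule at both
window boundaries, so each lane becomes
grip–fragment–gap–fragment–grip: tensile load must cross the gap
(through mineral, cross-links or intermolecular friction) rather than
running through a molecule gripped at both ends.  Each lane's
outermost chain ends are extended by 40 beads with the strengthened
bond parameters (rbreak = 70 Å); these extension beads form the rigid
grips.  With `periodic=True` the tiling wraps through the axial
boundary instead (minimum-image bonds), for infinite-fibril
equilibration.

**Mineralization.**  Mineral beads are placed along the continuation
of the lane's backbone curve, at the HAP equilibrium spacing
2^(1/6)·σ_HAP = 11.54 Å, with the first bead of each front at the
col–HAP equilibrium 2^(1/6)·σ_col-HAP = 11.09 Å from the terminal
collagen bead — the fresh model is clash-free by construction.  The
content c_mineral is the percentage of gap length occupied
(n·spacing/l·100); the count for a requested c is
`floor(c/100·l/s) + 1`, capped so opposing fronts never collide.
Morphologies: edge nucleation (fronts from both gap edges), center
nucleation (symmetric grid from the gap center), sparse (every second
reference position, axially sorted — exactly ⌈n/2⌉ beads, same span),
and double rows (+-spacing/2 perpendicular offsets about the gap line,
oriented between hexagonal neighbor directions so the rows keep ~12 Å
clearance from neighboring lanes; a full one-sided offset would sit
8.7 Å from a neighbor lane, deep inside col–HAP repulsion).

**Cross-links.**  Anchors are restricted to the central 95% of each
molecule's bead index range; partners must belong to a different
molecule within `r0_AGE + 4 Å`.  Each molecule owns a quota of
`n_age_per_tc` scaled by the fraction of its beads present in the
build window (largest-remainder rounding), so the total is exactly
`n_age_per_tc ×` (molecule strands per cross-section) and links never
accumulate on the short boundary fragments of cut molecules.  The
inserted bond's rest length is the AGE r0 regardless of the anchors'
instantaneous separation (pre-tensioned links would inject energy; the
AGE first-regime stiffness of 0.1 kcal/mol/Å² makes the residual
negligible).  AGE stiffness can be doubled via `stiffness_scale=2`.

## Dynamics

Velocity-Verlet with a Langevin thermostat in the BAOAB splitting;
Δt = 10 fs (bond periods are tens of ps at these masses, so this is
conservative — the NVE validation integrator holds relative energy
drift below 1e-4 over 10⁴ steps).  Neighbor lists are Verlet lists
with a 6 Å skin rebuilt every 20–50 steps.

**Minimization before dynamics.**  Freshly mineralized models are far
from the nonbonded minimum in one specific way: a mineral bead in a
gap is inside the (strong, ε = 137.1 kcal/mol) col–HAP attraction
wells of the *neighboring* lanes, and on first contact the structure
releases enough potential energy to heat a mini fibril by thousands of
kelvin in a picosecond.  `equilibrate` therefore runs a FIRE
minimization first (grips held), then thermostats at the target
temperature.  The mineral relaxing laterally toward the surrounding
molecules is the model's "glue" configuration, not an artifact.

**Equilibration.**  Finite fibrils: NVT with grips pinned.  Periodic
fibrils: the axial box length is additionally rescaled toward the
target axial stress with a weak Berendsen-style factor computed from
the virial (lateral directions are open — the cross-section is
finite).

**Steered pulling.**  The grip sets move apart as rigid bodies at
±v_pull/2 along the axis (default v_pull = 1e-4 Å/fs = 10 m/s); the
engineering-strain clock is exact kinematics (grip displacement over
the initial gauge length, the body length excluding grips).  The
holding force — minus the summed internal axial force on each grip,
averaged over both ends — is sampled every 100 steps.

**Thermostat during pulling.**  A lab-frame Langevin thermostat drags
every bead toward zero velocity; at the pull velocities a desk run can
afford, that drag (γ·m·v per bead, ~218 beads per molecule) exceeds
the collagen bond strength and suppresses the intermolecular sliding
that dominates unmineralized fibril failure.  Steered runs therefore
default to a profile-unbiased ("streaming") Langevin: the axial
coupling acts on fluctuations about each molecule's (and each mineral
column's) instantaneous mean axial velocity, while the transverse
components are thermostatted in full.  The group means themselves are
damped only weakly (`stream_damping`, default 10 000 fs vs 1000 fs for
fluctuations) toward the affine strain field v(x) = v_pull·(x−x_mid)/L
— zero bias for molecules following the macroscopic flow, but a drain
for the whole-molecule recoil energy released by bond-scission
cascades, which the fluctuation coupling cannot see.  The lab-frame
thermostat remains available (`pull_thermostat="full"`) and is always
used for equilibration.

Runs abort with an instability error pointing at the time step when
the kinetic temperature diverges: immediately at 50× the target or
non-finite values, and at 10× the target sustained over five
consecutive samples (single-sample recoil spikes of a few thousand
kelvin decay within picoseconds and are not divergence).

## Analysis

Engineering stress = holding force / initial cross-section area; the
area is the convex hull of the lateral lattice sites plus one
hexagonal cell (mini cross-sections deviate far from the nominal
circle, so the hull is recorded in the report).  From the curve:
σ_peak (global maximum after a 5-sample median filter used for
*detection only*), ε_peak, ε_PF0 (first strain after the peak where
the smoothed stress falls below 1% of σ_peak — the floor is a config
value), and the post-failure work W_PF = ∫σ dε over [ε_peak, ε_PF0]
by the trapezoid rule on the raw curve.  The initial modulus is the
least-squares slope on ε ∈ [0, 0.05].  Sawtooth metrics count
post-yield drops larger than 5% of σ_peak between successive local
extrema of the smoothed curve.  Broken bonds are counted per class
(collagen / end / AGE) from per-bond break steps recorded by the
integrator, and the average gap length is the mean axial distance
between the gap-terminal bead pairs identified at build time.

## Desk-scale protocol and what it shows

The full-scale protocol (155 molecules, 20 ns equilibration, 1e-4 Å/fs
pull to rupture) is the library default but needs cluster time.  The
test suite and trend checks run a desk-scale protocol chosen once:

* mini fibrils of 7 molecules × 5 D-periods (~2100 beads), so every
  lane still carries one interior gap;
* 1500-step (15 ps) thermostatted equilibration after FIRE
  minimization;
* pull at v = 1e-3 Å/fs with the streaming thermostat, Δt = 10 fs,
  damping 1000 fs, to a strain of 0.6.

At these conditions the package reproduces the qualitative mechanics:
an unmineralized, uncross-linked fibril fails by molecular pull-out
with zero broken collagen bonds and a sawtooth stress decay; mineral
raises the peak stress several-fold and, at high content, switches
failure to collagen bond scission; AGE cross-links raise the peak
stress at zero mineral; the initial modulus is insensitive to both.
Quantities that depend on absolute scale (peak stresses in GPa,
hundreds of broken bonds, W_PF magnitudes) are *not* desk-scale
reproducible: a 7-lane cross-section has a far larger surface-to-bulk
ratio than 155 lanes, and the tenfold-faster pull shifts rate-dependent
stick–slip. The synthetic mini fibril also idealizes what real
fibrils are not: perfectly crystalline lateral order, identical
molecules, no hydration, no enzymatic cross-links, no extrafibrillar
mineral — passing trend tests therefore validates the implementation's
mechanics, not a quantitative prediction for bone.

## Known limitations

* No solvent, electrostatics, pH effects, or enzymatic cross-links;
  mineral is restricted to gap zones (the extrafibrillar debate is out
  of scope).
* Angle triplets spanning the two fragments of a molecule rejoined
  across a periodic boundary are omitted (two per lane).
* Broken-bond endpoints never regain nonbonded interaction (static
  exclusions, LAMMPS `special_bonds` semantics).
* The Berendsen-style axial barostat targets the virial stress only
  weakly; it is meant for relaxing residual build stress, not for
  production NPT statistics.
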