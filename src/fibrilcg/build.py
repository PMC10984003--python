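"""Staggered fibril geometry construction.

Molecules sit on a hexagonal lateral lattice; each lattice site ("lane")
carries an axial stagger offset of k*D with k in {0..4} assigned so that
lateral neighbors always differ (the classic quarter/fifth-stagger
banding).  Along each lane, molecules tile with period 5*D leaving a
gap of ``gap_fraction*D`` between the end of one molecule and the start
of the next.

For a finite (pullable) fibril the infinite tiling is cut to a window of
``n_periods*D`` starting at an offset of 0.2*D into the pattern.  Any
offset u with 0 < u/D < 1 - gap_fraction guarantees that *every* lane's
molecule is cut at the window boundaries, so each lane becomes a
grip-fragment-gap-fragment-grip series and tensile load must cross the
gap zones instead of running through molecules gripped at both ends.  With ``periodic=True`` molecules wrap through
the axial boundary instead (infinite-fibril equilibration).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .backbone import BackboneTrace, wavy_backbone
from .model import Box, FibrilModel
from .parameters import (
    BOND_COLLAGEN,
    BOND_END,
    SPECIES_COLLAGEN,
    SPECIES_END,
    ForceField,
    default_forcefield,
)

__all__ = ["FibrilLayout", "build_fibril", "hex_lattice_sites", "default_backbone"]

#: number of distinct stagger offsets (k*D, k = 0..n_stagger-1)
N_STAGGER = 5


@dataclasses.dataclass(frozen=True)
class FibrilLayout:
    """Geometric parameters of the staggered fibril.

    The cross-section is specified either by an explicit molecule count
    ``n_molecules`` or by a nominal ``cross_section_radius``; the
    nominal radius maps to a count through the canonical density of
    155 molecules per 200-nm-diameter cross-section.
    """

    D: float = 670.0                   # axial period (A)
    gap_fraction: float = 0.6
    overlap_fraction: float = 0.4
    n_periods: int = 5                 # window length in D-periods
    cross_section_radius: float = 1000.0   # nominal radius (A)
    n_molecules: int | None = None     # overrides the radius if given
    lateral_spacing: float | None = None   # default: 2^(1/6)*sigma_col
    n_end_particles: int = 40          # strengthened extension per lane per end
    window_offset_frac: float = 0.2    # cut offset into the pattern, units of D
    wavelength: float | None = None    # backbone undulation period, default D/2

    def __post_init__(self) -> None:
        if abs(self.gap_fraction + self.overlap_fraction - 1.0) > 1e-9:
            raise ValueError("gap_fraction + overlap_fraction must equal 1")
        if self.D <= 0 or self.n_periods < 1:
            raise ValueError("D must be positive and n_periods >= 1")
        if not (0.0 < self.window_offset_frac < 1.0 - self.gap_fraction):
            raise ValueError(
                "window_offset_frac must lie in (0, 1 - gap_fraction) so that "
                "every stagger lane is cut at the window boundaries"
            )

    @property
    def gap_length(self) -> float:
        return self.gap_fraction * self.D

    @property
    def molecule_span(self) -> float:
        """Axial extent of one molecule: 5*D minus the gap."""
        return N_STAGGER * self.D - self.gap_length

    @property
    def length(self) -> float:
        return self.n_periods * self.D

    def molecule_count(self) -> int:
        if self.n_molecules is not None:
            if self.n_molecules < 1:
                raise ValueError("n_molecules must be >= 1")
            return self.n_molecules
        n = int(round(155.0 * (self.cross_section_radius / 1000.0) ** 2))
        if n < 1:
            raise ValueError(
                "cross-section radius too small to hold any molecule"
            )
        return n


def hex_lattice_sites(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """The ``n`` hexagonal lattice sites closest to the axis.

    Returns ``(sites, stagger)``: (n, 2) y/z coordinates centered on the
    axis, and the stagger index k in {0..4} per site, assigned by
    ``k = (i + 2 j) mod 5`` on the lattice coordinates, which guarantees
    that all six nearest neighbors of a site have a different k.
    """
    r = int(np.ceil(np.sqrt(n))) + 2
    ij = np.array(
        [(i, j) for i in range(-r, r + 1) for j in range(-r, r + 1)],
        dtype=np.int64,
    )
    y = (ij[:, 0] + 0.5 * ij[:, 1]) * spacing
    z = ij[:, 1] * (np.sqrt(3.0) / 2.0) * spacing
    rad2 = y * y + z * z
    ang = np.arctan2(z, y)
    order = np.lexsort((ij[:, 1], ij[:, 0], np.round(ang, 9), np.round(rad2, 6)))
    sel = order[:n]
    sites = np.column_stack([y[sel], z[sel]])
    stagger = ((ij[sel, 0] + 2 * ij[sel, 1]) % N_STAGGER).astype(np.int64)
    return sites, stagger


def default_backbone(layout: FibrilLayout, forcefield: ForceField | None = None,
                     n_particles: int = 218) -> BackboneTrace:
    """Sinusoidal backbone with exact r0 chords spanning 4.4*D axially."""
    ff = forcefield or default_forcefield()
    r0 = ff.bonds["collagen"].r0
    wavelength = layout.wavelength or layout.D / 2.0
    return wavy_backbone(n_particles, r0, layout.molecule_span, wavelength)


def build_fibril(
    layout: FibrilLayout,
    backbone: BackboneTrace | None = None,
    strengthen_ends: bool = True,
    forcefield: ForceField | None = None,
    periodic: bool = False,
    min_distance_check: bool = True,
) -> FibrilModel:
    """Construct the full fibril particle model (no mineral, no AGEs)."""
    ff = forcefield or default_forcefield()
    if backbone is None:
        backbone = default_backbone(layout, ff)
    span = backbone.axial_span
    if abs(span - layout.molecule_span) > float(np.max(backbone.spacings)):
        raise ValueError(
            f"backbone axial span {span:.2f} A inconsistent with layout "
            f"molecule span {layout.molecule_span:.2f} A"
        )
    if periodic and layout.n_periods % N_STAGGER != 0:
        raise ValueError("periodic fibrils need n_periods to be a multiple of 5")
    if periodic and strengthen_ends:
        raise ValueError("periodic fibrils have no ends to strengthen")
    if backbone.wave is not None:
        n_waves = layout.D / backbone.wave[1]
        if abs(n_waves - round(n_waves)) > 1e-6:
            raise ValueError(
                "backbone wavelength must divide the D-period so all "
                "staggered molecules share one global undulation phase"
            )

    n_mol_particles = backbone.n_particles
    r0 = ff.bonds["collagen"].r0
    D = layout.D
    period = N_STAGGER * D
    L = layout.length
    win_lo = layout.window_offset_frac * D
    win_hi = win_lo + L

    sites, stagger = hex_lattice_sites(layout.molecule_count(), layout_spacing(layout, ff))
    txs = backbone.coordinates[:, 0] - backbone.coordinates[0, 0]
    tys = backbone.coordinates[:, 1] - backbone.coordinates[0, 1]
    tzs = backbone.coordinates[:, 2] - backbone.coordinates[0, 2]

    # chains: list of dicts with coordinate arrays and bookkeeping
    chains = []
    mol_uid = 0
    n_rep = layout.n_periods // N_STAGGER if periodic else 0
    lane_mol_uid: dict[tuple[int, int], int] = {}
    for lane in range(len(sites)):
        offset = stagger[lane] * D
        m_lo = int(np.floor((win_lo - offset - span) / period)) - 1
        m_hi = int(np.ceil((win_hi - offset) / period)) + 1
        for m in range(m_lo, m_hi + 1):
            start = offset + m * period
            x = start + txs
            if periodic:
                mask = (x >= win_lo - 1e-9) & (x < win_hi - 1e-9)
            else:
                mask = (x >= win_lo - 1e-9) & (x <= win_hi + 1e-9)
            if mask.sum() < 2:
                continue
            idx = np.flatnonzero(mask)
            # under periodic wrapping, images separated by the box length
            # are the same physical molecule
            key = (lane, m % n_rep) if periodic else (lane, m)
            if key not in lane_mol_uid:
                lane_mol_uid[key] = mol_uid
                mol_uid += 1
            chains.append(
                dict(
                    lane=lane,
                    mol=lane_mol_uid[key],
                    image=m,
                    x=x[idx].copy(),
                    y=sites[lane, 0] + tys[idx],
                    z=sites[lane, 1] + tzs[idx],
                    mol_index=idx.copy(),
                    species=np.full(idx.size, SPECIES_COLLAGEN, dtype=np.int64),
                )
            )

    if not chains:
        raise ValueError("empty model: no molecule intersects the build window")

    # strengthened end extensions: prepend/append to each lane's outermost chain
    if strengthen_ends and not periodic:
        n_end = layout.n_end_particles
        by_lane: dict[int, list[int]] = {}
        for ci, ch in enumerate(chains):
            by_lane.setdefault(ch["lane"], []).append(ci)
        for lane, cis in by_lane.items():
            first = min(cis, key=lambda ci: chains[ci]["x"][0])
            last = max(cis, key=lambda ci: chains[ci]["x"][-1])
            ch = chains[first]
            ext_x = ch["x"][0] - r0 * np.arange(n_end, 0, -1)
            ch["x"] = np.concatenate([ext_x, ch["x"]])
            ch["y"] = np.concatenate([np.full(n_end, ch["y"][0]), ch["y"]])
            ch["z"] = np.concatenate([np.full(n_end, ch["z"][0]), ch["z"]])
            ch["mol_index"] = np.concatenate(
                [np.full(n_end, -1, dtype=np.int64), ch["mol_index"]]
            )
            ch["species"] = np.concatenate(
                [np.full(n_end, SPECIES_END, dtype=np.int64), ch["species"]]
            )
            ch = chains[last]
            ext_x = ch["x"][-1] + r0 * np.arange(1, n_end + 1)
            ch["x"] = np.concatenate([ch["x"], ext_x])
            ch["y"] = np.concatenate([ch["y"], np.full(n_end, ch["y"][-1])])
            ch["z"] = np.concatenate([ch["z"], np.full(n_end, ch["z"][-1])])
            ch["mol_index"] = np.concatenate(
                [ch["mol_index"], np.full(n_end, -1, dtype=np.int64)]
            )
            ch["species"] = np.concatenate(
                [ch["species"], np.full(n_end, SPECIES_END, dtype=np.int64)]
            )

    # concatenate chains into flat arrays
    counts = [ch["x"].size for ch in chains]
    starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
    n_total = int(sum(counts))
    positions = np.empty((n_total, 3))
    species = np.empty(n_total, dtype=np.int64)
    mol_id = np.empty(n_total, dtype=np.int64)
    lane_id = np.empty(n_total, dtype=np.int64)
    mol_index = np.empty(n_total, dtype=np.int64)
    bond_list = []
    bond_types = []
    for ch, s in zip(chains, starts):
        n = ch["x"].size
        sl = slice(s, s + n)
        positions[sl, 0] = ch["x"]
        positions[sl, 1] = ch["y"]
        positions[sl, 2] = ch["z"]
        species[sl] = ch["species"]
        mol_id[sl] = ch["mol"]
        lane_id[sl] = ch["lane"]
        mol_index[sl] = ch["mol_index"]
        ii = np.arange(s, s + n - 1)
        bond_list.append(np.column_stack([ii, ii + 1]))
        # a bond is "end" type if either endpoint is an end particle
        is_end = (ch["species"][:-1] == SPECIES_END) | (ch["species"][1:] == SPECIES_END)
        bond_types.append(np.where(is_end, BOND_END, BOND_COLLAGEN))
    bonds = np.concatenate(bond_list).astype(np.int64)
    bond_type = np.concatenate(bond_types).astype(np.int64)

    # periodic wrap: join each lane's chain images through the boundary
    if periodic:
        positions[:, 0] = win_lo + np.mod(positions[:, 0] - win_lo, L)
        extra_bonds = []
        for lane in set(ch["lane"] for ch in chains):
            cis = [ci for ci, ch in enumerate(chains) if ch["lane"] == lane]
            # reconnect fragments of the same molecule split by the window
            frags: dict[int, list[int]] = {}
            for ci in cis:
                frags.setdefault(chains[ci]["mol"], []).append(ci)
            # molecules may appear as one image only (fully inside);
            # a molecule whose template indices are split across two chains
            # with contiguous mol_index must be re-bonded
            for mol, group in frags.items():
                if len(group) < 2:
                    continue
                group = sorted(group, key=lambda ci: chains[ci]["mol_index"][0])
                for a, b in zip(group[:-1], group[1:]):
                    ia = starts[a] + chains[a]["x"].size - 1
                    ib = starts[b]
                    if (chains[a]["mol_index"][-1] + 1
                            == chains[b]["mol_index"][0]):
                        extra_bonds.append((ia, ib))
        if extra_bonds:
            bonds = np.vstack([bonds, np.array(extra_bonds, dtype=np.int64)])
            bond_type = np.concatenate(
                [bond_type, np.full(len(extra_bonds), BOND_COLLAGEN, dtype=np.int64)]
            )

    # angles: consecutive triplets along each chain
    box_l = L if periodic else 0.0
    angle_list = []
    for ch, s in zip(chains, starts):
        n = ch["x"].size
        if n >= 3:
            ii = np.arange(s, s + n - 2)
            angle_list.append(np.column_stack([ii, ii + 1, ii + 2]))
    angles = (np.concatenate(angle_list).astype(np.int64)
              if angle_list else np.empty((0, 3), dtype=np.int64))
    phi0 = _measure_angles(positions, angles, box_l)

    # gap-terminal pairs: consecutive chains along each lane.  A pair is a
    # true gap only when the left chain ends at a molecule's last bead and
    # the right chain starts at a molecule's first bead (the cut junction
    # of one molecule split by the window is contiguous in mol_index and
    # is excluded by this test).
    nlast = n_mol_particles - 1

    def _is_gap(a: int, b: int) -> bool:
        ca, cb = chains[a], chains[b]
        return (ca["mol_index"][ca["species"] == SPECIES_COLLAGEN][-1] == nlast
                and cb["mol_index"][cb["species"] == SPECIES_COLLAGEN][0] == 0)

    def _terminals(a: int, b: int) -> tuple[int, int]:
        ia = starts[a] + np.flatnonzero(chains[a]["species"] == SPECIES_COLLAGEN)[-1]
        ib = starts[b] + np.flatnonzero(chains[b]["species"] == SPECIES_COLLAGEN)[0]
        return int(ia), int(ib)

    gap_pairs = []
    for lane in set(ch["lane"] for ch in chains):
        cis = sorted(
            (ci for ci, ch in enumerate(chains) if ch["lane"] == lane),
            key=lambda ci: chains[ci]["x"][0],
        )
        for a, b in zip(cis[:-1], cis[1:]):
            if _is_gap(a, b):
                gap_pairs.append(_terminals(a, b))
        if periodic and len(cis) >= 2 and _is_gap(cis[-1], cis[0]):
            gap_pairs.append(_terminals(cis[-1], cis[0]))
    gap_pairs = (np.array(sorted(gap_pairs), dtype=np.int64)
                 if gap_pairs else np.empty((0, 2), dtype=np.int64))

    grip_left = np.flatnonzero((species == SPECIES_END) & (positions[:, 0] < win_lo))
    grip_right = np.flatnonzero((species == SPECIES_END) & (positions[:, 0] > win_hi))

    # shift so the fibril body starts at x = 0
    positions[:, 0] -= win_lo
    pad = 3.0 * layout_spacing(layout, ff)
    lo = positions.min(axis=0) - pad
    hi = positions.max(axis=0) + pad
    if periodic:
        lo[0], hi[0] = 0.0, L
    box = Box(lo=lo, hi=hi, periodic_x=periodic)

    meta = dict(
        D=D,
        gap_fraction=layout.gap_fraction,
        n_periods=layout.n_periods,
        molecule_span=span,
        n_mol_particles=n_mol_particles,
        lateral_spacing=layout_spacing(layout, ff),
        lane_sites=[[float(v) for v in s] for s in sites],
        lane_stagger=[int(k) for k in stagger],
        gauge=[0.0, L],
        n_end_particles=layout.n_end_particles if strengthen_ends else 0,
        age_stiffness_scale=1.0,
        periodic=periodic,
        wave_amplitude=backbone.wave[0] if backbone.wave else 0.0,
        wave_length=backbone.wave[1] if backbone.wave else 0.0,
        wave_x_offset=win_lo,
    )

    model = FibrilModel(
        positions=positions,
        species=species,
        mol_id=mol_id,
        lane_id=lane_id,
        mol_index=mol_index,
        bonds=bonds,
        bond_type=bond_type,
        broken=np.zeros(len(bonds), dtype=np.uint8),
        break_step=np.full(len(bonds), -1, dtype=np.int64),
        angles=angles,
        phi0=phi0,
        box=box,
        gap_pairs=gap_pairs,
        grip_left=grip_left.astype(np.int64),
        grip_right=grip_right.astype(np.int64),
        meta=meta,
    )
    if min_distance_check:
        _check_min_distance(model, 0.5 * min(p.sigma for p in ff.pairs.values()))
    return model


def layout_spacing(layout: FibrilLayout, ff: ForceField) -> float:
    return (layout.lateral_spacing
            if layout.lateral_spacing is not None else ff.r0_col_pair)


def _measure_angles(positions: np.ndarray, angles: np.ndarray, box_l: float
                    ) -> np.ndarray:
    """Equilibrium angles (radians) read off the built geometry."""
    if len(angles) == 0:
        return np.empty(0)
    r1 = positions[angles[:, 0]] - positions[angles[:, 1]]
    r2 = positions[angles[:, 2]] - positions[angles[:, 1]]
    if box_l > 0.0:
        for r in (r1, r2):
            r[:, 0] -= box_l * np.round(r[:, 0] / box_l)
    c = (r1 * r2).sum(axis=1) / (
        np.linalg.norm(r1, axis=1) * np.linalg.norm(r2, axis=1)
    )
    return np.arccos(np.clip(c, -1.0, 1.0))


def _check_min_distance(model: FibrilModel, dmin: float) -> None:
    tree = cKDTree(model.positions)
    pairs = tree.query_pairs(dmin, output_type="ndarray")
    if len(pairs):
        i, j = pairs[0]
        raise ValueError(
            f"build produced particles {i} and {j} closer than {dmin:.2f} A"
        )
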