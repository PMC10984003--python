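"""Deterministic model presets, from a two-bead dimer to the full fibril.

Presets are desk-scale stand-ins that preserve the layout invariants
(D-period, 0.6/0.4 gap-overlap split, 5-stagger rule) at reduced
molecule counts and window lengths:

===============  ==========================  =================
preset           cross-section               window
===============  ==========================  =================
dimer            2 bonded beads              --
single_molecule  1 molecule                  5 D-periods
mini_fibril_7    7 molecules                 2 D-periods
mini_fibril_19   19 molecules                2 D-periods
reference_full   155 molecules (nominal      5 D-periods
                 200 nm diameter)
===============  ==========================  =================

``overrides`` are applied to the :class:`FibrilLayout` (e.g.
``n_periods=5`` turns mini_fibril_7 into the trend-test fixture where
every lane has an interior gap).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .build import FibrilLayout, build_fibril
from .model import Box, FibrilModel
from .parameters import (
    BOND_AGE,
    BOND_COLLAGEN,
    BOND_END,
    SPECIES_COLLAGEN,
    ForceField,
    default_forcefield,
)

__all__ = ["FixtureSpec", "make_fixture", "two_particle_model", "PRESETS"]

PRESETS = {
    "single_molecule": dict(n_molecules=1, n_periods=5),
    "mini_fibril_7": dict(n_molecules=7, n_periods=2),
    "mini_fibril_19": dict(n_molecules=19, n_periods=2),
    "reference_full": dict(n_molecules=None, cross_section_radius=1000.0,
                           n_periods=5),
}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    preset: str = "mini_fibril_7"
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset != "dimer" and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset '{self.preset}'; choose from "
                f"{['dimer', *PRESETS]}"
            )


def make_fixture(spec: FixtureSpec, seed: int = 0,
                 forcefield: ForceField | None = None,
                 strengthen_ends: bool = True) -> FibrilModel:
    """Build a preset model; deterministic (seed kept for API symmetry)."""
    ff = forcefield or default_forcefield()
    if spec.preset == "dimer":
        r = spec.overrides.get("r", ff.bonds["collagen"].r0)
        return two_particle_model(r, bond_type=BOND_COLLAGEN, forcefield=ff)
    kw = dict(PRESETS[spec.preset])
    kw.update(spec.overrides)
    layout = FibrilLayout(**kw)
    return build_fibril(layout, strengthen_ends=strengthen_ends, forcefield=ff)


def two_particle_model(r: float, bond_type: int = BOND_COLLAGEN,
                       forcefield: ForceField | None = None) -> FibrilModel:
    """Two bonded beads at separation r along x; oracle-sized fixture."""
    positions = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    pad = 200.0
    return FibrilModel(
        positions=positions,
        species=np.zeros(2, dtype=np.int64),
        mol_id=np.array([0, 0], dtype=np.int64),
        lane_id=np.zeros(2, dtype=np.int64),
        mol_index=np.array([0, 1], dtype=np.int64),
        bonds=np.array([[0, 1]], dtype=np.int64),
        bond_type=np.array([bond_type], dtype=np.int64),
        broken=np.zeros(1, dtype=np.uint8),
        break_step=np.full(1, -1, dtype=np.int64),
        angles=np.empty((0, 3), dtype=np.int64),
        phi0=np.empty(0),
        box=Box(lo=positions.min(0) - pad, hi=positions.max(0) + pad),
        gap_pairs=np.empty((0, 2), dtype=np.int64),
        grip_left=np.empty(0, dtype=np.int64),
        grip_right=np.empty(0, dtype=np.int64),
        meta=dict(D=670.0, lane_sites=[[0.0, 0.0]],
                  lateral_spacing=(forcefield or default_forcefield()).r0_col_pair,
                  gauge=[0.0, r], n_mol_particles=2,
                  age_stiffness_scale=1.0),
    )
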