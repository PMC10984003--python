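"""Random insertion of AGE cross-links between neighboring molecules.

Cross-links are breakable bonds with glucosepane-like parameters,
inserted *per molecule* to avoid local accumulation: each molecule owns
``n_age_per_tc`` links scaled by the fraction of its beads present in
the build window (molecules cut by the window carry a proportional
share), so the total is exactly ``n_age_per_tc`` times the number of
molecule strands per cross-section.  Anchors are restricted to the
central 95% helical region of each molecule; partners must belong to a
different, laterally neighboring molecule and lie within a candidate
cutoff (AGE rest length + 4 A by default).  The inserted bond's rest
length is the AGE equilibrium distance regardless of the instantaneous
anchor separation, so insertion injects essentially no energy (the
first-regime AGE stiffness is 0.1 kcal/mol/A^2).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .model import FibrilModel
from .parameters import BOND_AGE, SPECIES_COLLAGEN, ForceField, default_forcefield

__all__ = ["CrossLinkConfig", "insert_crosslinks"]


@dataclasses.dataclass(frozen=True)
class CrossLinkConfig:
    n_age_per_tc: int = 0
    helical_fraction: float = 0.95
    stiffness_scale: float = 1.0     # multiplier on the AGE second-regime k1
    max_pair_distance: float | None = None  # default AGE r0 + 4 A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_per_tc < 0:
            raise ValueError("n_age_per_tc must be >= 0")
        if not (0.0 < self.helical_fraction <= 1.0):
            raise ValueError("helical_fraction must be in (0, 1]")


def insert_crosslinks(
    model: FibrilModel,
    cfg: CrossLinkConfig,
    forcefield: ForceField | None = None,
) -> FibrilModel:
    """Return a copy of ``model`` with AGE bonds added.

    Raises a ``RuntimeError`` naming the first molecule for which the
    exact per-molecule count cannot be honored.
    """
    ff = forcefield or default_forcefield()
    out = model.copy()
    out.meta["age_stiffness_scale"] = float(cfg.stiffness_scale)
    out.meta["n_age_per_tc"] = int(cfg.n_age_per_tc)
    if cfg.n_age_per_tc == 0:
        return out

    cutoff = (cfg.max_pair_distance if cfg.max_pair_distance is not None
              else ff.bonds["age"].r0 + 4.0)
    n_mol_particles = int(model.meta.get("n_mol_particles", 218))
    margin = (1.0 - cfg.helical_fraction) / 2.0 * (n_mol_particles - 1)
    lo_idx = margin
    hi_idx = (n_mol_particles - 1) - margin

    central = (
        (model.species == SPECIES_COLLAGEN)
        & (model.mol_index >= lo_idx)
        & (model.mol_index <= hi_idx)
    )
    cand_ids = np.flatnonzero(central)
    pos = model.positions[cand_ids]
    box_l = model.box.lx if model.box.periodic_x else 0.0
    if box_l > 0.0:
        shift = pos - model.box.lo
        shift[:, 0] = np.mod(shift[:, 0], box_l)
        span_y = shift[:, 1].max() + 10 * cutoff
        span_z = shift[:, 2].max() + 10 * cutoff
        tree = cKDTree(shift, boxsize=(box_l, span_y, span_z))
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    gi = cand_ids[pairs[:, 0]]
    gj = cand_ids[pairs[:, 1]]
    diff = model.mol_id[gi] != model.mol_id[gj]
    gi, gj = gi[diff], gj[diff]

    # candidates per owner molecule: a pair (i, j) can serve either owner
    by_mol: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(gi, gj):
        by_mol.setdefault(int(model.mol_id[i]), []).append((int(i), int(j)))
        by_mol.setdefault(int(model.mol_id[j]), []).append((int(j), int(i)))

    # Per-molecule quotas proportional to the beads each molecule actually
    # contributes to the build window (molecules cut by the window own
    # only a fragment), so links never accumulate on short fragments.
    # Largest-remainder rounding keeps the total exactly
    # n_age_per_tc * (number of molecule strands per cross-section).
    mols = np.sort(np.unique(model.mol_id[model.mol_id >= 0]))
    beads = np.array([
        int(np.sum((model.mol_id == mol) & (model.species == SPECIES_COLLAGEN)))
        for mol in mols
    ])
    n_strands = beads.sum() / n_mol_particles
    total_target = int(round(cfg.n_age_per_tc * n_strands))
    raw = cfg.n_age_per_tc * beads / n_mol_particles
    quota = np.floor(raw).astype(int)
    remainder_order = np.argsort(-(raw - quota), kind="stable")
    for k in remainder_order[: total_target - quota.sum()]:
        quota[k] += 1

    rng = np.random.default_rng(cfg.seed)
    used: set[tuple[int, int]] = set()
    new_bonds = []
    for mol, want in zip(mols, quota):
        cands = by_mol.get(int(mol), [])
        order = rng.permutation(len(cands))
        taken = 0
        if want == 0:
            continue
        for k in order:
            i, j = cands[k]
            key = (min(i, j), max(i, j))
            if key in used:
                continue
            used.add(key)
            new_bonds.append(key)
            taken += 1
            if taken == want:
                break
        if taken < want:
            raise RuntimeError(
                f"molecule {mol}: only {taken} candidate pairs available, "
                f"need {want}; increase max_pair_distance or "
                f"lower n_age_per_tc"
            )
    if not new_bonds:
        return out

    nb = np.array(new_bonds, dtype=np.int64)
    out.bonds = np.vstack([out.bonds, nb])
    out.bond_type = np.concatenate(
        [out.bond_type, np.full(len(nb), BOND_AGE, dtype=np.int64)])
    out.broken = np.concatenate(
        [out.broken, np.zeros(len(nb), dtype=np.uint8)])
    out.break_step = np.concatenate(
        [out.break_step, np.full(len(nb), -1, dtype=np.int64)])
    return out
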