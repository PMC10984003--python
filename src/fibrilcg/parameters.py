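"""Force-field parameter containers and YAML loading.

The trilinear breakable bond, the harmonic angle and the soft-core
Lennard-Jones pair interactions are each described by a small frozen
dataclass.  A :class:`ForceField` bundles one spec per interaction class
and provides packed numpy parameter tables for the numba kernels.
"""
from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "BondSpec",
    "AngleSpec",
    "PairSpec",
    "ForceField",
    "load_forcefield",
    "default_forcefield",
]

# integer codes shared with model arrays and kernels
SPECIES_COLLAGEN = 0
SPECIES_END = 1
SPECIES_MINERAL = 2

BOND_COLLAGEN = 0
BOND_END = 1
BOND_AGE = 2

PAIR_COL_COL = 0
PAIR_HAP_HAP = 1
PAIR_COL_HAP = 2

#: species x species -> pair-type lookup (end particles pair like collagen)
PAIR_TABLE = np.array(
    [
        [PAIR_COL_COL, PAIR_COL_COL, PAIR_COL_HAP],
        [PAIR_COL_COL, PAIR_COL_COL, PAIR_COL_HAP],
        [PAIR_COL_HAP, PAIR_COL_HAP, PAIR_HAP_HAP],
    ],
    dtype=np.int64,
)


@dataclasses.dataclass(frozen=True)
class BondSpec:
    """Trilinear breakable spring.

    Force is piecewise linear in the particle distance r with a stiff
    second regime between ``r1`` and ``rbreak`` and a short
    regularization ramp of width ``a = z*(rbreak - r1)`` past the
    breaking distance, after which the bond is permanently broken.
    """

    r0: float
    r1: float
    rbreak: float
    k0: float
    k1: float
    z: float

    @property
    def a(self) -> float:
        """Regularization ramp width (A)."""
        return self.z * (self.rbreak - self.r1)

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.rbreak):
            raise ValueError(
                f"require r0 < r1 < rbreak, got {self.r0}, {self.r1}, {self.rbreak}"
            )
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("bond stiffnesses must be positive")

    def scaled(self, stiffness_scale: float) -> "BondSpec":
        """Return a copy with ``k1`` multiplied by ``stiffness_scale``."""
        return dataclasses.replace(self, k1=self.k1 * stiffness_scale)


@dataclasses.dataclass(frozen=True)
class AngleSpec:
    """Harmonic bending between particle triplets.

    Equilibrium angles ``phi0`` are per-triplet and recorded from the
    initial molecule geometry; only the stiffness lives here.
    """

    kb: float
    phi0_range: tuple[float, float] = (170.0, 180.0)

    def __post_init__(self) -> None:
        if self.kb <= 0:
            raise ValueError("angle stiffness must be positive")


@dataclasses.dataclass(frozen=True)
class PairSpec:
    """Soft-core Lennard-Jones nonbonded interaction.

    Below ``lam*sigma`` the force is capped at its value at
    ``lam*sigma`` (linear potential), which removes the LJ singularity;
    the potential is cut and shifted to zero at ``cutoff``.
    """

    epsilon: float
    sigma: float
    lam: float
    cutoff: float

    def __post_init__(self) -> None:
        if min(self.epsilon, self.sigma, self.cutoff) <= 0:
            raise ValueError("epsilon, sigma, cutoff must be positive")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("soft-core parameter lam must be in (0, 1)")

    @property
    def r_min(self) -> float:
        """Distance of the potential minimum, 2^(1/6)*sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma


@dataclasses.dataclass(frozen=True)
class ForceField:
    """Complete parameter set for the fibril model."""

    bonds: dict[str, BondSpec]
    angle: AngleSpec
    pairs: dict[str, PairSpec]
    masses: dict[str, float]

    _BOND_ORDER = ("collagen", "end", "age")
    _PAIR_ORDER = ("col_col", "hap_hap", "col_hap")

    def bond_table(self, age_stiffness_scale: float = 1.0) -> np.ndarray:
        """Packed (3, 7) table: r0, r1, rbreak, k0, k1, z, a per bond type."""
        rows = []
        for name in self._BOND_ORDER:
            s = self.bonds[name]
            if name == "age":
                s = s.scaled(age_stiffness_scale)
            rows.append([s.r0, s.r1, s.rbreak, s.k0, s.k1, s.z, s.a])
        return np.array(rows, dtype=np.float64)

    def pair_table(self) -> np.ndarray:
        """Packed (3, 5) table: epsilon, sigma, lam, cutoff, eshift."""
        rows = []
        for name in self._PAIR_ORDER:
            p = self.pairs[name]
            sr6 = (p.sigma / p.cutoff) ** 6
            eshift = 4.0 * p.epsilon * (sr6 * sr6 - sr6)
            rows.append([p.epsilon, p.sigma, p.lam, p.cutoff, eshift])
        return np.array(rows, dtype=np.float64)

    def mass_by_species(self) -> np.ndarray:
        m = self.masses
        return np.array([m["collagen"], m["collagen"], m["mineral"]])

    @property
    def max_cutoff(self) -> float:
        return max(p.cutoff for p in self.pairs.values())

    #: equilibrium spacing of mineral particles, 2^(1/6)*sigma_HAP
    @property
    def r0_hap(self) -> float:
        return self.pairs["hap_hap"].r_min

    #: equilibrium collagen-mineral distance, 2^(1/6)*sigma_col-HAP
    @property
    def r0_col_hap(self) -> float:
        return self.pairs["col_hap"].r_min

    #: default lateral spacing between molecule axes, 2^(1/6)*sigma_col
    @property
    def r0_col_pair(self) -> float:
        return self.pairs["col_col"].r_min


_BOND_KEYS = {"r0", "r1", "rbreak", "k0", "k1", "z"}
_PAIR_KEYS = {"epsilon", "sigma", "lam", "cutoff"}


def _check_keys(section: dict, expected: set[str], where: str) -> None:
    got = set(section)
    if got != expected:
        missing = expected - got
        extra = got - expected
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if extra:
            parts.append(f"unknown {sorted(extra)}")
        raise ValueError(f"forcefield section '{where}': " + ", ".join(parts))


def load_forcefield(path: str | Path | None = None) -> ForceField:
    """Load and validate a force-field parameter file (YAML).

    With ``path=None`` the packaged default table is used.
    """
    if path is None:
        text = (
            resources.files("fibrilcg").joinpath("data/forcefield_default.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    for top in ("bonds", "angle", "pairs", "masses"):
        if top not in raw:
            raise ValueError(f"forcefield file missing section '{top}'")
    bonds = {}
    for name in ("collagen", "end", "age"):
        if name not in raw["bonds"]:
            raise ValueError(f"forcefield bonds section missing '{name}'")
        _check_keys(raw["bonds"][name], _BOND_KEYS, f"bonds.{name}")
        bonds[name] = BondSpec(**raw["bonds"][name])
    pairs = {}
    for name in ("col_col", "hap_hap", "col_hap"):
        if name not in raw["pairs"]:
            raise ValueError(f"forcefield pairs section missing '{name}'")
        _check_keys(raw["pairs"][name], _PAIR_KEYS, f"pairs.{name}")
        pairs[name] = PairSpec(**raw["pairs"][name])
    ang = raw["angle"]
    angle = AngleSpec(kb=float(ang["kb"]), phi0_range=tuple(ang.get("phi0_range", (170.0, 180.0))))
    masses = {k: float(v) for k, v in raw["masses"].items()}
    for name in ("collagen", "mineral"):
        if name not in masses:
            raise ValueError(f"forcefield masses section missing '{name}'")
    return ForceField(bonds=bonds, angle=angle, pairs=pairs, masses=masses)


def default_forcefield() -> ForceField:
    """The packaged default parameter set."""
    return load_forcefield(None)
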