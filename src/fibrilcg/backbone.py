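"""Tropocollagen backbone traces.

A tropocollagen molecule is represented as an ordered bead chain with
exactly equal consecutive spacing (the bond equilibrium distance).  Two
generators are provided:

* :func:`generate_backbone` — straight chain along +x, optionally with a
  small sinusoidal perturbation in y.
* :func:`wavy_backbone` — chain marched along a sinusoid with *exact*
  chord spacing whose amplitude is root-found so that the chain's axial
  extent hits a prescribed span.  This reconciles the molecule's contour
  length (n-1 bonds at r0) with the shorter axial span demanded by the
  staggered D-period geometry, and produces equilibrium bend angles in
  the 170-180 degree range.

A user-supplied trace can be loaded from a plain-text coordinate table
with :func:`load_backbone`.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = ["BackboneTrace", "generate_backbone", "wavy_backbone", "load_backbone"]


@dataclasses.dataclass(frozen=True)
class BackboneTrace:
    """Ordered 3D bead positions (A) of one tropocollagen molecule.

    ``wave`` records (amplitude, wavelength) when the trace lies on the
    sinusoid y = amplitude*sin(2 pi x / wavelength); gap-zone mineral is
    then placed on the continuation of the same curve.  ``None`` for
    arbitrary/imported traces.
    """

    coordinates: np.ndarray  # (n, 3)
    wave: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError("backbone needs an (n>=2, 3) coordinate array")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]

    @property
    def spacings(self) -> np.ndarray:
        """Consecutive bead distances (A)."""
        d = np.diff(self.coordinates, axis=0)
        return np.sqrt((d * d).sum(axis=1))

    @property
    def axial_span(self) -> float:
        """Extent along x between first and last bead (A)."""
        return float(self.coordinates[-1, 0] - self.coordinates[0, 0])

    @property
    def contour_length(self) -> float:
        return float(self.spacings.sum())


def generate_backbone(
    n_particles: int,
    spacing: float,
    amplitude: float = 0.0,
    wavelength: float | None = None,
) -> BackboneTrace:
    """Equidistant idealized backbone along +x.

    With ``amplitude == 0`` (default) the chain is straight and its total
    length is exactly ``(n_particles - 1) * spacing``.  A nonzero
    amplitude superimposes ``y = amplitude * sin(2 pi x / wavelength)``
    with *chord* lengths kept exactly equal to ``spacing`` by marching
    along the curve.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if amplitude == 0.0:
        x = np.arange(n_particles, dtype=np.float64) * spacing
        coords = np.zeros((n_particles, 3))
        coords[:, 0] = x
        return BackboneTrace(coords)
    if wavelength is None or wavelength <= 0:
        raise ValueError("a positive wavelength is required with amplitude != 0")
    coords = _march_sinusoid(n_particles, spacing, amplitude, wavelength, x0=0.0)
    return BackboneTrace(coords, wave=(amplitude, wavelength))


def _march_sinusoid(
    n: int, spacing: float, amplitude: float, wavelength: float, x0: float
) -> np.ndarray:
    """Place n beads on y = A sin(2 pi x / L) with exact chord spacing."""
    k = 2.0 * np.pi / wavelength

    def y(x: float) -> float:
        return amplitude * np.sin(k * x)

    coords = np.zeros((n, 3))
    x = x0
    coords[0, 0] = x
    coords[0, 1] = y(x)
    for i in range(1, n):
        yi = coords[i - 1, 1]
        xi = coords[i - 1, 0]

        def chord(dx: float) -> float:
            return dx * dx + (y(xi + dx) - yi) ** 2 - spacing * spacing

        # dx is between spacing/sqrt(1+max_slope^2) and spacing
        lo = spacing / np.sqrt(1.0 + (amplitude * k) ** 2) * 0.5
        hi = spacing * 1.0000001
        dx = brentq(chord, lo, hi, xtol=1e-12)
        coords[i, 0] = xi + dx
        coords[i, 1] = y(xi + dx)
    return coords


def wavy_backbone(
    n_particles: int, spacing: float, axial_span: float, wavelength: float
) -> BackboneTrace:
    """Sinusoidal backbone with exact chords and a prescribed axial span.

    The amplitude is root-found so that the x-distance between the first
    and last bead equals ``axial_span``.  Requires
    ``axial_span < (n_particles - 1) * spacing`` (otherwise the chain is
    straight and :func:`generate_backbone` should be used).
    """
    contour = (n_particles - 1) * spacing
    if not (0 < axial_span <= contour):
        raise ValueError("axial_span must be in (0, contour length]")
    if axial_span == contour:
        return generate_backbone(n_particles, spacing)

    def span_err(amplitude: float) -> float:
        c = _march_sinusoid(n_particles, spacing, amplitude, wavelength, 0.0)
        return (c[-1, 0] - c[0, 0]) - axial_span

    # crude upper bracket: slope a gives contraction ~ 1/sqrt(1+a^2/2)
    hi = wavelength  # far more than enough
    amp = brentq(span_err, 1e-9, hi, xtol=1e-10)
    coords = _march_sinusoid(n_particles, spacing, amp, wavelength, 0.0)
    return BackboneTrace(coords, wave=(amp, wavelength))


def load_backbone(path: str | Path) -> BackboneTrace:
    """Read a plain-text coordinate table (x y z per line, comments '#')."""
    coords = np.loadtxt(path, comments="#", dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns x y z")
    return BackboneTrace(coords)
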