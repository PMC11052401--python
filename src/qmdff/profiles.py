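"""Tabulated torsional energy profiles and the cosine Fourier basis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import StructureError

__all__ = ["TorsionProfile", "fourier_eval", "fourier_design_matrix"]


def fourier_design_matrix(angles_deg: np.ndarray, order: int) -> np.ndarray:
    """Columns cos(j*delta), j = 0..order, for angles in degrees."""
    rad = np.asarray(angles_deg, dtype=float) * units.RAD_PER_DEG
    return np.cos(np.outer(rad, np.arange(order + 1)))


def fourier_eval(coeffs: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """V(delta) = sum_j c_j cos(j*delta) (kJ/mol) for angles in degrees."""
    coeffs = np.asarray(coeffs, dtype=float)
    return fourier_design_matrix(angles_deg, len(coeffs) - 1) @ coeffs


@dataclass
class TorsionProfile:
    """Relaxed-scan energies V(delta) on a grid of dihedral angles.

    ``energies`` are kJ/mol relative to the grid minimum (the constructor
    does not re-shift; scan generators normalize before building).  Scan
    geometries may be attached so residual-based torsion fits can evaluate
    the rest of the force field at the exact scan structures.
    """

    dihedral: tuple[int, int, int, int]
    angles_deg: np.ndarray
    energies: np.ndarray
    label: str = ""
    geometries: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles_deg.size == 0:
            raise StructureError("empty torsion profile")
        if self.angles_deg.shape != self.energies.shape:
            raise StructureError("angle and energy grids differ in length")
        if not np.all(np.diff(self.angles_deg) > 0):
            raise StructureError("profile grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.angles_deg.size

    def shifted_to_zero_minimum(self) -> "TorsionProfile":
        return TorsionProfile(self.dihedral, self.angles_deg.copy(),
                              self.energies - self.energies.min(),
                              self.label, self.geometries)
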