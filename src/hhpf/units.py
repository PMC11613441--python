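"""Reduced <-> molecular (SI-like) unit conversions.

Internally the simulator works in the GROMACS-style molecular unit set
(nm, ps, amu, kJ/mol), in which the energy unit is consistent:
1 kJ/mol = 1 amu nm^2 / ps^2.  Observables are commonly reported in
Lennard-Jones reduced units (starred quantities T*, rho*, u*, c_V*, r*),
obtained by scaling with a reference energy ``epsilon_ref``, length
``sigma_ref`` and mass ``mass_ref``.

The default reference scales are argon-like LJ parameters, chosen so that
a mesh spacing of 0.04 nm corresponds to a reduced spacing r* = 0.117.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant in kJ/(mol K) (molar convention; CODATA).
KB = 0.00831446261815324

_KINDS = ("length", "energy", "temperature", "time", "density", "specific_heat")


@dataclass(frozen=True)
class UnitSystem:
    """Reference scales defining the reduced-unit system.

    Parameters
    ----------
    epsilon_ref : float
        Reference energy in kJ/mol.
    sigma_ref : float
        Reference length in nm.
    mass_ref : float
        Reference mass in amu.
    """

    epsilon_ref: float = 0.996
    sigma_ref: float = 0.3405
    mass_ref: float = 39.948

    def __post_init__(self) -> None:
        if not (self.epsilon_ref > 0 and self.sigma_ref > 0 and self.mass_ref > 0):
            raise ValueError("all reference scales must be strictly positive")

    @property
    def tau(self) -> float:
        """Intrinsic time unit sigma * sqrt(mass / epsilon), in ps."""
        return self.sigma_ref * math.sqrt(self.mass_ref / self.epsilon_ref)

    def scale(self, kind: str) -> float:
        """Dimensioned value of one reduced unit of ``kind``."""
        if kind == "length":
            return self.sigma_ref
        if kind == "energy":
            return self.epsilon_ref
        if kind == "temperature":
            return self.epsilon_ref / KB
        if kind == "time":
            return self.tau
        if kind == "density":
            # number density: rho* = rho_nm^-3 * sigma_ref^3
            return self.sigma_ref ** -3
        if kind == "specific_heat":
            # per-particle heat capacity in kJ/(mol K); c_V* = c_V / k_B
            return KB
        raise ValueError(
            f"unknown quantity kind {kind!r}; expected one of {_KINDS}"
        )


def to_reduced(value, kind: str, units: UnitSystem = UnitSystem()):
    """Convert a dimensioned quantity (nm, kJ/mol, K, ps, nm^-3, kJ/mol/K)
    to its reduced counterpart."""
    return value / units.scale(kind)


def from_reduced(value, kind: str, units: UnitSystem = UnitSystem()):
    """Inverse of :func:`to_reduced`."""
    return value * units.scale(kind)
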