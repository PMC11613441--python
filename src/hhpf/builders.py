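"""Deterministic builders for simulation and test systems.

All builders take a reduced number density and a unit system; box edges
come from ``L* = (N / rho*)^(1/3)`` converted to nm.  Every random choice
flows from the supplied seed.
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import ParticleSystem
from .units import UnitSystem, from_reduced


def box_edge_for(n_particles: int, rho_star: float,
                 units: UnitSystem = UnitSystem()) -> float:
    """Cubic box edge (nm) holding ``n_particles`` at reduced density."""
    if rho_star <= 0:
        raise ValueError("rho_star must be positive")
    return from_reduced((n_particles / rho_star) ** (1.0 / 3.0), "length", units)


def build_uniform_system(n_particles: int, rho_star: float,
                         units: UnitSystem = UnitSystem(),
                         seed: int = 0) -> ParticleSystem:
    """Monatomic particles uniformly distributed in a cubic box."""
    rng = np.random.default_rng(seed)
    edge = box_edge_for(n_particles, rho_star, units)
    pos = rng.uniform(0.0, edge, (n_particles, 3))
    return ParticleSystem(
        pos, np.zeros((n_particles, 3)),
        np.full(n_particles, units.mass_ref), (edge, edge, edge),
    )


def build_two_bead_system(n_molecules: int, rho_star: float,
                          bond: tuple[float, float] = (0.25, 500.0),
                          units: UnitSystem = UnitSystem(),
                          seed: int = 0) -> ParticleSystem:
    """Bonded dimers at reduced *bead* density.

    Each molecule is two beads at separation ``r0`` in a uniformly random
    orientation around a uniformly random center. ``bond = (r0 [nm],
    k [kJ/mol/nm^2])``.
    """
    r0, k_bond = bond
    n_beads = 2 * n_molecules
    edge = box_edge_for(n_beads, rho_star, units)
    if r0 >= 0.5 * edge:
        raise ValueError("bond length r0 must be below half the box edge")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, edge, (n_molecules, 3))
    # isotropic orientations
    u = rng.normal(size=(n_molecules, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    pos = np.empty((n_beads, 3))
    pos[0::2] = centers - 0.5 * r0 * u
    pos[1::2] = centers + 0.5 * r0 * u
    mol = np.repeat(np.arange(n_molecules), 2)
    bonds = np.column_stack([np.arange(0, n_beads, 2),
                             np.arange(1, n_beads, 2)])
    return ParticleSystem(
        pos, np.zeros((n_beads, 3)), np.full(n_beads, units.mass_ref),
        (edge, edge, edge), molecule_of=mol, bonds=bonds,
        bond_r0=np.full(n_molecules, r0), bond_k=np.full(n_molecules, k_bond),
    )


def build_lattice_system(n_per_axis: int, rho_star: float,
                         units: UnitSystem = UnitSystem()) -> ParticleSystem:
    """Simple-cubic lattice (deterministic; handy for cold starts)."""
    n = n_per_axis ** 3
    edge = box_edge_for(n, rho_star, units)
    a = edge / n_per_axis
    grid = (np.stack(np.meshgrid(*[np.arange(n_per_axis)] * 3,
                                 indexing="ij"), axis=-1)
            .reshape(-1, 3) + 0.5) * a
    return ParticleSystem(grid, np.zeros((n, 3)),
                          np.full(n, units.mass_ref), (edge, edge, edge))


def build_two_particle_system(r: float, box_edge: float,
                              units: UnitSystem = UnitSystem()) -> ParticleSystem:
    """Two particles separated by r along x, centered in a cubic box."""
    c = 0.5 * box_edge
    pos = np.array([[c - 0.5 * r, c, c], [c + 0.5 * r, c, c]])
    return ParticleSystem(pos, np.zeros((2, 3)), np.full(2, units.mass_ref),
                          (box_edge, box_edge, box_edge))
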