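"""NVT molecular dynamics: velocity-Verlet, CSVR and Nosé-Hoover-chain
thermostats, harmonic bonds, and the run driver.

Units are molecular throughout (nm, ps, amu, kJ/mol); the kinetic energy
``sum m v^2 / 2`` is then directly in kJ/mol.  Temperature is defined from
equipartition with dof = 3N - 3 (net momentum removed and kept zero by
both thermostats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .units import KB, UnitSystem


# ---------------------------------------------------------------------------
# system container


@dataclass
class ParticleSystem:
    """Positions/velocities/masses plus molecular topology and periodic box.

    ``bonds`` is an (B, 2) integer array of particle indices with parallel
    arrays ``bond_r0`` (equilibrium lengths, nm) and ``bond_k`` (spring
    constants, kJ/mol/nm^2).  Bonded pairs must share a molecule index.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    box: tuple[float, float, float]
    molecule_of: np.ndarray | None = None
    bonds: np.ndarray | None = None
    bond_r0: np.ndarray | None = None
    bond_k: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.masses = np.asarray(self.masses, dtype=float)
        if self.n < 1:
            raise ValueError("need at least one particle")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.molecule_of is None:
            self.molecule_of = np.arange(self.n)
        if self.bonds is not None and len(self.bonds):
            self.bonds = np.asarray(self.bonds, dtype=np.int64)
            mol = self.molecule_of
            if np.any(mol[self.bonds[:, 0]] != mol[self.bonds[:, 1]]):
                raise ValueError("bonded pairs must belong to the same molecule")
        self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def dof(self) -> int:
        return 3 * self.n - 3

    def wrap(self) -> None:
        self.positions = np.mod(self.positions, np.asarray(self.box))

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities ** 2))

    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (max(self.dof, 1) * KB)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            self.box,
            None if self.molecule_of is None else self.molecule_of.copy(),
            None if self.bonds is None else self.bonds.copy(),
            None if self.bond_r0 is None else np.asarray(self.bond_r0).copy(),
            None if self.bond_k is None else np.asarray(self.bond_k).copy(),
        )


def maxwell_velocities(system: ParticleSystem, T: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann draw at temperature T with net momentum removed,
    rescaled to hit the target kinetic temperature exactly."""
    sigma = np.sqrt(KB * T / system.masses)[:, None]
    v = rng.standard_normal((system.n, 3)) * sigma
    p = (system.masses[:, None] * v).sum(axis=0)
    v -= p / system.masses.sum()
    ke = float(0.5 * np.sum(system.masses[:, None] * v ** 2))
    if ke > 0 and T > 0:
        v *= math.sqrt(0.5 * system.dof * KB * T / ke)
    return v


# ---------------------------------------------------------------------------
# bonded forces


def bonded_forces(system: ParticleSystem):
    """Harmonic bond energy 1/2 k (r - r0)^2 with minimum-image distances."""
    if system.bonds is None or len(system.bonds) == 0:
        return 0.0, np.zeros_like(system.positions)
    box = np.asarray(system.box)
    i, j = system.bonds[:, 0], system.bonds[:, 1]
    d = system.positions[i] - system.positions[j]
    d -= box * np.rint(d / box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise FloatingPointError("bonded pair at identical positions")
    k = np.asarray(system.bond_k, dtype=float)
    r0 = np.asarray(system.bond_r0, dtype=float)
    energy = float(0.5 * np.sum(k * (r - r0) ** 2))
    fmag = -k * (r - r0) / r
    fvec = fmag[:, None] * d
    forces = np.zeros_like(system.positions)
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return energy, forces


class CompositeForceProvider:
    """Nonbonded provider (field or pair engine) plus harmonic bonds."""

    def __init__(self, nonbonded):
        self.nonbonded = nonbonded

    def __call__(self, system):
        e_nb, f_nb = self.nonbonded.energy_forces(system)
        e_b, f_b = bonded_forces(system)
        return e_nb + e_b, f_nb + f_b


# ---------------------------------------------------------------------------
# integrator


def velocity_verlet_step(system: ParticleSystem, force_provider, dt: float,
                         forces: np.ndarray | None = None):
    """One kick-drift-kick step; returns (potential energy, new forces).

    ``forces`` are the forces at the current positions (recomputed when not
    supplied).  Positions are re-wrapped into the box after the drift.
    """
    if forces is None:
        _, forces = force_provider(system)
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError(
            f"non-finite force encountered; positions range "
            f"{system.positions.min()}..{system.positions.max()}"
        )
    inv_m = 1.0 / system.masses[:, None]
    system.velocities += 0.5 * dt * forces * inv_m
    system.positions += dt * system.velocities
    system.wrap()
    energy, new_forces = force_provider(system)
    system.velocities += 0.5 * dt * new_forces * inv_m
    return energy, new_forces


# ---------------------------------------------------------------------------
# thermostats


@dataclass(frozen=True)
class ThermostatSpec:
    """Thermostat selection: CSVR (stochastic velocity rescaling),
    Nosé-Hoover chains, or none.

    ``coupling`` is the relaxation/damping time in ps (0.1 ps CSVR /
    0.4 ps NHC by convention here); ``chain_length`` applies to NHC.
    """

    kind: str = "CSVR"
    T_target: float = 300.0
    coupling: float = 0.1
    chain_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("CSVR", "NHC", "none"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.kind != "none" and self.coupling <= 0:
            raise ValueError("coupling time must be positive")
        if self.kind == "NHC" and self.chain_length < 1:
            raise ValueError("NHC needs chain_length >= 1")


def csvr_step(velocities: np.ndarray, masses: np.ndarray, spec: ThermostatSpec,
              dof: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Canonical-sampling-through-velocity-rescaling update (one step).

    Rescales the kinetic energy toward the canonical distribution with
    relaxation time ``spec.coupling``; deterministic given the generator
    state; preserves net momentum (a pure global rescale).
    """
    ke = float(0.5 * np.sum(masses[:, None] * velocities ** 2))
    ke_target = 0.5 * dof * KB * spec.T_target
    if ke <= 0.0:
        if ke_target > 0.0:
            sigma = np.sqrt(KB * spec.T_target / masses)[:, None]
            v = rng.standard_normal(velocities.shape) * sigma
            p = (masses[:, None] * v).sum(axis=0)
            return v - p / masses.sum()
        return velocities
    c1 = math.exp(-dt / spec.coupling)
    r1 = rng.standard_normal()
    # sum of (dof-1) squared normals via the chi^2 distribution
    s = float(rng.chisquare(dof - 1)) if dof > 1 else 0.0
    ratio = ke_target / (dof * ke)
    alpha_sq = (
        c1
        + (1.0 - c1) * ratio * (r1 * r1 + s)
        + 2.0 * r1 * math.sqrt(c1 * (1.0 - c1) * ratio)
    )
    return velocities * math.sqrt(max(alpha_sq, 0.0))


class NoseHooverChain:
    """Deterministic Nosé-Hoover chain acting on the total kinetic energy.

    State: chain positions xi (for the conserved quantity) and momenta
    p_xi; masses Q1 = dof kB T tau^2, Qk = kB T tau^2.  The half-step
    update uses the standard Suzuki-Trotter split with a velocity-scale
    accumulator.
    """

    def __init__(self, spec: ThermostatSpec, dof: int):
        self.spec = spec
        self.dof = dof
        m = spec.chain_length
        tau2 = spec.coupling ** 2
        self.q = np.full(m, KB * spec.T_target * tau2)
        self.q[0] *= dof
        self.xi = np.zeros(m)
        self.p_xi = np.zeros(m)

    def half_step(self, velocities: np.ndarray, masses: np.ndarray,
                  dt: float) -> np.ndarray:
        """Advance the chain by dt/2 and rescale velocities in place."""
        m = self.spec.chain_length
        kbt = KB * self.spec.T_target
        ke2 = float(np.sum(masses[:, None] * velocities ** 2))  # 2*KE
        dt2, dt4, dt8 = 0.5 * dt, 0.25 * dt, 0.125 * dt
        g = np.zeros(m)
        g[m - 1] = ((self.p_xi[m - 2] ** 2 / self.q[m - 2] - kbt)
                    if m > 1 else 0.0)
        # update chain tail-to-head
        for k in range(m - 1, -1, -1):
            if k == 0:
                g[0] = ke2 - self.dof * kbt
            else:
                g[k] = self.p_xi[k - 1] ** 2 / self.q[k - 1] - kbt
            if k < m - 1:
                f = math.exp(-dt8 * self.p_xi[k + 1] / self.q[k + 1])
                self.p_xi[k] = self.p_xi[k] * f * f + dt4 * g[k] * f
            else:
                self.p_xi[k] += dt4 * g[k]
        scale = math.exp(-dt2 * self.p_xi[0] / self.q[0])
        velocities *= scale
        ke2 *= scale * scale
        self.xi += dt2 * self.p_xi / self.q
        # head-to-tail
        for k in range(m):
            if k == 0:
                g[0] = ke2 - self.dof * kbt
            else:
                g[k] = self.p_xi[k - 1] ** 2 / self.q[k - 1] - kbt
            if k < m - 1:
                f = math.exp(-dt8 * self.p_xi[k + 1] / self.q[k + 1])
                self.p_xi[k] = self.p_xi[k] * f * f + dt4 * g[k] * f
            else:
                self.p_xi[k] += dt4 * g[k]
        return velocities

    def energy(self) -> float:
        """Thermostat contribution to the extended conserved quantity."""
        kbt = KB * self.spec.T_target
        e = float(np.sum(self.p_xi ** 2 / (2.0 * self.q)))
        e += self.dof * kbt * self.xi[0]
        if self.spec.chain_length > 1:
            e += kbt * float(self.xi[1:].sum())
        return e


def nhc_step(velocities: np.ndarray, masses: np.ndarray, chain: NoseHooverChain,
             dt: float) -> np.ndarray:
    """Single half-step chain update (functional wrapper)."""
    return chain.half_step(velocities, masses, dt)


# ---------------------------------------------------------------------------
# run driver


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one NVT run."""

    engine: str  # "field" | "pair"
    dt: float  # ps
    n_steps: int
    n_equil: int = 0
    stride: int = 100
    seed: int = 0
    thermostat: ThermostatSpec = dc_field(default_factory=ThermostatSpec)
    traj_stride: int = 0  # 0: keep only equilibrated frames at `stride`
    units: UnitSystem = dc_field(default_factory=UnitSystem)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.engine not in ("field", "pair"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class RunResult:
    """Trajectory frames (production only) and the observable series."""

    frames: list[np.ndarray]
    observables: pd.DataFrame
    system: ParticleSystem
    conserved: Optional[pd.DataFrame] = None


def run_nvt(config: SimulationConfig, system: ParticleSystem, force_provider,
            log: Callable[[str], None] | None = None) -> RunResult:
    """NVT run: equilibration then production, observables at ``stride``.

    Fully reproducible given ``config.seed``: the same seed feeds the
    Maxwell velocity draw (only when the input velocities are all zero)
    and the CSVR noise stream.  Recorded per sample: step, instantaneous
    temperature, kinetic/potential/total energy per particle (kJ/mol).
    """
    rng = np.random.default_rng(config.seed)
    ts = config.thermostat
    if not np.any(system.velocities) and ts.kind != "none" and ts.T_target > 0:
        system.velocities = maxwell_velocities(system, ts.T_target, rng)
    chain = (NoseHooverChain(ts, system.dof) if ts.kind == "NHC" else None)

    energy, forces = force_provider(system)
    frames: list[np.ndarray] = []
    rows = []
    total = config.n_equil + config.n_steps

    def record(step, energy):
        ke = system.kinetic_energy()
        n = system.n
        rows.append(dict(
            step=step, T=system.temperature(),
            u_kinetic=ke / n, u_potential=energy / n,
            u_total=(ke + energy) / n,
        ))

    record(0, energy)
    if config.n_steps == 0 and config.n_equil == 0:
        frames.append(system.positions.copy())
        return RunResult(frames, pd.DataFrame(rows), system)

    for step in range(1, total + 1):
        if chain is not None:
            chain.half_step(system.velocities, system.masses, config.dt)
        energy, forces = velocity_verlet_step(system, force_provider,
                                              config.dt, forces)
        if chain is not None:
            chain.half_step(system.velocities, system.masses, config.dt)
        elif ts.kind == "CSVR":
            system.velocities = csvr_step(system.velocities, system.masses,
                                          ts, system.dof, config.dt, rng)
        if step % config.stride == 0 or step == total:
            record(step, energy)
            if step > config.n_equil:
                frames.append(system.positions.copy())
            if log is not None:
                log(f"step {step} T {system.temperature():.2f} "
                    f"U {energy:.4f}")
    obs = pd.DataFrame(rows)
    obs["production"] = obs["step"] > config.n_equil
    return RunResult(frames, obs, system)
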