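"""TOML run configuration.

Every block carrying physical quantities declares ``units = "reduced"`` or
``"si"`` explicitly, so a file can mix reduced state points with SI filter
parameters without silent misinterpretation.  ``load_config`` returns the
built system, force provider, and :class:`~hhpf.dynamics.SimulationConfig`.

Minimal example::

    [units]
    epsilon_ref = 0.996   # kJ/mol
    sigma_ref = 0.3405    # nm
    mass_ref = 39.948     # amu

    [system]
    kind = "uniform"      # or "two_bead"
    n = 500
    rho_star = 0.3
    seed = 11

    [run]
    engine = "pair"       # or "field"
    units = "si"
    dt = 0.01             # ps
    n_steps = 20000
    n_equil = 20000
    stride = 200
    seed = 42

    [thermostat]
    kind = "NHC"          # CSVR | NHC | none
    units = "reduced"
    T = 2.0               # T* (reduced) or K (si)
    coupling = 0.4        # always ps
    chain_length = 3

    [mgcm]
    units = "si"
    a = [29.288, -8.291]
    sigma = [0.208, 0.304]
    cutoff = 1.55

    # for engine = "field" instead of [mgcm]:
    # [field]
    # units = "si"
    # h = 0.04
    # coeff = 1.0
    # window = "tri-linear"
    # [filter]
    # units = "si"
    # a = [1.1486, -0.6882]
    # sigma = [0.1027, 0.2150]
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .builders import build_two_bead_system, build_uniform_system
from .dynamics import (CompositeForceProvider, ParticleSystem,
                       SimulationConfig, ThermostatSpec)
from .field import EnergyFunctionalParams, FieldForceProvider, Mesh
from .pair import NeighborScheme, PairForceProvider
from .potentials import GaussianFilterSpec, MGCMParams
from .units import UnitSystem, from_reduced


class ConfigError(ValueError):
    pass


def _units_mode(block: dict, name: str) -> str:
    mode = block.get("units")
    if mode not in ("reduced", "si"):
        raise ConfigError(
            f"block [{name}] must declare units = \"reduced\" or \"si\""
        )
    return mode


def _length(value: float, mode: str, us: UnitSystem) -> float:
    return from_reduced(value, "length", us) if mode == "reduced" else value


def _energy(value: float, mode: str, us: UnitSystem) -> float:
    return from_reduced(value, "energy", us) if mode == "reduced" else value


@dataclass
class LoadedRun:
    system: ParticleSystem
    force_provider: CompositeForceProvider
    sim_config: SimulationConfig
    units: UnitSystem
    rho_star: float
    raw: dict


def load_config(path, seed_override: int | None = None,
                engine_override: str | None = None) -> LoadedRun:
    raw = tomllib.loads(Path(path).read_text())
    ub = raw.get("units", {})
    us = UnitSystem(ub.get("epsilon_ref", 0.996), ub.get("sigma_ref", 0.3405),
                    ub.get("mass_ref", 39.948))

    sysb = raw.get("system")
    if sysb is None:
        raise ConfigError("missing [system] block")
    kind = sysb.get("kind", "uniform")
    rho_star = float(sysb["rho_star"])
    sys_seed = int(sysb.get("seed", 0))
    if kind == "uniform":
        system = build_uniform_system(int(sysb["n"]), rho_star, us, sys_seed)
    elif kind == "two_bead":
        bond = (float(sysb.get("bond_r0", 0.25)),
                float(sysb.get("bond_k", 500.0)))
        system = build_two_bead_system(int(sysb["n_molecules"]), rho_star,
                                       bond, us, sys_seed)
    else:
        raise ConfigError(f"unknown system kind {kind!r}")

    runb = raw.get("run")
    if runb is None:
        raise ConfigError("missing [run] block")
    rmode = _units_mode(runb, "run")
    dt = float(runb["dt"]) * (us.tau if rmode == "reduced" else 1.0)
    engine = engine_override or runb.get("engine", "pair")

    tb = raw.get("thermostat", {})
    if tb:
        tmode = _units_mode(tb, "thermostat")
        T = float(tb["T"])
        if tmode == "reduced":
            T = from_reduced(T, "temperature", us)
        thermostat = ThermostatSpec(
            tb.get("kind", "CSVR"), T, float(tb.get("coupling", 0.1)),
            int(tb.get("chain_length", 3)),
        )
    else:
        thermostat = ThermostatSpec("none", 0.0)

    if engine == "pair":
        mb = raw.get("mgcm")
        if mb is None:
            raise ConfigError("engine 'pair' needs an [mgcm] block")
        mmode = _units_mode(mb, "mgcm")
        terms = tuple(
            (_energy(a, mmode, us), _length(s, mmode, us))
            for a, s in zip(mb["a"], mb["sigma"])
        )
        params = MGCMParams(terms)
        cutoff = mb.get("cutoff")
        cutoff = (_length(float(cutoff), mmode, us) if cutoff is not None
                  else 5.0 * max(s for _, s in terms))
        nonbonded = PairForceProvider(params, NeighborScheme(cutoff))
    elif engine == "field":
        fb = raw.get("field")
        flb = raw.get("filter")
        if fb is None or flb is None:
            raise ConfigError("engine 'field' needs [field] and [filter] blocks")
        fmode = _units_mode(fb, "field")
        flmode = _units_mode(flb, "filter")
        h = _length(float(fb["h"]), fmode, us)
        filt = GaussianFilterSpec(tuple(
            (float(a), _length(s, flmode, us))
            for a, s in zip(flb["a"], flb["sigma"])
        ))
        func = EnergyFunctionalParams(
            coeff=float(fb.get("coeff", 1.0)), phi0=float(fb.get("phi0", 0.0)),
        )
        mesh = Mesh(system.box, h, fb.get("window", "tri-linear"))
        nonbonded = FieldForceProvider(mesh, filt, func)
    else:
        raise ConfigError(f"unknown engine {engine!r}")

    sim = SimulationConfig(
        engine=engine, dt=dt, n_steps=int(runb["n_steps"]),
        n_equil=int(runb.get("n_equil", 0)),
        stride=int(runb.get("stride", 100)),
        seed=seed_override if seed_override is not None
        else int(runb.get("seed", 0)),
        thermostat=thermostat, units=us,
    )
    return LoadedRun(system, CompositeForceProvider(nonbonded), sim, us,
                     rho_star, raw)
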