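import math

import numpy as np
import pytest
from scipy import stats

from hhpf.builders import build_uniform_system
from hhpf.dynamics import (
    CompositeForceProvider,
    NoseHooverChain,
    ParticleSystem,
    SimulationConfig,
    ThermostatSpec,
    bonded_forces,
    csvr_step,
    maxwell_velocities,
    run_nvt,
    velocity_verlet_step,
)
from hhpf.pair import NeighborScheme, PairForceProvider
from hhpf.potentials import ARGON_MGCM
from hhpf.units import KB

from conftest import make_gas


class ZeroForce:
    def __call__(self, system):
        return 0.0, np.zeros_like(system.positions)


def mgcm_provider(cutoff=1.6):
    return CompositeForceProvider(
        PairForceProvider(ARGON_MGCM, NeighborScheme(cutoff)))


class TestVelocityVerlet:
    def test_free_particle_drifts_linearly(self):
        sys_ = ParticleSystem([[1.0, 1.0, 1.0]], [[0.3, -0.1, 0.2]], [10.0],
                              (5.0, 5.0, 5.0))
        velocity_verlet_step(sys_, ZeroForce(), 0.5)
        np.testing.assert_allclose(sys_.positions[0],
                                   [1.15, 0.95, 1.1], rtol=1e-14)

    def test_harmonic_dimer_period(self):
        # mu = m/2; period = 2 pi sqrt(mu / k)
        m, k, r0 = 20.0, 400.0, 0.3
        period = 2 * math.pi * math.sqrt((m / 2) / k)
        dt = period / 200
        sys_ = ParticleSystem(
            [[2.0, 2.0, 2.0], [2.35, 2.0, 2.0]], np.zeros((2, 3)),
            [m, m], (4.0, 4.0, 4.0), molecule_of=np.zeros(2, dtype=int),
            bonds=[[0, 1]], bond_r0=[r0], bond_k=[k])

        class Bonds:
            def __call__(self, s):
                return bonded_forces(s)

        sep = []
        for _ in range(400):
            velocity_verlet_step(sys_, Bonds(), dt)
            sep.append(sys_.positions[1, 0] - sys_.positions[0, 0])
        sep = np.asarray(sep)
        # find the first return to maximum extension
        k_ret = np.argmax(sep[150:250]) + 150
        measured = (k_ret + 1) * dt
        assert measured == pytest.approx(period, rel=1e-3)

    def test_nve_energy_conservation_mgcm_gas(self):
        sys_ = make_gas(64, 4.0, seed=5)
        rng = np.random.default_rng(0)
        sys_.velocities = maxwell_velocities(sys_, 150.0, rng)
        prov = mgcm_provider()
        e, f = prov(sys_)
        e0 = e + sys_.kinetic_energy()
        for _ in range(2000):
            e, f = velocity_verlet_step(sys_, prov, 0.004, f)
        e1 = e + sys_.kinetic_energy()
        assert abs(e1 - e0) <= 1e-4 * abs(e0)

    def test_nonfinite_force_aborts(self):
        class BadForce:
            def __call__(self, s):
                return 0.0, np.full_like(s.positions, np.nan)

        sys_ = make_gas(4, 3.0, seed=0)
        with pytest.raises(FloatingPointError):
            velocity_verlet_step(sys_, BadForce(), 0.01)


class TestCSVR:
    def test_fixed_point_no_noise_limit(self):
        sys_ = make_gas(32, 4.0, seed=1)
        rng = np.random.default_rng(3)
        sys_.velocities = maxwell_velocities(sys_, 100.0, rng)
        spec = ThermostatSpec("CSVR", sys_.temperature(), coupling=1e12)
        v = csvr_step(sys_.velocities.copy(), sys_.masses, spec, sys_.dof,
                      0.004, np.random.default_rng(0))
        np.testing.assert_allclose(v, sys_.velocities, rtol=1e-5)

    def test_ideal_gas_reaches_target_temperature(self):
        sys_ = make_gas(64, 4.0, seed=2)
        rng = np.random.default_rng(4)
        sys_.velocities = maxwell_velocities(sys_, 50.0, rng)
        spec = ThermostatSpec("CSVR", 120.0, coupling=0.1)
        ts = []
        for i in range(30000):
            sys_.velocities = csvr_step(sys_.velocities, sys_.masses, spec,
                                        sys_.dof, 0.004, rng)
            if i > 3000 and i % 20 == 0:
                ts.append(sys_.temperature())
        assert np.mean(ts) == pytest.approx(120.0, rel=0.02)

    def test_kinetic_energy_is_gamma_distributed(self):
        sys_ = make_gas(64, 4.0, seed=3)
        rng = np.random.default_rng(5)
        sys_.velocities = maxwell_velocities(sys_, 120.0, rng)
        spec = ThermostatSpec("CSVR", 120.0, coupling=0.1)
        kes = []
        for i in range(50000):
            sys_.velocities = csvr_step(sys_.velocities, sys_.masses, spec,
                                        sys_.dof, 0.004, rng)
            if i > 2000 and i % 25 == 0:
                kes.append(sys_.kinetic_energy())
        ks = stats.kstest(np.asarray(kes),
                          stats.gamma(a=sys_.dof / 2, scale=KB * 120.0).cdf)
        assert ks.pvalue > 0.01

    def test_momentum_preserved(self):
        sys_ = make_gas(16, 4.0, seed=6)
        rng = np.random.default_rng(6)
        sys_.velocities = maxwell_velocities(sys_, 90.0, rng)
        p0 = (sys_.masses[:, None] * sys_.velocities).sum(axis=0)
        spec = ThermostatSpec("CSVR", 150.0, coupling=0.05)
        v = csvr_step(sys_.velocities, sys_.masses, spec, sys_.dof, 0.01, rng)
        p1 = (sys_.masses[:, None] * v).sum(axis=0)
        np.testing.assert_allclose(p1, p0, atol=1e-10)

    def test_zero_kinetic_energy_reseeds(self):
        sys_ = make_gas(16, 4.0, seed=7)
        spec = ThermostatSpec("CSVR", 100.0, coupling=0.1)
        v = csvr_step(np.zeros_like(sys_.velocities), sys_.masses, spec,
                      sys_.dof, 0.01, np.random.default_rng(1))
        assert 0.5 * np.sum(sys_.masses[:, None] * v ** 2) > 0


class TestNHC:
    def test_stationary_chain_at_target(self):
        sys_ = make_gas(32, 4.0, seed=8)
        rng = np.random.default_rng(8)
        sys_.velocities = maxwell_velocities(sys_, 150.0, rng)
        spec = ThermostatSpec("NHC", 150.0, coupling=0.4, chain_length=3)
        chain = NoseHooverChain(spec, sys_.dof)
        v0 = sys_.velocities.copy()
        chain.half_step(sys_.velocities, sys_.masses, 0.004)
        # at the fixed point (T = T_target, zero chain momenta) velocities
        # are rescaled only at second order in dt
        np.testing.assert_allclose(sys_.velocities, v0, rtol=5e-5)

    def test_holds_target_temperature_mgcm(self):
        sys_ = make_gas(64, 4.0, seed=9)
        rng = np.random.default_rng(9)
        sys_.velocities = maxwell_velocities(sys_, 150.0, rng)
        prov = mgcm_provider()
        spec = ThermostatSpec("NHC", 150.0, coupling=0.4, chain_length=3)
        chain = NoseHooverChain(spec, sys_.dof)
        e, f = prov(sys_)
        ts = []
        for i in range(20000):
            chain.half_step(sys_.velocities, sys_.masses, 0.004)
            e, f = velocity_verlet_step(sys_, prov, 0.004, f)
            chain.half_step(sys_.velocities, sys_.masses, 0.004)
            if i > 4000 and i % 20 == 0:
                ts.append(sys_.temperature())
        assert np.mean(ts) == pytest.approx(150.0, rel=0.02)

    def test_extended_conserved_quantity(self):
        sys_ = make_gas(64, 4.0, seed=10)
        rng = np.random.default_rng(10)
        sys_.velocities = maxwell_velocities(sys_, 150.0, rng)
        prov = mgcm_provider()
        spec = ThermostatSpec("NHC", 150.0, coupling=0.4, chain_length=3)
        chain = NoseHooverChain(spec, sys_.dof)
        e, f = prov(sys_)
        c0 = None
        drift = 0.0
        for i in range(10000):
            chain.half_step(sys_.velocities, sys_.masses, 0.004)
            e, f = velocity_verlet_step(sys_, prov, 0.004, f)
            chain.half_step(sys_.velocities, sys_.masses, 0.004)
            c = e + sys_.kinetic_energy() + chain.energy()
            c0 = c if c0 is None else c0
            drift = max(drift, abs(c - c0))
        assert drift <= 1e-4 * abs(c0)


class TestBondedForces:
    def test_zero_at_equilibrium(self):
        sys_ = ParticleSystem([[1.0, 1.0, 1.0], [1.25, 1.0, 1.0]],
                              np.zeros((2, 3)), [40.0, 40.0], (3.0, 3.0, 3.0),
                              molecule_of=np.zeros(2, dtype=int),
                              bonds=[[0, 1]], bond_r0=[0.25], bond_k=[500.0])
        e, f = bonded_forces(sys_)
        assert e == 0.0
        np.testing.assert_allclose(f, 0.0)

    def test_hookes_law(self):
        d = 0.04
        sys_ = ParticleSystem([[1.0, 1.0, 1.0], [1.29, 1.0, 1.0]],
                              np.zeros((2, 3)), [40.0, 40.0], (3.0, 3.0, 3.0),
                              molecule_of=np.zeros(2, dtype=int),
                              bonds=[[0, 1]], bond_r0=[0.25], bond_k=[500.0])
        e, f = bonded_forces(sys_)
        assert e == pytest.approx(0.5 * 500.0 * d * d)
        np.testing.assert_allclose(f[0], [500.0 * d, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f[1], [-500.0 * d, 0, 0], atol=1e-12)

    def test_minimum_image_bond_across_boundary(self):
        # same geometry, one image-wrapped: energies must agree
        plain = ParticleSystem([[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]],
                               np.zeros((2, 3)), [40.0, 40.0],
                               (3.0, 3.0, 3.0),
                               molecule_of=np.zeros(2, dtype=int),
                               bonds=[[0, 1]], bond_r0=[0.25], bond_k=[500.0])
        wrapped = ParticleSystem([[2.9, 1.0, 1.0], [0.2, 1.0, 1.0]],
                                 np.zeros((2, 3)), [40.0, 40.0],
                                 (3.0, 3.0, 3.0),
                                 molecule_of=np.zeros(2, dtype=int),
                                 bonds=[[0, 1]], bond_r0=[0.25],
                                 bond_k=[500.0])
        e1, _ = bonded_forces(plain)
        e2, _ = bonded_forces(wrapped)
        assert e1 == pytest.approx(e2, rel=1e-14)

    def test_coincident_bonded_pair_is_singular(self):
        sys_ = ParticleSystem([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                              np.zeros((2, 3)), [40.0, 40.0], (3.0, 3.0, 3.0),
                              molecule_of=np.zeros(2, dtype=int),
                              bonds=[[0, 1]], bond_r0=[0.25], bond_k=[500.0])
        with pytest.raises(FloatingPointError):
            bonded_forces(sys_)

    def test_cross_molecule_bond_rejected(self):
        with pytest.raises(ValueError, match="molecule"):
            ParticleSystem([[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]],
                           np.zeros((2, 3)), [40.0, 40.0], (3.0, 3.0, 3.0),
                           molecule_of=np.array([0, 1]),
                           bonds=[[0, 1]], bond_r0=[0.25], bond_k=[500.0])


class TestRunDriver:
    def test_zero_steps_returns_initial_frame(self):
        sys_ = make_gas(8, 4.0, seed=11)
        cfg = SimulationConfig("pair", dt=0.01, n_steps=0,
                               thermostat=ThermostatSpec("none", 0.0))
        res = run_nvt(cfg, sys_, mgcm_provider())
        assert len(res.frames) == 1
        np.testing.assert_allclose(res.frames[0], sys_.positions)

    def test_bit_identical_reruns_with_same_seed(self):
        cfg = SimulationConfig("pair", dt=0.01, n_steps=300, n_equil=100,
                               stride=50, seed=77,
                               thermostat=ThermostatSpec("CSVR", 150.0, 0.1))
        a = run_nvt(cfg, build_uniform_system(256, 0.3, seed=1),
                    mgcm_provider(1.55))
        b = run_nvt(cfg, build_uniform_system(256, 0.3, seed=1),
                    mgcm_provider(1.55))
        assert a.observables.equals(b.observables)
        np.testing.assert_array_equal(a.frames[-1], b.frames[-1])

    def test_ideal_gas_equipartition(self):
        # interactions off: mean reduced total energy per particle = 1.5 T*
        sys_ = make_gas(128, 6.0, seed=12)
        cfg = SimulationConfig(
            "pair", dt=0.01, n_steps=20000, n_equil=2000, stride=20, seed=3,
            thermostat=ThermostatSpec("CSVR", 119.79653, 0.1))  # T* = 1
        res = run_nvt(cfg, sys_, ZeroForce())
        prod = res.observables[res.observables["production"]]
        u_star = prod["u_total"].mean() / 0.996
        assert u_star == pytest.approx(1.5, rel=0.02)
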