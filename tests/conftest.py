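import numpy as np
import pytest

from hhpf.dynamics import ParticleSystem
from hhpf.potentials import ARGON_MGCM, TWO_GAUSSIAN_FILTER, GaussianFilterSpec
from hhpf.units import UnitSystem


@pytest.fixture(scope="session")
def units():
    return UnitSystem()


@pytest.fixture(scope="session")
def argon_params():
    return ARGON_MGCM


@pytest.fixture(scope="session")
def two_gauss_filter():
    return TWO_GAUSSIAN_FILTER


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gas(n, box_edge, seed=0, mass=39.948, temp_sigma=0.0):
    """Uniform random gas in a cubic box, optionally with random velocities."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, (n, 3))
    vel = temp_sigma * rng.standard_normal((n, 3))
    return ParticleSystem(pos, vel, np.full(n, mass),
                          (box_edge, box_edge, box_edge))


@pytest.fixture
def random_filter_factory():
    def make(seed):
        r = np.random.default_rng(seed)
        return GaussianFilterSpec(
            ((float(r.uniform(0.5, 1.5)), float(r.uniform(0.08, 0.15))),
             (float(r.uniform(-0.9, -0.2)), float(r.uniform(0.18, 0.3)))),
        )
    return make
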