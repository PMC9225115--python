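import numpy as np
import pytest

from t1rhomap.containers import AcquisitionProtocol
from t1rhomap.operators import make_encoding
from t1rhomap.phantom import PhantomSpec, make_phantom_maps
from t1rhomap.sampling import (cartesian_schedule, golden_angle_schedule,
                               nyquist_spoke_count, radial_subsample)
from t1rhomap.simulate import simulate_kspace

TSL_SMALL = np.array([0.0, 8.0, 16.0, 32.0, 64.0])


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(matrix_size=48, base_size=32)


@pytest.fixture(scope="session")
def small_maps(small_spec):
    return make_phantom_maps(small_spec)


@pytest.fixture(scope="session")
def cart_full(small_maps):
    """Noiseless fully sampled cartesian acquisition of the small phantom."""
    schedule = cartesian_schedule(48, 1.0, TSL_SMALL.size, seed=0)
    protocol = AcquisitionProtocol(tsl=TSL_SMALL, matrix_size=48,
                                   scheme="cartesian", af=1.0)
    encoding = make_encoding(schedule)
    data = simulate_kspace(small_maps, protocol, schedule,
                           noise_fraction=0.0, seed=0, encoding=encoding)
    return data, encoding


@pytest.fixture(scope="session")
def radial_small(small_maps):
    """Noisy AF-10 radial acquisition of the small phantom."""
    base = golden_angle_schedule(nyquist_spoke_count(48), 48)
    schedule = radial_subsample(base, 10.0, TSL_SMALL.size)
    protocol = AcquisitionProtocol(tsl=TSL_SMALL, matrix_size=48,
                                   scheme="radial", af=10.0)
    encoding = make_encoding(schedule)
    data = simulate_kspace(small_maps, protocol, schedule,
                           noise_fraction=0.05, seed=1, encoding=encoding)
    return data, encoding


@pytest.fixture(scope="session")
def support(small_maps):
    return small_maps.s0 > 1e-3
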