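"""Noisy multi-contrast k-space simulation from known parameter maps.

Complex Gaussian noise is calibrated relative to the signal: the total
complex standard deviation equals ``noise_fraction`` times the mean
magnitude of the noiseless samples (real and imaginary components are
independent with std sigma/sqrt(2) each).
"""

from __future__ import annotations

import numpy as np

from .containers import (AcquisitionProtocol, KSpaceData, ParameterMaps,
                         SamplingSchedule)
from .operators import ForwardModel, _EncodingBase, make_encoding

__all__ = ["simulate_kspace", "simulate_radial_phantom_kspace"]


def simulate_kspace(maps: ParameterMaps, protocol: AcquisitionProtocol,
                    schedule: SamplingSchedule, noise_fraction: float = 0.0,
                    seed: int = 0,
                    encoding: _EncodingBase | None = None) -> KSpaceData:
    """Apply the forward model to true maps and add calibrated complex noise.

    ``noise_fraction = 0`` returns exactly the noiseless samples.  Identical
    seeds give bit-identical noise.
    """
    if maps.shape != (protocol.matrix_size, protocol.matrix_size):
        raise ValueError("maps inconsistent with protocol matrix size")
    if schedule.n_contrasts != protocol.n_contrasts:
        raise ValueError("schedule inconsistent with protocol contrasts")
    if encoding is None:
        encoding = make_encoding(schedule)
    model = ForwardModel(encoding, protocol.tsl)
    noiseless = model(maps)
    sigma = 0.0
    samples = noiseless
    if noise_fraction > 0:
        sigma = noise_fraction * np.mean(np.abs(noiseless))
        rng = np.random.default_rng(seed)
        noise = (rng.standard_normal(noiseless.shape)
                 + 1j * rng.standard_normal(noiseless.shape)) * (sigma / np.sqrt(2))
        samples = noiseless + noise
    return KSpaceData(samples=samples, schedule=schedule, protocol=protocol,
                      noise_sigma=float(sigma), noise_fraction=noise_fraction,
                      seed=seed)


def simulate_radial_phantom_kspace(spec=None, tsl=None, af: float = 1.0,
                                   noise_fraction: float = 0.05,
                                   seed: int = 0,
                                   encoding_cache: dict | None = None):
    """One-call phantom experiment input: maps + radial k-space at a given AF.

    Defaults follow the simulated study conditions: 192 matrix, spin-lock
    times 0, 4, 8, 16, 32, 64, 128 ms, ~N*pi/2 golden-angle spokes at full
    sampling, 5% complex noise.  Returns ``(maps, data, encoding)``.
    """
    from .phantom import PhantomSpec, make_phantom_maps
    from .sampling import (golden_angle_schedule, nyquist_spoke_count,
                           radial_subsample)

    spec = spec or PhantomSpec()
    tsl = np.asarray([0.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0]
                     if tsl is None else tsl, dtype=float)
    maps = make_phantom_maps(spec)
    n = spec.matrix_size
    base = golden_angle_schedule(nyquist_spoke_count(n), n)
    schedule = radial_subsample(base, af, len(tsl))
    protocol = AcquisitionProtocol(tsl=tsl, matrix_size=n, scheme="radial",
                                   af=af)
    key = tuple(tuple(map(int, b)) for b in schedule.spoke_indices)
    if encoding_cache is not None and key in encoding_cache:
        encoding = encoding_cache[key]
    else:
        encoding = make_encoding(schedule)
        if encoding_cache is not None:
            encoding_cache[key] = encoding
    data = simulate_kspace(maps, protocol, schedule, noise_fraction, seed,
                           encoding=encoding)
    return maps, data, encoding
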