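"""Shepp–Logan-style numerical phantom with known T1rho, S0 and phase maps.

The phantom provides structured ground truth for parameter-recovery
experiments: the classic head-phantom ellipses define the S0 intensity,
each ellipse carries its own constant T1rho, and the phase is a linear
ramp along the horizontal axis.  The phantom is rasterised at
``base_size`` pixels and centred in a zero-padded ``matrix_size`` grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ParameterMaps

__all__ = ["PhantomSpec", "make_phantom_maps", "SHEPP_LOGAN_ELLIPSES"]

# Modified Shepp–Logan ellipse table: (intensity, a, b, x0, y0, phi_deg).
# Axes and centres are in the [-1, 1] square; intensities are additive.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass
class PhantomSpec:
    """Geometry and parameter ranges of the synthetic target.

    Defaults follow the simulated radial study conditions: a 128-pixel
    phantom zero-filled to a 192 grid, T1rho between 20 and 120 ms, peak
    S0 of 1 and a phase ramp of one full cycle across the matrix.
    """

    matrix_size: int = 192
    base_size: int = 128
    t1rho_range: tuple[float, float] = (20.0, 120.0)
    s0_max: float = 1.0
    phase_slope: float | None = None  # radians per pixel column

    def __post_init__(self) -> None:
        if self.base_size > self.matrix_size:
            raise ValueError("base_size must not exceed matrix_size")
        lo, hi = self.t1rho_range
        if not (0 < lo < hi):
            raise ValueError("t1rho_range must be positive and increasing")
        if self.s0_max < 0:
            raise ValueError("s0_max must be non-negative")
        if self.phase_slope is None:
            self.phase_slope = 2.0 * np.pi / self.matrix_size


def _ellipse_masks(base_size: int) -> list[np.ndarray]:
    """Boolean inside-masks of the phantom ellipses on the base grid."""
    # pixel centres mapped to [-1, 1]; y axis points up as in the classic table
    coords = (np.arange(base_size) - (base_size - 1) / 2) / (base_size / 2)
    x, y = np.meshgrid(coords, -coords)
    masks = []
    for _, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        masks.append((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return masks


def make_phantom_maps(spec: PhantomSpec | None = None) -> ParameterMaps:
    """Build ground-truth S0, T1rho and phase maps from a phantom spec.

    S0 is the additive ellipse-intensity image rescaled so its maximum is
    ``spec.s0_max`` (zero background).  T1rho is piecewise constant: each
    ellipse, applied in table order so later ellipses overwrite earlier
    ones, receives a distinct value evenly spaced over ``t1rho_range``;
    pixels outside the phantom carry the lower bound (irrelevant where
    S0 = 0).  The phase is ``phase_slope * x`` over the full matrix, with
    ``x`` the 0-based pixel column.
    """
    spec = spec or PhantomSpec()
    masks = _ellipse_masks(spec.base_size)

    s0_base = np.zeros((spec.base_size, spec.base_size))
    for (intensity, *_), mask in zip(SHEPP_LOGAN_ELLIPSES, masks):
        s0_base[mask] += intensity
    s0_base = np.clip(s0_base, 0.0, None)
    if s0_base.max() > 0 and spec.s0_max > 0:
        s0_base *= spec.s0_max / s0_base.max()
    else:
        s0_base[:] = 0.0

    lo, hi = spec.t1rho_range
    values = np.linspace(lo, hi, len(masks))
    t1_base = np.full((spec.base_size, spec.base_size), lo)
    for value, mask in zip(values, masks):
        t1_base[mask] = value

    n, b = spec.matrix_size, spec.base_size
    off = (n - b) // 2
    s0 = np.zeros((n, n))
    t1rho = np.full((n, n), lo)
    s0[off:off + b, off:off + b] = s0_base
    t1rho[off:off + b, off:off + b] = t1_base

    cols = np.arange(n, dtype=float)
    phase = np.broadcast_to(spec.phase_slope * cols, (n, n)).copy()
    return ParameterMaps(s0=s0, t1rho=t1rho, phase=phase)
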