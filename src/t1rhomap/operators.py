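"""Forward operators of the spin-lock signal model and their adjoints.

The measurement model is ``m = K(S0, T1rho, theta) + e`` with
``K = A o B o D``:

* ``D`` maps the parameter maps to per-contrast magnitude images
  ``r_c = S0 * exp(-TSL_c / T1rho)`` (the phase passes through),
* ``B`` embeds magnitude and phase into complex images ``r_c * exp(i*theta)``,
* ``A`` is the block-diagonal Fourier encoding: undersampled centred FFT
  for cartesian rows, Kaiser–Bessel NUFFT for radial trajectories, with a
  global constant chosen so the block-diagonal operator has unit norm.

The Jacobian of ``B o D`` is diagonal per pixel, which is what makes the
embedded reconstruction's per-block step sizes cheap to compute.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from .containers import KSpaceData, ParameterMaps, SamplingSchedule
from .nufft import NUFFT2D

__all__ = [
    "decay_images",
    "phase_embed",
    "contrast_images",
    "CartesianEncoding",
    "RadialEncoding",
    "make_encoding",
    "ForwardModel",
    "spatial_grad",
    "spatial_grad_adjoint",
    "contrast_diff1",
    "contrast_diff1_adjoint",
    "contrast_diff2",
    "contrast_diff2_adjoint",
    "power_iteration_norm",
]


# ---------------------------------------------------------------------------
# Signal model


def decay_images(maps: ParameterMaps, tsl: np.ndarray) -> np.ndarray:
    """Magnitude images r_c = S0 * exp(-TSL_c / T1rho), shape (C, ny, nx)."""
    tsl = np.asarray(tsl, dtype=float)
    if np.any(maps.t1rho <= 0):
        raise ValueError("t1rho must be strictly positive")
    return maps.s0[None] * np.exp(-tsl[:, None, None] / maps.t1rho[None])


def phase_embed(magnitudes: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Complex images r_c * exp(i*theta); real part r*cos(theta), imaginary
    part r*sin(theta)."""
    return magnitudes * np.exp(1j * phase)[None] if magnitudes.ndim == 3 \
        else magnitudes * np.exp(1j * phase)


def contrast_images(maps: ParameterMaps, tsl: np.ndarray) -> np.ndarray:
    """Complex per-contrast images of the signal model, (C, ny, nx)."""
    return phase_embed(decay_images(maps, tsl), maps.phase)


# ---------------------------------------------------------------------------
# Encodings


def _fft2c(image: np.ndarray) -> np.ndarray:
    """Centred unitary 2-D DFT."""
    n = image.shape[-1]
    return fftshift(fft2(ifftshift(image, axes=(-2, -1)),
                         norm="ortho"), axes=(-2, -1))


def _ifft2c(spectrum: np.ndarray) -> np.ndarray:
    return fftshift(ifft2(ifftshift(spectrum, axes=(-2, -1)),
                          norm="ortho"), axes=(-2, -1))


def power_iteration_norm(forward, adjoint, shape, n_iter: int = 30,
                         tol: float = 1e-6, seed: int = 0,
                         v0: np.ndarray | None = None) -> float:
    """Operator-norm estimate of a linear map given forward/adjoint callables."""
    rng = np.random.default_rng(seed)
    v = v0 if v0 is not None else (rng.standard_normal(shape)
                                   + 1j * rng.standard_normal(shape))
    norm = 0.0
    for _ in range(n_iter):
        w = adjoint(forward(v))
        new_norm = np.sqrt(np.vdot(w, w).real)
        if new_norm == 0:
            return 0.0
        v = w / new_norm
        if norm and abs(np.sqrt(new_norm) - np.sqrt(norm)) \
                <= tol * np.sqrt(norm):
            norm = new_norm
            break
        norm = new_norm
    return float(np.sqrt(norm))


class _EncodingBase:
    """Common interface: normalized per-contrast Fourier sampling blocks."""

    n: int
    n_contrasts: int
    n_samples: int
    norm_const: float

    def _forward_block(self, image: np.ndarray, c: int) -> np.ndarray:
        raise NotImplementedError

    def _adjoint_block(self, samples: np.ndarray, c: int) -> np.ndarray:
        raise NotImplementedError

    def _calibrate(self) -> None:
        """Estimate the block-diagonal operator norm (power iteration)."""
        self.norm_const = 1.0

        def fwd(v):
            return self.forward(v)

        def adj(v):
            return self.adjoint(v)

        self.norm_const = power_iteration_norm(
            fwd, adj, (self.n_contrasts, self.n, self.n))

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Apply the normalized encoding A to (C, ny, nx) images -> (C, M)."""
        images = np.asarray(images, dtype=complex)
        if images.shape != (self.n_contrasts, self.n, self.n):
            raise ValueError("image stack shape mismatch")
        out = np.empty((self.n_contrasts, self.n_samples), dtype=complex)
        for c in range(self.n_contrasts):
            out[c] = self._forward_block(images[c], c)
        return out / self.norm_const

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Apply A^H to (C, M) samples -> (C, ny, nx) images."""
        samples = np.asarray(samples, dtype=complex)
        out = np.empty((self.n_contrasts, self.n, self.n), dtype=complex)
        for c in range(self.n_contrasts):
            out[c] = self._adjoint_block(samples[c], c)
        return out / self.norm_const

    def initial_image(self, samples_c: np.ndarray, c: int) -> np.ndarray:
        """Approximate single-contrast inverse used to initialize solvers."""
        raise NotImplementedError


class CartesianEncoding(_EncodingBase):
    """Per-contrast undersampled centred unitary FFT: A_c = U_c F."""

    def __init__(self, schedule: SamplingSchedule) -> None:
        if schedule.scheme != "cartesian":
            raise ValueError("cartesian schedule required")
        self.schedule = schedule
        self.n = schedule.matrix_size
        self.n_contrasts = schedule.n_contrasts
        self.rows = [np.asarray(r) for r in schedule.rows]
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("contrasts must sample equally many rows")
        self.n_samples = len(self.rows[0]) * self.n
        self._calibrate()

    def _forward_block(self, image: np.ndarray, c: int) -> np.ndarray:
        return _fft2c(image)[self.rows[c], :].ravel()

    def _adjoint_block(self, samples: np.ndarray, c: int) -> np.ndarray:
        spectrum = np.zeros((self.n, self.n), dtype=complex)
        spectrum[self.rows[c], :] = samples.reshape(-1, self.n)
        return _ifft2c(spectrum)

    def initial_image(self, samples_c: np.ndarray, c: int) -> np.ndarray:
        # zero-filled inverse FFT on the unnormalized scale (exact for full
        # sampling since F is unitary)
        return self._adjoint_block(samples_c * self.norm_const, c)


class RadialEncoding(_EncodingBase):
    """Per-contrast NUFFT blocks A_c = P_c F L_c on a radial trajectory."""

    def __init__(self, schedule: SamplingSchedule, width: int = 4,
                 oversampling: float = 2.0) -> None:
        if schedule.scheme != "radial":
            raise ValueError("radial schedule required")
        self.schedule = schedule
        self.n = schedule.matrix_size
        self.n_contrasts = schedule.n_contrasts
        self._trajs = [schedule.trajectory(c)
                       for c in range(self.n_contrasts)]
        sizes = {t.shape[0] for t in self._trajs}
        if len(sizes) != 1:
            raise ValueError("contrasts must have equally many samples")
        self.n_samples = sizes.pop()
        self._nuffts = [NUFFT2D(t, self.n, width=width,
                                oversampling=oversampling)
                        for t in self._trajs]
        # ramp density compensation, used only to initialize solvers
        self._dcf = []
        for t in self._trajs:
            radius = np.hypot(t[:, 0], t[:, 1])
            self._dcf.append(np.maximum(radius, 0.25 / self.n))
        self._calibrate()
        self._init_scale = self._calibrate_initial()

    def _forward_block(self, image: np.ndarray, c: int) -> np.ndarray:
        return self._nuffts[c].forward(image)

    def _adjoint_block(self, samples: np.ndarray, c: int) -> np.ndarray:
        return self._nuffts[c].adjoint(samples)

    def _calibrate_initial(self) -> float:
        """Amplitude calibration of the density-compensated adjoint: a unit
        point source at the image centre should come back at unit height."""
        delta = np.zeros((self.n, self.n), dtype=complex)
        delta[self.n // 2, self.n // 2] = 1.0
        s = self._forward_block(delta, 0)
        g = self._adjoint_block(self._dcf[0] * s, 0)
        peak = g[self.n // 2, self.n // 2].real
        return 1.0 / peak if peak > 0 else 1.0

    def initial_image(self, samples_c: np.ndarray, c: int) -> np.ndarray:
        w = self._dcf[c]
        return self._init_scale * self._adjoint_block(
            w * samples_c * self.norm_const, c)


def make_encoding(schedule: SamplingSchedule) -> _EncodingBase:
    """Build the encoding operator matching a sampling schedule."""
    if schedule.scheme == "cartesian":
        return CartesianEncoding(schedule)
    return RadialEncoding(schedule)


# ---------------------------------------------------------------------------
# Non-linear forward model and Jacobian


class ForwardModel:
    """The composite map K = A o B o D and its Jacobian machinery."""

    def __init__(self, encoding: _EncodingBase, tsl: np.ndarray) -> None:
        self.encoding = encoding
        self.tsl = np.asarray(tsl, dtype=float)
        if self.tsl.size != encoding.n_contrasts:
            raise ValueError("tsl length must match encoding contrasts")

    def __call__(self, maps: ParameterMaps) -> np.ndarray:
        """k-space samples of the signal model, shape (C, M)."""
        return self.encoding.forward(contrast_images(maps, self.tsl))

    def jacobian_apply(self, maps: ParameterMaps, d_s0: np.ndarray,
                       d_t1rho: np.ndarray, d_phase: np.ndarray) -> np.ndarray:
        """Directional derivative of K at ``maps``: grad K . (d_s0, d_t1, d_th)."""
        decay = np.exp(-self.tsl[:, None, None] / maps.t1rho[None])
        r = maps.s0[None] * decay
        dr = decay * d_s0[None] \
            + r * (self.tsl[:, None, None] / maps.t1rho[None] ** 2) * d_t1rho[None]
        d_images = np.exp(1j * maps.phase)[None] * (dr + 1j * r * d_phase[None])
        return self.encoding.forward(d_images)

    def jacobian_adjoint(self, maps: ParameterMaps,
                         samples: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray]:
        """Adjoint [grad K]^H applied to k-space-shaped values -> 3 maps."""
        z = self.encoding.adjoint(samples)
        g = np.exp(-1j * maps.phase)[None] * z
        decay = np.exp(-self.tsl[:, None, None] / maps.t1rho[None])
        r = maps.s0[None] * decay
        d_s0 = np.sum(decay * g.real, axis=0)
        d_t1rho = np.sum(r * (self.tsl[:, None, None] / maps.t1rho[None] ** 2)
                         * g.real, axis=0)
        d_phase = np.sum(r * g.imag, axis=0)
        return d_s0, d_t1rho, d_phase


def forward(maps: ParameterMaps, encoding: _EncodingBase,
            tsl: np.ndarray) -> np.ndarray:
    """Convenience wrapper: K(S0, T1rho, theta) for given encoding and TSLs."""
    return ForwardModel(encoding, tsl)(maps)


def forward_from_data(maps: ParameterMaps, data: KSpaceData,
                      encoding: _EncodingBase) -> np.ndarray:
    return ForwardModel(encoding, data.protocol.tsl)(maps)


# ---------------------------------------------------------------------------
# Discrete difference operators (forward differences, replicate boundary)


def spatial_grad(image: np.ndarray) -> np.ndarray:
    """Forward differences along the last two axes; output (2,) + shape.
    The last difference in each direction is zero (Neumann boundary)."""
    gy = np.zeros_like(np.asarray(image))
    gx = np.zeros_like(gy)
    gy[..., :-1, :] = image[..., 1:, :] - image[..., :-1, :]
    gx[..., :, :-1] = image[..., :, 1:] - image[..., :, :-1]
    return np.stack([gy, gx])


def spatial_grad_adjoint(grad: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`spatial_grad` (negative divergence)."""
    gy, gx = grad[0], grad[1]
    out = np.zeros_like(gy)
    out[..., :-1, :] -= gy[..., :-1, :]
    out[..., 1:, :] += gy[..., :-1, :]
    out[..., :, :-1] -= gx[..., :, :-1]
    out[..., :, 1:] += gx[..., :, :-1]
    return out


def contrast_diff1(series: np.ndarray) -> np.ndarray:
    """First differences along the contrast axis (axis 0); last row zero."""
    out = np.zeros_like(np.asarray(series))
    out[:-1] = series[1:] - series[:-1]
    return out


def contrast_diff1_adjoint(diff: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(diff))
    out[:-1] -= diff[:-1]
    out[1:] += diff[:-1]
    return out


def contrast_diff2(series: np.ndarray) -> np.ndarray:
    """Second differences along the contrast axis, interior contrasts only
    (rows 0 and C-1 of the output are zero).  Requires C >= 3."""
    series = np.asarray(series)
    if series.shape[0] < 3:
        raise ValueError("second-order contrast differences require C >= 3")
    out = np.zeros_like(series)
    out[1:-1] = series[:-2] - 2 * series[1:-1] + series[2:]
    return out


def contrast_diff2_adjoint(diff: np.ndarray) -> np.ndarray:
    diff = np.asarray(diff)
    out = np.zeros_like(diff)
    out[:-2] += diff[1:-1]
    out[1:-1] -= 2 * diff[1:-1]
    out[2:] += diff[1:-1]
    return out
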