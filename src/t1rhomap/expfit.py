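"""Pixel-by-pixel mono-exponential T1rho fitting.

Converts reconstructed intensity series |u_k| into T1rho and S0 maps by
bounded non-linear least squares on S(TSL) = S0 * exp(-TSL/T1rho),
started from a closed-form log-linear initializer.  Pixels whose signal
never rises above an intensity threshold are flagged unfittable.  The S0
map of a two-step reconstruction comes from this fit (not from the
TSL = 0 image); the phase map is reported from the argument of the
TSL = 0 image for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .containers import ContrastImageSeries, ParameterMaps

__all__ = ["FitConfig", "fit_pixel", "fit_map", "MonoExpFit"]


@dataclass
class FitConfig:
    """Bounds and thresholds of the pixel fit.

    ``t1rho_bounds`` are in ms; ``intensity_threshold`` is relative to the
    series maximum magnitude; ``tsl_max`` (ms) optionally drops contrasts
    whose spin-lock time exceeds it (for series whose longest spin-lock
    signal sits at the noise floor).
    """

    t1rho_bounds: tuple[float, float] = (0.1, 1000.0)
    s0_min: float = 0.0
    intensity_threshold: float = 1e-3
    max_fit_iters: int = 100
    tsl_max: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.t1rho_bounds
        if not (0 < lo < hi):
            raise ValueError("t1rho_bounds must be positive and ordered")
        if self.s0_min < 0:
            raise ValueError("s0_min must be >= 0")


def _loglinear_init(intensities: np.ndarray, tsl: np.ndarray,
                    config: FitConfig) -> tuple[float, float]:
    """Closed-form starting point: least-squares line through log S vs TSL."""
    pos = intensities > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tsl[pos], np.log(intensities[pos]), 1)
        t1rho = -1.0 / slope if slope < 0 else config.t1rho_bounds[1]
        s0 = float(np.exp(intercept))
    else:
        t1rho = 0.5 * sum(config.t1rho_bounds)
        s0 = float(intensities.max(initial=0.0))
    lo, hi = config.t1rho_bounds
    return float(np.clip(t1rho, lo, hi)), max(s0, config.s0_min, 1e-30)


def fit_pixel(intensities: np.ndarray, tsl: np.ndarray,
              config: FitConfig | None = None,
              threshold: float | None = None) -> tuple[float, float, bool]:
    """Fit (T1rho, S0) to one pixel's magnitude series.

    Parameters
    ----------
    intensities : array, shape (C,)
        Magnitudes |u_k| at each spin-lock time.
    tsl : array, shape (C,)
        Spin-lock times in ms (at least two, one positive).
    threshold : float, optional
        Absolute intensity below which the pixel counts as unfittable
        (all samples below it).  Defaults to
        ``config.intensity_threshold * max(intensities)`` — i.e. no pixel
        is flagged when fitting a single pixel without context.

    Returns
    -------
    (t1rho, s0, ok) : fitted values (ms, signal units) and a flag that is
    False for unfittable or non-converged pixels.
    """
    config = config or FitConfig()
    intensities = np.asarray(intensities, dtype=float)
    tsl = np.asarray(tsl, dtype=float)
    if intensities.shape != tsl.shape:
        raise ValueError("intensities and tsl must have equal length")
    if tsl.size < 2 or not np.any(tsl > 0):
        raise ValueError("need at least two spin-lock times, one positive")
    if threshold is None:
        threshold = config.intensity_threshold * intensities.max(initial=0.0)
    if np.all(intensities < threshold) or intensities.max(initial=0.0) <= 0:
        return config.t1rho_bounds[0], config.s0_min, False

    t1rho0, s00 = _loglinear_init(intensities, tsl, config)
    lo, hi = config.t1rho_bounds

    def resid(p):
        return p[1] * np.exp(-tsl / p[0]) - intensities

    def jac(p):
        e = np.exp(-tsl / p[0])
        return np.stack([p[1] * e * tsl / p[0] ** 2, e], axis=-1)

    sol = least_squares(
        resid, x0=[t1rho0, s00], jac=jac,
        bounds=([lo, config.s0_min], [hi, np.inf]),
        max_nfev=config.max_fit_iters, method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return float(sol.x[0]), float(sol.x[1]), bool(sol.success)


def fit_map(series: ContrastImageSeries, tsl: np.ndarray | None = None,
            config: FitConfig | None = None) -> tuple[ParameterMaps,
                                                      np.ndarray]:
    """Apply :func:`fit_pixel` to every pixel of an image series.

    Returns the fitted maps (phase taken from the argument of the TSL = 0
    image, or of the shortest-TSL image if none is zero) and a boolean
    mask of pixels that fitted successfully.
    """
    config = config or FitConfig()
    tsl = np.asarray(series.tsl if tsl is None else tsl, dtype=float)
    mags = series.magnitudes
    if config.tsl_max is not None:
        keep = tsl <= config.tsl_max
        tsl, mags = tsl[keep], mags[keep]
    if not np.all(np.isfinite(mags)):
        raise ValueError("series magnitudes must be finite")
    c0 = int(np.argmin(tsl))
    ny, nx = mags.shape[1:]
    threshold = config.intensity_threshold * mags.max(initial=0.0)
    t1rho = np.full((ny, nx), config.t1rho_bounds[0])
    s0 = np.full((ny, nx), config.s0_min)
    ok = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            t1rho[i, j], s0[i, j], ok[i, j] = fit_pixel(
                mags[:, i, j], tsl, config, threshold=threshold)
    phase = np.angle(series.images[c0])
    return ParameterMaps(s0=s0, t1rho=t1rho,
                         phase=phase), ok


class MonoExpFit(BaseEstimator):
    """Estimator interface to the pixel-wise mono-exponential fit.

    ``fit`` takes a :class:`ContrastImageSeries` (with its spin-lock
    times) and exposes the fitted maps as attributes.

    Attributes
    ----------
    maps_ : ParameterMaps
    t1rho_map_, s0_map_, phase_map_ : ndarray
    flags_ : ndarray of bool
        True where the pixel fit converged above threshold.
    """

    def __init__(self, t1rho_bounds: tuple[float, float] = (0.1, 1000.0),
                 s0_min: float = 0.0, intensity_threshold: float = 1e-3,
                 max_fit_iters: int = 100, tsl_max: float | None = None):
        self.t1rho_bounds = t1rho_bounds
        self.s0_min = s0_min
        self.intensity_threshold = intensity_threshold
        self.max_fit_iters = max_fit_iters
        self.tsl_max = tsl_max

    def fit(self, X: ContrastImageSeries, y=None,
            tsl: np.ndarray | None = None):
        config = FitConfig(
            t1rho_bounds=self.t1rho_bounds, s0_min=self.s0_min,
            intensity_threshold=self.intensity_threshold,
            max_fit_iters=self.max_fit_iters, tsl_max=self.tsl_max)
        maps, ok = fit_map(X, tsl=tsl, config=config)
        self.maps_ = maps
        self.t1rho_map_ = maps.t1rho
        self.s0_map_ = maps.s0
        self.phase_map_ = maps.phase
        self.flags_ = ok
        return self
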