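"""Compressed-sensing reference reconstructions and the zero-filled iFFT.

Two convex models reconstruct the complex per-contrast image series u
from undersampled k-space before any signal-model fitting:

* ``s1c1``:  ||Au - m||^2 + alpha TV_S(u) + beta TV_C(u) — isotropic
  spatial TV per contrast plus a 1-norm of first contrast differences;
* ``s1c2``:  ||Au - m||^2 + alpha TV_SC(u) — a single root combining the
  spatial differences with the second-order contrast difference.

Both are solved with the (linear) primal-dual proximal splitting of
Chambolle and Pock with steps tau = sigma = 0.99 / L, L the power-
iteration norm of the stacked operator [A; differences].  Complex TV uses
the pointwise Euclidean norm of the stacked real/imaginary difference
components (the modulus of the complex differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import ContrastImageSeries, KSpaceData
from .operators import (_EncodingBase, contrast_diff1, contrast_diff1_adjoint,
                        contrast_diff2, contrast_diff2_adjoint, make_encoding,
                        power_iteration_norm, spatial_grad,
                        spatial_grad_adjoint)

__all__ = ["CSConfig", "solve_cs", "solve_ifft", "cs_objective", "CSRecon",
           "cs_unknown_count", "embedded_unknown_count",
           "unknown_reduction_percent"]


@dataclass
class CSConfig:
    """Model selection and weights for the CS reconstructions."""

    model: str = "s1c2"
    alpha: float = 1e-3
    beta: float = 1e-3  # used by s1+c1 only
    max_iters: int = 5000
    rel_tol: float = 1e-7

    def __post_init__(self) -> None:
        model = self.model.replace("+", "").lower()
        if model not in ("s1c1", "s1c2"):
            raise ValueError("model must be 's1c1' or 's1c2'")
        self.model = model
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be >= 0")


def _complex_tv_project(v: np.ndarray, radius: float) -> np.ndarray:
    """Project stacked complex difference components onto the ball of the
    given radius of their pointwise Euclidean (modulus) norm.  The leading
    axis indexes the difference components."""
    if radius <= 0:
        return np.zeros_like(v)
    norms = np.sqrt(np.sum(np.abs(v) ** 2, axis=0))
    factor = radius / np.maximum(norms, radius)
    return v * factor[None]


def cs_objective(u: np.ndarray, data: KSpaceData, encoding: _EncodingBase,
                 config: CSConfig) -> float:
    """Objective value of the chosen CS model at an image series."""
    resid = encoding.forward(u) - data.samples
    obj = float(np.sum(np.abs(resid) ** 2))
    g = spatial_grad(u)  # (2, C, ny, nx)
    if config.model == "s1c1":
        obj += config.alpha * float(
            np.sum(np.sqrt(np.sum(np.abs(g) ** 2, axis=0))))
        obj += config.beta * float(np.sum(np.abs(contrast_diff1(u))))
    else:
        c2 = contrast_diff2(u)
        obj += config.alpha * float(np.sum(np.sqrt(
            np.sum(np.abs(g) ** 2, axis=0) + np.abs(c2) ** 2)))
    return obj


def _stack_norm(encoding: _EncodingBase, config: CSConfig, shape) -> float:
    """Power-iteration norm of the stacked operator [A; differences]."""
    use_c2 = config.model == "s1c2"

    def fwd(u):
        parts = [encoding.forward(u).ravel(), spatial_grad(u).ravel()]
        if config.model == "s1c1":
            parts.append(contrast_diff1(u).ravel())
        elif use_c2:
            parts.append(contrast_diff2(u).ravel())
        return parts

    def fwd_flat(u):
        return np.concatenate(fwd(u))

    c, n = shape[0], shape[1]

    def adj_flat(parts):
        m = encoding.n_samples * c
        ksp = parts[:m].reshape(c, -1)
        g = parts[m:m + 2 * c * n * n].reshape((2, c, n, n))
        out = encoding.adjoint(ksp) + spatial_grad_adjoint(g)
        rest = parts[m + 2 * c * n * n:]
        if rest.size:
            d = rest.reshape(shape)
            out = out + (contrast_diff2_adjoint(d) if use_c2
                         else contrast_diff1_adjoint(d))
        return out

    return power_iteration_norm(fwd_flat, adj_flat, shape)


def solve_cs(data: KSpaceData, encoding: _EncodingBase | None = None,
             config: CSConfig | None = None) -> tuple[ContrastImageSeries,
                                                      dict]:
    """Chambolle–Pock solve of the selected CS model."""
    config = config or CSConfig()
    if encoding is None:
        encoding = make_encoding(data.schedule)
    c = data.protocol.n_contrasts
    n = data.protocol.matrix_size
    shape = (c, n, n)
    if config.model == "s1c2" and c < 3:
        raise ValueError("the s1c2 model needs at least three contrasts")
    m = data.samples

    L = _stack_norm(encoding, config, shape)
    tau = sigma = 0.99 / max(L, 1e-30)

    u = encoding.adjoint(m)  # zero-filled adjoint initializer
    y_data = np.zeros_like(m)
    y_s = np.zeros((2,) + shape, dtype=complex)
    y_c = np.zeros(shape, dtype=complex)

    converged = False
    rel_change = np.inf
    history = {"iteration": [], "objective": [], "rel_change": []}
    u_bar = u.copy()
    for it in range(1, config.max_iters + 1):
        # dual ascent on y + sigma K(u_bar)
        y_data = (y_data + sigma * encoding.forward(u_bar) - sigma * m) \
            / (1.0 + sigma / 2.0)
        if config.model == "s1c1":
            y_s = _complex_tv_project(y_s + sigma * spatial_grad(u_bar),
                                      config.alpha)
            y_c = _complex_tv_project(
                (y_c + sigma * contrast_diff1(u_bar))[None],
                config.beta)[0]
            grad_reg = spatial_grad_adjoint(y_s) + contrast_diff1_adjoint(y_c)
        else:
            stacked = np.concatenate(
                [y_s + sigma * spatial_grad(u_bar),
                 (y_c + sigma * contrast_diff2(u_bar))[None]], axis=0)
            stacked = _complex_tv_project(stacked, config.alpha)
            y_s, y_c = stacked[:2], stacked[2]
            grad_reg = spatial_grad_adjoint(y_s) + contrast_diff2_adjoint(y_c)

        u_new = u - tau * (encoding.adjoint(y_data) + grad_reg)
        du = np.linalg.norm((u_new - u).ravel())
        nu = np.linalg.norm(u_new.ravel())
        if not np.isfinite(nu) or nu > 1e300:
            raise FloatingPointError(
                f"CS solver diverged at iteration {it}")
        rel_change = du / max(nu, 1e-30)
        u_bar = 2.0 * u_new - u
        u = u_new

        if it % 50 == 0 or it == 1:
            history["iteration"].append(it)
            history["objective"].append(
                cs_objective(u, data, encoding, config))
            history["rel_change"].append(float(rel_change))
        if it > 2 and rel_change < config.rel_tol:
            converged = True
            break

    report = dict(history)
    report["n_iter"] = it
    report["converged"] = converged
    report["final_rel_change"] = float(rel_change)
    series = ContrastImageSeries(images=u, tsl=data.protocol.tsl)
    return series, report


def solve_ifft(data: KSpaceData,
               encoding: _EncodingBase | None = None) -> ContrastImageSeries:
    """Zero-filled inverse DFT reference (cartesian sampling only)."""
    if data.schedule.scheme != "cartesian":
        raise ValueError("the iFFT reference is defined for cartesian data")
    if encoding is None:
        encoding = make_encoding(data.schedule)
    images = np.stack([encoding.initial_image(data.samples[c], c)
                       for c in range(data.protocol.n_contrasts)])
    return ContrastImageSeries(images=images, tsl=data.protocol.tsl)


# ---------------------------------------------------------------------------
# Unknown-count bookkeeping (basis of the reduction-in-unknowns reporting)


def cs_unknown_count(n_pixels: int, n_contrasts: int) -> int:
    """Real unknowns of the CS parameterization: one complex image per
    contrast, i.e. 2*N*C."""
    return 2 * n_pixels * n_contrasts


def embedded_unknown_count(n_pixels: int) -> int:
    """Real unknowns of the embedded parameterization: S0, T1rho, theta."""
    return 3 * n_pixels


def unknown_reduction_percent(n_contrasts: int, n_pixels: int = 1) -> float:
    """Percent reduction in unknowns of the embedded vs CS parameterization
    (independent of the pixel count)."""
    cs = cs_unknown_count(n_pixels, n_contrasts)
    emb = embedded_unknown_count(n_pixels)
    return 100.0 * (1.0 - emb / cs)


class CSRecon(BaseEstimator):
    """Estimator interface to the CS reference reconstructions.

    Attributes
    ----------
    images_ : ContrastImageSeries
        Reconstructed complex per-contrast images.
    history_ : dict
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, model: str = "s1c2", alpha: float = 1e-3,
                 beta: float = 1e-3, max_iters: int = 5000,
                 rel_tol: float = 1e-7):
        self.model = model
        self.alpha = alpha
        self.beta = beta
        self.max_iters = max_iters
        self.rel_tol = rel_tol

    def fit(self, X: KSpaceData, y=None, encoding: _EncodingBase | None = None):
        config = CSConfig(model=self.model, alpha=self.alpha, beta=self.beta,
                          max_iters=self.max_iters, rel_tol=self.rel_tol)
        series, report = solve_cs(X, encoding=encoding, config=config)
        self.images_ = series
        self.history_ = report
        self.n_iter_ = report["n_iter"]
        self.converged_ = report["converged"]
        return self
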