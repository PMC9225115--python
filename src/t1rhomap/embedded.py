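"""Embedded (direct) T1rho reconstruction by non-linear primal-dual
proximal splitting.

The reconstruction solves

    min_{S0, T1rho, theta}  ||K(S0, T1rho, theta) - m||_2^2
        + alpha1 TV(S0) + alpha2 TV(T1rho) + alpha3 ||grad theta||_2^2
        + box constraints S0 >= a1, T1rho >= a2,

where K is the non-linear signal model composed with the (normalized)
Fourier encoding.  The non-linear map H stacks K with the spatial
difference operators of all three maps; each iteration takes a primal
step through the Jacobian adjoint of H, over-relaxes, and applies dual
proximal steps.

Step sizes.  The Jacobian of the magnitude/phase embedding is diagonal
per pixel, so the three parameter blocks have cheaply computable squared
sup-norm sums L1^2, L2^2, L3^2 (see :func:`compute_block_norms`).  The
primal block steps are inverse to these squared norms,
``tau_i = scale / L_i^2`` — the per-block curvature scale — which gives
the weakly coupled T1rho block (whose Jacobian entries carry the small
factor TSL/T1rho^2) the large steps it needs.  Each dual block gets its
own step chosen so the preconditioned convergence criterion

    || Sigma^{1/2} grad_H(x) T^{1/2} ||^2 < 1

holds by construction (budgets 0.5 for the data block and 0.15 for each
regularizer block); the criterion is additionally estimated numerically
at logged iterations and the primal steps are rescaled globally if it is
ever found violated.  All steps are kept non-increasing across
iterations, refreshing the block norms at every iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .containers import KSpaceData, ParameterMaps
from .operators import (ForwardModel, _EncodingBase, make_encoding,
                        spatial_grad, spatial_grad_adjoint)

__all__ = [
    "EmbeddedConfig",
    "DualSteps",
    "SolverState",
    "initialize",
    "compute_block_norms",
    "derive_steps",
    "prox_primal",
    "prox_dual_data",
    "prox_dual_tv",
    "prox_dual_l2grad",
    "solve",
    "EmbeddedRecon",
]

# fractions of the convergence budget allotted to the dual blocks
_DATA_BUDGET = 0.5
_REG_BUDGET = 0.15
_DIFF_NORM_SQ = 8.0  # squared norm of the 2-D forward-difference operator


@dataclass
class EmbeddedConfig:
    """Tunables of the embedded reconstruction.

    ``alpha1``/``alpha2`` weight the total variation of S0 and T1rho,
    ``alpha3`` the squared gradient norm of the phase.  Usable weight
    magnitudes track the squared image intensity scale: around 1e-5 for
    alpha3 at unit-peak data (values like 0.01 belong to raw scanner
    intensities; see docs/methods.md).  ``a1``/``a2`` are the small
    positive lower bounds on S0 and T1rho; ``tau2_multiplier`` boosts the
    T1rho step; ``omega`` is the relaxation parameter of the splitting.
    """

    alpha1: float = 1e-4
    alpha2: float = 1e-4
    alpha3: float = 0.01
    a1: float = 1e-6
    a2: float = 1e-6
    tau2_multiplier: float = 1.0
    omega: float = 1.0
    max_iters: int = 10_000
    rel_tol: float = 1e-6
    t1rho_init: float = 20.0
    step_check_every: int = 50
    phase_warmup_iters: int = 0
    phase_init_smooth: float = 0.0
    phase_init: str = "tsl0"  # or "composite"

    @property
    def _phase_init_mode(self) -> str:
        if self.phase_init not in ("tsl0", "composite"):
            raise ValueError("phase_init must be 'tsl0' or 'composite'")
        return self.phase_init

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("box bounds a1, a2 must be positive")
        if self.omega < 0:
            raise ValueError("relaxation omega must be >= 0")


@dataclass
class DualSteps:
    """Per-block dual step sizes."""

    data: float
    s0: float
    t1rho: float
    phase: float

    def as_array(self) -> np.ndarray:
        return np.array([self.data, self.s0, self.t1rho, self.phase])

    def minimum(self, other: "DualSteps") -> "DualSteps":
        return DualSteps(*np.minimum(self.as_array(), other.as_array()))


@dataclass
class SolverState:
    """Primal/dual iterates and step parameters of the splitting."""

    x: ParameterMaps
    y_data: np.ndarray
    y_s0: np.ndarray
    y_t1rho: np.ndarray
    y_phase: np.ndarray
    tau: np.ndarray  # (tau1, tau2, tau3)
    sigma: DualSteps
    iteration: int = 0
    step_scale: float = 1.0
    history: dict = field(default_factory=lambda: {
        "iteration": [], "objective": [], "rel_change": [],
        "tau1": [], "tau2": [], "tau3": [], "sigma_data": [],
        "step_criterion": []})


def initialize(data: KSpaceData, encoding: _EncodingBase,
               config: EmbeddedConfig) -> SolverState:
    """Starting point: S0 and phase from the (density-compensated) adjoint
    of the TSL = 0 measurements, T1rho constant, dual variable zero."""
    tsl = data.protocol.tsl
    zero_idx = np.flatnonzero(tsl == 0)
    if zero_idx.size == 0:
        raise ValueError("initialization requires a TSL = 0 contrast")
    c0 = int(zero_idx[0])
    z = encoding.initial_image(data.samples[c0], c0)
    s0 = np.maximum(np.abs(z), config.a1)
    if config._phase_init_mode == "composite":
        # all contrasts share theta, so the adjoint of the pooled data —
        # complementary sampling gives it the union k-space coverage —
        # estimates the phase far better than the TSL=0 subset alone
        z = sum(encoding.initial_image(data.samples[c], c)
                for c in range(data.protocol.n_contrasts))
    if config.phase_init_smooth > 0:
        # low-pass the adjoint before reading the phase: ringing sidelobes
        # of undersampled/disc-limited adjoints carry pi-flips that would
        # otherwise seed the phase map with local-minimum traps
        from scipy.ndimage import gaussian_filter
        z_smooth = (gaussian_filter(z.real, config.phase_init_smooth)
                    + 1j * gaussian_filter(z.imag, config.phase_init_smooth))
        phase = np.angle(z_smooth)
    else:
        phase = np.angle(z)
    t1rho = np.full_like(s0, config.t1rho_init)
    x = ParameterMaps(s0=s0, t1rho=t1rho, phase=phase)
    shape = s0.shape
    return SolverState(
        x=x,
        y_data=np.zeros_like(data.samples),
        y_s0=np.zeros((2,) + shape),
        y_t1rho=np.zeros((2,) + shape),
        y_phase=np.zeros((2,) + shape),
        tau=np.zeros(3),
        sigma=DualSteps(0.0, 0.0, 0.0, 0.0),
    )


def compute_block_norms(maps: ParameterMaps,
                        tsl: np.ndarray) -> tuple[float, float, float]:
    """Squared sup-norm sums of the three Jacobian column blocks of B o D:

    L1^2 = sum_c ||exp(-TSL_c/T1rho)||_inf^2,
    L2^2 = sum_c ||r_c * TSL_c/T1rho^2||_inf^2,
    L3^2 = sum_c ||S0 * exp(-TSL_c/T1rho)||_inf^2,

    with r_c = S0 * exp(-TSL_c/T1rho).
    """
    tsl = np.asarray(tsl, dtype=float)
    if np.any(maps.t1rho <= 0):
        raise ValueError("t1rho must be strictly positive")
    decay = np.exp(-tsl[:, None, None] / maps.t1rho[None])
    r = maps.s0[None] * decay
    l1 = float(np.sum(np.max(decay, axis=(1, 2)) ** 2))
    l2 = float(np.sum(np.max(
        r * (tsl[:, None, None] / maps.t1rho[None] ** 2), axis=(1, 2)) ** 2))
    l3 = float(np.sum(np.max(r, axis=(1, 2)) ** 2))
    return l1, l2, l3


def derive_steps(norms: tuple[float, float, float], config: EmbeddedConfig,
                 scale: float = 1.0) -> tuple[np.ndarray, DualSteps]:
    """Primal block steps and per-block dual steps from the block norms.

    tau_i = scale / L_i^2 (tau2 additionally multiplied by
    ``tau2_multiplier``); the dual steps are set so each block's share of
    the convergence criterion stays below its budget, i.e.
    sigma_data * sum_i tau_i L_i^2 = 0.5 and
    sigma_reg,i * 8 * tau_i = 0.15.
    """
    l1, l2, l3 = norms
    if max(norms) <= 0:
        raise ValueError("all block norms are zero")
    floor = 1e-300
    tau = scale / np.maximum(np.array([l1, l2, l3]), floor)
    tau[1] *= config.tau2_multiplier
    sigma = DualSteps(
        data=_DATA_BUDGET / max(tau[0] * l1 + tau[1] * l2 + tau[2] * l3,
                                floor),
        s0=_REG_BUDGET / (_DIFF_NORM_SQ * tau[0]),
        t1rho=_REG_BUDGET / (_DIFF_NORM_SQ * tau[1]),
        phase=_REG_BUDGET / (_DIFF_NORM_SQ * tau[2]),
    )
    return tau, sigma


def prox_primal(x: ParameterMaps, config: EmbeddedConfig) -> ParameterMaps:
    """Resolvent of the box-constraint indicator: clamp S0 and T1rho."""
    return ParameterMaps(
        s0=np.maximum(x.s0, config.a1),
        t1rho=np.maximum(x.t1rho, config.a2),
        phase=x.phase,
    )


def prox_dual_data(v: np.ndarray, sigma: float, m: np.ndarray) -> np.ndarray:
    """Resolvent of the conjugate of z -> ||z - m||_2^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (v - sigma * m) / (1.0 + sigma / 2.0)


def prox_dual_tv(v: np.ndarray, radius: float) -> np.ndarray:
    """Pixel-wise projection of difference 2-vectors onto the disc of the
    given radius (conjugate resolvent of the TV seminorm)."""
    if radius <= 0:
        return np.zeros_like(v)
    norms = np.sqrt(np.sum(v ** 2, axis=0))
    factor = radius / np.maximum(norms, radius)
    return v * factor[None]


def prox_dual_l2grad(v: np.ndarray, sigma: float, alpha: float) -> np.ndarray:
    """Resolvent of the conjugate of g -> alpha * ||g||_2^2 (linear shrink)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if alpha <= 0:
        return np.zeros_like(v)
    return v / (1.0 + sigma / (2.0 * alpha))


def _estimate_data_row_norm_sq(model: ForwardModel, x: ParameterMaps,
                               tau: np.ndarray, n_iter: int = 8,
                               seed: int = 0) -> float:
    """Power-iteration estimate of ||A grad(BoD)(x) T^{1/2}||^2 — the data
    row of the preconditioned criterion.  The sup-norm block bounds
    sum_i tau_i L_i^2 can overestimate this by a large factor (the maxima
    sit at different pixels and the encoding is not isometric on them), so
    the measured value lets the data dual step be correspondingly larger."""
    rng = np.random.default_rng(seed)
    shape = x.shape
    d = [rng.standard_normal(shape) for _ in range(3)]
    sqt = np.sqrt(tau)
    norm = 0.0
    for _ in range(n_iter):
        ksamp = model.jacobian_apply(x, d[0] * sqt[0], d[1] * sqt[1],
                                     d[2] * sqt[2])
        a0, a1, a2 = model.jacobian_adjoint(x, ksamp)
        w = [a0 * sqt[0], a1 * sqt[1], a2 * sqt[2]]
        norm = float(np.sqrt(sum(np.sum(v ** 2) for v in w)))
        if norm == 0:
            return 0.0
        d = [v / norm for v in w]
    return norm


def _estimate_step_criterion(model: ForwardModel, x: ParameterMaps,
                             tau: np.ndarray, sigma: DualSteps,
                             n_iter: int = 8, seed: int = 0) -> float:
    """Power-iteration estimate of ||Sigma^{1/2} grad_H(x) T^{1/2}||^2,
    the preconditioned convergence criterion of the splitting (reduces to
    tau * sigma * ||grad_H||^2 for scalar steps)."""
    rng = np.random.default_rng(seed)
    shape = x.shape
    d = [rng.standard_normal(shape) for _ in range(3)]
    sqt = np.sqrt(tau)
    crit = 0.0
    for _ in range(n_iter):
        ds0, dt1, dth = d[0] * sqt[0], d[1] * sqt[1], d[2] * sqt[2]
        ksamp = sigma.data * model.jacobian_apply(x, ds0, dt1, dth)
        gs0 = sigma.s0 * spatial_grad(ds0)
        gt1 = sigma.t1rho * spatial_grad(dt1)
        gth = sigma.phase * spatial_grad(dth)
        as0, at1, ath = model.jacobian_adjoint(x, ksamp)
        as0 = as0 + spatial_grad_adjoint(gs0)
        at1 = at1 + spatial_grad_adjoint(gt1)
        ath = ath + spatial_grad_adjoint(gth)
        w = [as0 * sqt[0], at1 * sqt[1], ath * sqt[2]]
        crit = float(np.sqrt(sum(np.sum(v ** 2) for v in w)))
        if crit == 0:
            return 0.0
        d = [v / crit for v in w]
    return crit


def _objective(model: ForwardModel, x: ParameterMaps, m: np.ndarray,
               config: EmbeddedConfig) -> float:
    resid = model(x) - m
    obj = float(np.sum(np.abs(resid) ** 2))
    if config.alpha1 > 0:
        obj += config.alpha1 * float(
            np.sum(np.sqrt(np.sum(spatial_grad(x.s0) ** 2, axis=0))))
    if config.alpha2 > 0:
        obj += config.alpha2 * float(
            np.sum(np.sqrt(np.sum(spatial_grad(x.t1rho) ** 2, axis=0))))
    if config.alpha3 > 0:
        obj += config.alpha3 * float(np.sum(spatial_grad(x.phase) ** 2))
    return obj


def solve(data: KSpaceData, encoding: _EncodingBase | None = None,
          config: EmbeddedConfig | None = None,
          callback=None) -> tuple[ParameterMaps, dict]:
    """Run the non-linear primal-dual splitting to convergence.

    Returns the final maps (always satisfying the box constraints) and a
    convergence report with the iteration history.
    """
    config = config or EmbeddedConfig()
    if encoding is None:
        encoding = make_encoding(data.schedule)
    tsl = data.protocol.tsl
    if not np.any(tsl > 0):
        raise ValueError("at least one positive spin-lock time is required")
    model = ForwardModel(encoding, tsl)
    m = data.samples

    state = initialize(data, encoding, config)
    x = state.x
    norms = compute_block_norms(x, tsl)
    tau, sigma = derive_steps(norms, config, state.step_scale)
    # tighten the data dual step with the measured data-row norm
    row_sq = _estimate_data_row_norm_sq(model, x, tau)
    if row_sq > 0:
        sigma.data = max(sigma.data, _DATA_BUDGET / row_sq)
    rho = _estimate_step_criterion(model, x, tau, sigma)
    if rho >= 1.0:
        state.step_scale *= 0.9 / rho
        tau, sigma = derive_steps(norms, config, state.step_scale)
    state.tau, state.sigma = tau, sigma

    converged = False
    rel_change = np.inf
    for it in range(1, config.max_iters + 1):
        # primal: x <- prox_G(x - T [grad H(x)]^H y)
        gs0, gt1, gth = model.jacobian_adjoint(x, state.y_data)
        gs0 = gs0 + spatial_grad_adjoint(state.y_s0)
        gt1 = gt1 + spatial_grad_adjoint(state.y_t1rho)
        gth = gth + spatial_grad_adjoint(state.y_phase)
        s0_new = np.maximum(x.s0 - state.tau[0] * gs0, config.a1)
        t1_new = np.maximum(x.t1rho - state.tau[1] * gt1, config.a2)
        # phase warm-up: hold theta until the magnitudes have adapted, so
        # large early residuals cannot scramble the phase through the
        # encoding's point-spread sidelobes
        if it <= config.phase_warmup_iters:
            th_new = x.phase
        else:
            th_new = x.phase - state.tau[2] * gth
        x_new = ParameterMaps(s0=s0_new, t1rho=t1_new, phase=th_new)

        dx = np.sqrt(np.sum((x_new.s0 - x.s0) ** 2)
                     + np.sum((x_new.t1rho - x.t1rho) ** 2)
                     + np.sum((x_new.phase - x.phase) ** 2))
        nx = np.sqrt(np.sum(x_new.s0 ** 2) + np.sum(x_new.t1rho ** 2)
                     + np.sum(x_new.phase ** 2))
        if not np.isfinite(nx) or nx > 1e300:
            raise FloatingPointError(
                f"embedded solver diverged at iteration {it} "
                f"(primal norm {nx:.3e}); consider smaller steps or "
                "stronger regularization")
        rel_change = dx / max(nx, 1e-30)

        # over-relaxation; the extrapolated point may leave the box, but
        # T1rho keeps a tiny positive floor so the decay stays defined
        x_bar = ParameterMaps.unchecked(
            s0=x_new.s0 + config.omega * (x_new.s0 - x.s0),
            t1rho=np.maximum(
                x_new.t1rho + config.omega * (x_new.t1rho - x.t1rho),
                min(config.a2, 1e-12)),
            phase=x_new.phase + config.omega * (x_new.phase - x.phase),
        )

        # dual proximal steps on y + sigma * H(x_bar)
        sig = state.sigma
        state.y_data = prox_dual_data(
            state.y_data + sig.data * model(x_bar), sig.data, m)
        state.y_s0 = prox_dual_tv(
            state.y_s0 + sig.s0 * spatial_grad(x_bar.s0), config.alpha1)
        state.y_t1rho = prox_dual_tv(
            state.y_t1rho + sig.t1rho * spatial_grad(x_bar.t1rho),
            config.alpha2)
        state.y_phase = prox_dual_l2grad(
            state.y_phase + sig.phase * spatial_grad(x_bar.phase), sig.phase,
            config.alpha3)

        x = x_new
        state.x = x
        state.iteration = it

        # refresh step sizes from the current iterate; never increase them
        # (the data sigma is refreshed at check points from its measured
        # row norm rather than the conservative sup-norm bound)
        norms = compute_block_norms(x, tsl)
        tau_new, sigma_new = derive_steps(norms, config, state.step_scale)
        state.tau = np.minimum(state.tau, tau_new)
        state.sigma = DualSteps(
            data=state.sigma.data,
            s0=min(state.sigma.s0, sigma_new.s0),
            t1rho=min(state.sigma.t1rho, sigma_new.t1rho),
            phase=min(state.sigma.phase, sigma_new.phase),
        )

        if it % config.step_check_every == 0 or it == 1:
            row_sq = _estimate_data_row_norm_sq(model, x, state.tau, seed=it)
            if row_sq > 0:
                state.sigma.data = min(state.sigma.data,
                                       _DATA_BUDGET / row_sq)
            rho = _estimate_step_criterion(model, x, state.tau, state.sigma,
                                           seed=it)
            if rho >= 1.0:
                shrink = 0.9 / rho
                state.step_scale *= shrink
                state.tau = state.tau * shrink
            state.history["iteration"].append(it)
            state.history["objective"].append(_objective(model, x, m, config))
            state.history["rel_change"].append(float(rel_change))
            state.history["tau1"].append(float(state.tau[0]))
            state.history["tau2"].append(float(state.tau[1]))
            state.history["tau3"].append(float(state.tau[2]))
            state.history["sigma_data"].append(float(state.sigma.data))
            state.history["step_criterion"].append(float(min(rho, 0.9)
                                                         if rho >= 1.0
                                                         else rho))
            if callback is not None:
                callback(state)

        # the very first primal step is a no-op (y starts at zero), so the
        # stopping test only applies once the duals have acted
        if it > 2 and rel_change < config.rel_tol:
            converged = True
            break

    report = dict(state.history)
    report["n_iter"] = state.iteration
    report["converged"] = converged
    report["final_rel_change"] = float(rel_change)
    return x, report


class EmbeddedRecon(BaseEstimator):
    """Estimator interface to the embedded T1rho reconstruction.

    ``fit`` takes a :class:`~t1rhomap.containers.KSpaceData` container and
    exposes the reconstructed maps as fitted attributes.

    Parameters mirror :class:`EmbeddedConfig`.

    Attributes
    ----------
    maps_ : ParameterMaps
        Reconstructed S0, T1rho (ms) and phase (rad) maps.
    s0_map_, t1rho_map_, phase_map_ : ndarray
        Convenience views of the same maps.
    history_ : dict
        Convergence log (objective, step sizes, relative change,
        step-criterion estimates).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, alpha1: float = 1e-4, alpha2: float = 1e-4,
                 alpha3: float = 0.01, a1: float = 1e-6, a2: float = 1e-6,
                 tau2_multiplier: float = 1.0, omega: float = 1.0,
                 max_iters: int = 10_000, rel_tol: float = 1e-6,
                 t1rho_init: float = 20.0, step_check_every: int = 50,
                 phase_init: str = "tsl0"):
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.alpha3 = alpha3
        self.a1 = a1
        self.a2 = a2
        self.tau2_multiplier = tau2_multiplier
        self.omega = omega
        self.max_iters = max_iters
        self.rel_tol = rel_tol
        self.t1rho_init = t1rho_init
        self.step_check_every = step_check_every
        self.phase_init = phase_init

    def _config(self) -> EmbeddedConfig:
        return EmbeddedConfig(
            alpha1=self.alpha1, alpha2=self.alpha2, alpha3=self.alpha3,
            a1=self.a1, a2=self.a2, tau2_multiplier=self.tau2_multiplier,
            omega=self.omega, max_iters=self.max_iters, rel_tol=self.rel_tol,
            t1rho_init=self.t1rho_init,
            step_check_every=self.step_check_every,
            phase_init=self.phase_init)

    def fit(self, X: KSpaceData, y=None, encoding: _EncodingBase | None = None):
        maps, report = solve(X, encoding=encoding, config=self._config())
        self.maps_ = maps
        self.s0_map_ = maps.s0
        self.t1rho_map_ = maps.t1rho
        self.phase_map_ = maps.phase
        self.history_ = report
        self.n_iter_ = report["n_iter"]
        self.converged_ = report["converged"]
        return self
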