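import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from t1rhomap.containers import AcquisitionProtocol, ParameterMaps
from t1rhomap.embedded import (DualSteps, EmbeddedConfig, EmbeddedRecon,
                               compute_block_norms, derive_steps, initialize,
                               prox_dual_data, prox_dual_l2grad, prox_dual_tv,
                               prox_primal, solve)
from t1rhomap.operators import make_encoding
from t1rhomap.phantom import PhantomSpec, make_phantom_maps
from t1rhomap.sampling import (cartesian_schedule, golden_angle_schedule,
                               radial_subsample)
from t1rhomap.simulate import simulate_kspace

TSL3 = np.array([0.0, 16.0, 64.0])


@pytest.fixture(scope="module")
def tiny_problem():
    """24x24 phantom, 3 contrasts, noiseless full cartesian sampling."""
    spec = PhantomSpec(matrix_size=24, base_size=16)
    maps = make_phantom_maps(spec)
    schedule = cartesian_schedule(24, 1.0, TSL3.size, seed=0)
    protocol = AcquisitionProtocol(tsl=TSL3, matrix_size=24,
                                   scheme="cartesian", af=1.0)
    encoding = make_encoding(schedule)
    data = simulate_kspace(maps, protocol, schedule, 0.0, seed=0,
                           encoding=encoding)
    return maps, data, encoding


class TestInitialize:
    def test_t1rho_starts_constant_and_duals_zero(self, tiny_problem):
        _, data, encoding = tiny_problem
        state = initialize(data, encoding, EmbeddedConfig())
        assert np.all(state.x.t1rho == 20.0)
        for block in (state.y_data, state.y_s0, state.y_t1rho,
                      state.y_phase):
            assert np.all(block == 0)

    def test_s0_recovers_phantom_from_full_cartesian(self):
        """With noiseless full sampling and zero phase the TSL=0 adjoint
        initialization reproduces the phantom S0 exactly."""
        spec = PhantomSpec(matrix_size=24, base_size=16, phase_slope=0.0)
        maps = make_phantom_maps(spec)
        schedule = cartesian_schedule(24, 1.0, 2, seed=0)
        protocol = AcquisitionProtocol(tsl=np.array([0.0, 30.0]),
                                       matrix_size=24, scheme="cartesian",
                                       af=1.0)
        encoding = make_encoding(schedule)
        data = simulate_kspace(maps, protocol, schedule, 0.0, seed=0,
                               encoding=encoding)
        state = initialize(data, encoding, EmbeddedConfig(a1=1e-9))
        inside = maps.s0 > 0
        assert np.allclose(state.x.s0[inside], maps.s0[inside], atol=1e-10)

    def test_requires_tsl_zero_contrast(self, tiny_problem):
        _, data, encoding = tiny_problem
        data_no0 = type(data)(
            samples=data.samples,
            schedule=data.schedule,
            protocol=AcquisitionProtocol(tsl=np.array([4.0, 16.0, 64.0]),
                                         matrix_size=24, scheme="cartesian",
                                         af=1.0),
        )
        with pytest.raises(ValueError, match="TSL"):
            initialize(data_no0, encoding, EmbeddedConfig())


class TestBlockNorms:
    def test_single_tsl0_contrast(self):
        maps = ParameterMaps(s0=np.full((3, 3), 0.5),
                             t1rho=np.full((3, 3), 37.0),
                             phase=np.zeros((3, 3)))
        l1, l2, l3 = compute_block_norms(maps, np.array([0.0]))
        assert l1 == 1.0
        assert l2 == 0.0  # a TSL=0 measurement has no T1rho sensitivity
        assert np.isclose(l3, 0.25)

    def test_l3_bounded_by_l1_when_s0_below_one(self):
        rng = np.random.default_rng(0)
        maps = ParameterMaps(s0=rng.uniform(0, 1, (8, 8)),
                             t1rho=rng.uniform(20, 120, (8, 8)),
                             phase=np.zeros((8, 8)))
        tsl = np.array([0.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
        l1, _, l3 = compute_block_norms(maps, tsl)
        assert l3 <= l1

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        maps = ParameterMaps(s0=rng.uniform(0, 2, (5, 5)),
                             t1rho=rng.uniform(5, 200, (5, 5)),
                             phase=rng.uniform(-1, 1, (5, 5)))
        tsl = np.array([0.0, 10.0, 50.0])
        l1, l2, l3 = compute_block_norms(maps, tsl)
        decay = np.exp(-tsl[:, None, None] / maps.t1rho)
        r = maps.s0 * decay
        assert np.isclose(l1, sum(d.max() ** 2 for d in decay))
        assert np.isclose(l2, sum(
            (r[i] * tsl[i] / maps.t1rho ** 2).max() ** 2
            for i in range(3)))
        assert np.isclose(l3, sum(ri.max() ** 2 for ri in r))


class TestDeriveSteps:
    def test_inverse_relation_and_symmetry(self):
        tau, _ = derive_steps((2.0, 2.0, 2.0), EmbeddedConfig())
        assert np.allclose(tau, tau[0])
        tau2, _ = derive_steps((1.0, 4.0, 16.0), EmbeddedConfig())
        assert tau2[0] / tau2[1] == pytest.approx(4.0)
        assert tau2[0] / tau2[2] == pytest.approx(16.0)

    def test_tau2_multiplier_scales_only_t1rho_step(self):
        base, _ = derive_steps((1.0, 4.0, 16.0), EmbeddedConfig())
        boosted, sig = derive_steps((1.0, 4.0, 16.0),
                                    EmbeddedConfig(tau2_multiplier=50.0))
        assert boosted[1] == pytest.approx(50.0 * base[1])
        assert boosted[0] == base[0] and boosted[2] == base[2]
        # the boosted T1rho block still meets its share of the criterion:
        # sigma_t1rho * 8 * tau2 stays at the regularizer budget
        assert sig.t1rho * 8.0 * boosted[1] == pytest.approx(0.15)

    def test_dual_steps_satisfy_budgets(self):
        norms = (3.0, 0.001, 2.5)
        tau, sig = derive_steps(norms, EmbeddedConfig())
        assert sig.data * sum(t * l for t, l in zip(tau, norms)) \
            == pytest.approx(0.5)
        for s, t in ((sig.s0, tau[0]), (sig.t1rho, tau[1]),
                     (sig.phase, tau[2])):
            assert s * 8.0 * t == pytest.approx(0.15)

    def test_all_zero_norms_rejected(self):
        with pytest.raises(ValueError):
            derive_steps((0.0, 0.0, 0.0), EmbeddedConfig())


class TestProxOperators:
    def test_primal_projection_idempotent(self):
        cfg = EmbeddedConfig(a1=0.5, a2=2.0)
        x = ParameterMaps.unchecked(
            s0=np.array([[-1.0, 0.7]]), t1rho=np.array([[1.0, 5.0]]),
            phase=np.array([[0.3, -0.2]]))
        p = prox_primal(x, cfg)
        assert np.all(p.s0 >= 0.5) and np.all(p.t1rho >= 2.0)
        assert p.s0[0, 0] == 0.5 and p.s0[0, 1] == 0.7
        again = prox_primal(p, cfg)
        assert np.array_equal(again.s0, p.s0)
        assert np.array_equal(again.t1rho, p.t1rho)
        assert np.array_equal(again.phase, x.phase)

    def test_data_resolvent_against_numerical_minimizer(self):
        """The closed-form resolvent of the conjugate data term matches
        argmin_y {F*(y) + (y-v)^2/(2 sigma)} computed numerically,
        with F(z) = (z-m)^2 so F*(y) = y*m + y^2/4."""
        sigma, m, v = 0.7, 1.3, -0.4

        def objective(y):
            return y * m + y ** 2 / 4 + (y - v) ** 2 / (2 * sigma)

        num = minimize_scalar(objective, bounds=(-100, 100), method="bounded")
        closed = prox_dual_data(np.array([v + 0j]), sigma,
                                np.array([m + 0j]))[0]
        assert closed.real == pytest.approx(num.x, abs=1e-6)

    def test_l2grad_resolvent_against_numerical_minimizer(self):
        sigma, alpha, v = 0.9, 0.03, 2.2

        def objective(y):
            return y ** 2 / (4 * alpha) + (y - v) ** 2 / (2 * sigma)

        num = minimize_scalar(objective, bounds=(-100, 100), method="bounded")
        closed = prox_dual_l2grad(np.array([v]), sigma, alpha)[0]
        assert closed == pytest.approx(num.x, abs=1e-6)

    def test_tv_projection_cases(self):
        v = np.array([[[3.0]], [[4.0]]])  # pointwise norm 5
        proj = prox_dual_tv(v, 1.0)
        assert np.isclose(np.sqrt(np.sum(proj ** 2)), 1.0)
        assert np.allclose(proj.ravel(), [0.6, 0.8])
        # interior points are untouched; radius 0 kills the block
        inside = np.array([[[0.1]], [[0.2]]])
        assert np.array_equal(prox_dual_tv(inside, 2.0), inside)
        assert np.all(prox_dual_tv(v, 0.0) == 0)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            prox_dual_data(np.zeros(2, dtype=complex), 0.0,
                           np.zeros(2, dtype=complex))


class TestSolve:
    def test_noiseless_recovery_and_solver_contracts(self, tiny_problem):
        """On noiseless fully sampled cartesian data the solver recovers
        T1rho and S0 on the support; along the way every logged iterate
        satisfies the step criterion, the box constraints hold and the
        step sizes never increase."""
        maps, data, encoding = tiny_problem
        crit_log = []
        feasible = []
        cfg = EmbeddedConfig(alpha1=1e-6, alpha2=1e-6, alpha3=1e-6,
                             max_iters=2500, rel_tol=1e-9)
        rec, report = solve(data, encoding, cfg,
                            callback=lambda st: (
                                crit_log.append(st.history["step_criterion"][-1]),
                                feasible.append(
                                    st.x.s0.min() >= cfg.a1
                                    and st.x.t1rho.min() >= cfg.a2)))
        sup = maps.s0 > 1e-3
        rel = np.sqrt(np.mean((rec.t1rho[sup] - maps.t1rho[sup]) ** 2)) \
            / np.sqrt(np.mean(maps.t1rho[sup] ** 2))
        assert rel < 0.02
        assert np.all(rec.s0 >= cfg.a1) and np.all(rec.t1rho >= cfg.a2)
        assert all(feasible)
        assert all(c < 1.0 for c in crit_log)
        for key in ("tau1", "tau2", "tau3", "sigma_data"):
            seq = report[key]
            assert all(b <= a + 1e-15 for a, b in zip(seq, seq[1:]))

    def test_strong_t1rho_tv_flattens_the_map(self, tiny_problem):
        _, data, encoding = tiny_problem
        cfg = EmbeddedConfig(alpha1=1e-6, alpha2=50.0, alpha3=1e-6,
                             max_iters=800, rel_tol=1e-12)
        rec, _ = solve(data, encoding, cfg)
        # TV-dominated limit: spatial variation collapses
        assert np.std(rec.t1rho) < 0.05 * np.mean(rec.t1rho)

    def test_phase_shift_equivariance(self):
        """Adding a global phase constant to the simulated object shifts
        the recovered phase by that constant and leaves S0/T1rho alone."""
        spec = PhantomSpec(matrix_size=24, base_size=16)
        maps = make_phantom_maps(spec)
        shift = 0.8
        shifted = ParameterMaps(maps.s0, maps.t1rho, maps.phase + shift)
        schedule = cartesian_schedule(24, 1.0, TSL3.size, seed=0)
        protocol = AcquisitionProtocol(tsl=TSL3, matrix_size=24,
                                       scheme="cartesian", af=1.0)
        encoding = make_encoding(schedule)
        cfg = EmbeddedConfig(alpha1=1e-6, alpha2=1e-6, alpha3=1e-6,
                             max_iters=1200, rel_tol=1e-9)
        rec_a, _ = solve(simulate_kspace(maps, protocol, schedule, 0.0, 0,
                                         encoding=encoding), encoding, cfg)
        rec_b, _ = solve(simulate_kspace(shifted, protocol, schedule, 0.0, 0,
                                         encoding=encoding), encoding, cfg)
        sup = maps.s0 > 1e-2
        dphi = (rec_b.phase[sup] - rec_a.phase[sup] - shift + np.pi) \
            % (2 * np.pi) - np.pi
        assert np.abs(dphi).max() < 1e-2
        assert np.allclose(rec_b.t1rho[sup], rec_a.t1rho[sup], rtol=1e-2)
        assert np.allclose(rec_b.s0[sup], rec_a.s0[sup], rtol=1e-2,
                           atol=1e-4)

    def test_three_spokes_per_contrast_stays_finite(self):
        """Extreme undersampling (AF-101-style spoke budget) completes
        without divergence and returns finite feasible maps."""
        spec = PhantomSpec(matrix_size=24, base_size=16)
        maps = make_phantom_maps(spec)
        base = golden_angle_schedule(38, 24)
        schedule = radial_subsample(base, 12.7, TSL3.size)  # 3 spokes each
        assert all(len(b) == 3 for b in schedule.spoke_indices)
        protocol = AcquisitionProtocol(tsl=TSL3, matrix_size=24,
                                       scheme="radial", af=12.7)
        encoding = make_encoding(schedule)
        data = simulate_kspace(maps, protocol, schedule, 0.05, seed=5,
                               encoding=encoding)
        cfg = EmbeddedConfig(alpha1=1e-3, alpha2=1e-3, alpha3=0.01,
                             max_iters=400, rel_tol=1e-9)
        rec, report = solve(data, encoding, cfg)
        assert np.all(np.isfinite(rec.s0))
        assert np.all(np.isfinite(rec.t1rho))
        assert np.all(np.isfinite(rec.phase))
        assert np.all(rec.t1rho >= cfg.a2)

    def test_protocol_requires_positive_tsl(self):
        """A protocol with only TSL=0 carries no relaxation information and
        is rejected before any solver can run."""
        with pytest.raises(ValueError):
            AcquisitionProtocol(tsl=np.array([0.0]), matrix_size=24,
                                scheme="cartesian", af=1.0)


class TestEstimator:
    def test_fit_exposes_maps_and_params_roundtrip(self, tiny_problem):
        maps, data, encoding = tiny_problem
        est = EmbeddedRecon(alpha1=1e-6, alpha2=1e-6, alpha3=1e-6,
                            max_iters=300, rel_tol=1e-9)
        assert est.get_params()["alpha2"] == 1e-6
        est.set_params(max_iters=400)
        est.fit(data, encoding=encoding)
        assert est.n_iter_ <= 400
        assert est.t1rho_map_.shape == maps.t1rho.shape
        assert est.maps_.s0 is est.s0_map_
        assert len(est.history_["objective"]) > 0
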