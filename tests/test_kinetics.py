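"""Closed-form Michaelis-Menten machinery: rates, Jacobian, timescales,
slow-manifold expressions, reduced models and the regime map."""

import numpy as np
import pytest

from msid import (
    case_initial_state,
    case_parameters,
    classify_regime,
    derive_constants,
    full_rhs,
    make_fixture,
    pea_sim_c,
    pea_sim_residual,
    reduced_rhs,
    rqssa_sim_s,
    sqssa_sim_c,
    timescale_profile,
)
from msid.kinetics import InvalidParameterError, analytic_jacobian


class TestDerivedConstants:
    @pytest.mark.parametrize(
        "rates, expected",
        [((10, 100, 1, 0.5), (10.0, 0.1, 10.1)),
         ((3, 3, 0.5, 1000), (1.0, 1 / 6, 7 / 6)),
         ((10, 0, 1, 0.5), (0.0, 0.1, 0.1))],
    )
    def test_examples(self, rates, expected):
        p = derive_constants(*rates)
        assert p.KR == pytest.approx(expected[0])
        assert p.K == pytest.approx(expected[1])
        assert p.KM == pytest.approx(expected[2])
        assert p.KM == p.KR + p.K

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1), (1, 1, 0, 1),
                                     (1, -2, 1, 1), (1, 1, 1, 0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            derive_constants(*bad)


class TestVectorField:
    def test_case1_off_manifold_point(self, case1_params):
        np.testing.assert_allclose(full_rhs((0.0, 1.0), case1_params),
                                   [5.0, -5.0])

    def test_origin_is_equilibrium(self, case2_params):
        np.testing.assert_array_equal(full_rhs((0.0, 0.0), case2_params),
                                      [0.0, 0.0])

    def test_case2_sim_point_balances_binding(self, case2_params):
        # on the rQSSA manifold the reversible reaction is near equilibrium,
        # leaving only the catalytic drain -k2*c
        dc, ds = full_rhs((910.0, 10.11111), case2_params)
        assert dc == pytest.approx(-455.0, rel=5e-4)
        assert ds == pytest.approx(0.0, abs=0.05)

    def test_jacobian_closed_form_at_origin(self, case1_params):
        np.testing.assert_allclose(
            analytic_jacobian((0.0, 0.0), case1_params),
            [[-101.0, 5.0], [100.0, -5.0]],
        )

    def test_jacobian_trace_identity(self, case3_params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = rng.uniform(0, case3_params.e0)
            s = rng.uniform(0, 10)
            J = analytic_jacobian((c, s), case3_params)
            expected = -(case3_params.k1f * s + case3_params.k1b
                         + case3_params.k2 + case3_params.k1f
                         * (case3_params.e0 - c))
            assert np.trace(J) == pytest.approx(expected)

    def test_jacobian_matches_finite_differences(self, case1_params):
        x0 = np.array([0.02, 0.7])
        J = analytic_jacobian(x0, case1_params)
        eps = 1e-7
        for j in range(2):
            dx = np.zeros(2)
            dx[j] = eps
            fd = (full_rhs(x0 + dx, case1_params)
                  - full_rhs(x0 - dx, case1_params)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-6)


class TestTimescales:
    def test_eigenvalue_formula_matches_numeric_eigensolve(self):
        rng = np.random.default_rng(11)
        for case in ("case1", "case2", "case3"):
            p = case_parameters(case)
            for _ in range(100):
                c = rng.uniform(0, p.e0 * 0.999)
                s = rng.uniform(1e-6, 10.0)
                prof = timescale_profile((c, s), p)
                lam = np.sort(np.linalg.eigvals(analytic_jacobian((c, s), p)))
                np.testing.assert_allclose(
                    lam, sorted([prof.lambda_fast, prof.lambda_slow]),
                    rtol=1e-8)

    def test_case1_initial_condition_profile(self, case1_params):
        prof = timescale_profile((0.045045, 1.0), case1_params)
        assert prof.mu == pytest.approx(0.1 / 11.0, rel=1e-6)
        assert prof.nu == pytest.approx(4.1360e-2, rel=1e-3)
        assert prof.epsilon == pytest.approx(3.41e-4, rel=2e-2)

    def test_fully_bound_enzyme_has_no_separation_left(self, case1_params):
        prof = timescale_profile((case1_params.e0, 1.0), case1_params)
        assert prof.nu == 0.0
        assert prof.epsilon == 0.0
        assert prof.tau2 == np.inf  # slow eigenvalue vanishes

    def test_epsilon_quarter_limit(self):
        p = derive_constants(1.0, 0.0, 1.0, 1.0)
        # mu = nu = 1e3 corresponds to eps = t^2/(1+2t)^2 -> 1/4
        t = 1e3
        eps = t * t / (1 + 2 * t) ** 2
        assert abs(eps - 0.25) < 1e-3

    def test_epsilon_below_quarter_on_grid(self):
        mu, nu = np.meshgrid(np.logspace(-4, 4, 200), np.logspace(-4, 4, 200))
        eps = mu * nu / (1 + mu + nu) ** 2
        assert np.all(eps < 0.25)

    def test_ordering_and_stability(self):
        rng = np.random.default_rng(3)
        p = case_parameters("case2")
        for _ in range(50):
            prof = timescale_profile(
                (rng.uniform(0, p.e0 * 0.99), rng.uniform(0, 20)), p)
            assert prof.tau1 <= prof.tau2
            assert prof.lambda_fast <= 0 and prof.lambda_slow <= 0


class TestSlowManifolds:
    def test_case1_initial_complex(self, case1_params):
        assert sqssa_sim_c(1.0, case1_params) == pytest.approx(0.045045,
                                                               abs=5e-7)

    def test_case2_initial_substrate(self, case2_params):
        assert rqssa_sim_s(910.0, case2_params) == pytest.approx(10.11111,
                                                                 abs=5e-6)

    def test_zero_substrate_gives_zero_complex(self, case1_params):
        assert sqssa_sim_c(0.0, case1_params) == 0.0

    def test_rqssa_domain_error(self, case2_params):
        with pytest.raises(ValueError):
            rqssa_sim_s(case2_params.e0, case2_params)

    def test_pea_root_satisfies_residual(self, case3_params):
        c = pea_sim_c(10.0, case3_params)
        assert abs(pea_sim_residual((c, 10.0), case3_params)) < 1e-9
        assert 0 < c < case3_params.e0


class TestReducedModels:
    def test_sqssa_slow_equation_expansion(self, case1_params):
        # dc/dt = -k2 (e0-c)^2 c / (KM e0) expands to a cubic in c
        coef = np.array([
            -case1_params.k2 * case1_params.e0 / case1_params.KM,
            2 * case1_params.k2 / case1_params.KM,
            -case1_params.k2 / (case1_params.KM * case1_params.e0),
        ])
        np.testing.assert_allclose(coef, [-0.0495, 0.198, -0.198],
                                   rtol=2e-3)
        c = np.linspace(0, 0.045, 7)
        rhs = reduced_rhs(np.stack([c, np.ones_like(c)], axis=1),
                          case1_params, "sQSSA")[:, 0]
        np.testing.assert_allclose(rhs, coef[0] * c + coef[1] * c**2
                                   + coef[2] * c**3, rtol=1e-12)

    def test_rqssa_fast_equation_expansion(self, case2_params):
        s = np.linspace(0.01, 10, 9)
        rhs = reduced_rhs(np.stack([np.full_like(s, 5.0), s], axis=1),
                          case2_params, "rQSSA")[:, 1]
        np.testing.assert_allclose(rhs, -0.5 * s - 0.5 * s**2, rtol=1e-12)

    def test_pea_interpolates_between_qssa_limits(self, case1_params):
        # nu -> 0: PEA slow equation matches sQSSA's ds/dt = -k2 c
        state = np.array([case1_params.e0 * (1 - 1e-9), 1.0])  # nu ~ 0
        pea = reduced_rhs(state, case1_params, "PEA")
        assert pea[1] == pytest.approx(-case1_params.k2 * state[0], rel=1e-6)
        assert pea[0] == pytest.approx(0.0, abs=1e-6)
        # nu -> inf: PEA matches rQSSA's dc/dt = -k2 c
        p0 = derive_constants(1000.0, 1e-6, 0.5, 100.0)
        state = np.array([1.0, 1e-9])                          # nu huge
        pea = reduced_rhs(state, p0, "PEA")
        assert pea[0] == pytest.approx(-p0.k2 * 1.0, rel=1e-5)

    def test_rqssa_requires_reversible_binding(self):
        p = derive_constants(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            reduced_rhs((0.5, 0.5), p, "rQSSA")

    def test_sqssa_consistent_with_full_model_on_manifold(self, case1_params):
        traj = make_fixture("case1", "full")
        slow_full = traj.fields[:, 1]
        slow_red = reduced_rhs(traj.states, case1_params, "sQSSA")[:, 1]
        rel = np.abs(slow_red - slow_full) / np.max(np.abs(slow_full))
        assert np.max(rel) < 0.05


class TestRegimeMap:
    def test_case1_starts_in_sqssa_region(self, case1_params):
        prof = timescale_profile(case_initial_state("case1"), case1_params)
        assert classify_regime(prof) == "sQSSA"

    def test_no_valid_reduction_when_eps_large(self, case1_params):
        prof = timescale_profile((0.045045, 1.0), case1_params)
        # mu = nu = 1 has eps = 1/9 > 1e-2
        fake = type(prof)(mu=1.0, nu=1.0, epsilon=1 / 9, lambda_fast=-1.0,
                          lambda_slow=-0.5, tau1=1.0, tau2=2.0)
        assert classify_regime(fake) == "none"

    def test_substrate_dominated_state_is_rqssa(self, case1_params):
        prof = timescale_profile((0.045045, 1.0), case1_params)
        fake = type(prof)(mu=0.01, nu=100.0, epsilon=1e-3, lambda_fast=-1.0,
                          lambda_slow=-0.5, tau1=1.0, tau2=2.0)
        assert classify_regime(fake) == "rQSSA"
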