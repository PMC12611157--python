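"""Weak-form sparse identification: test functions, sparse solver, R^2 and
the end-to-end threshold-sweep identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msid import make_fixture, r_squared, simulate
from msid.kinetics import derive_constants
from msid.simulate import NoiseSpec, Trajectory
from msid.sindy import (
    CandidateLibrary,
    WeakSINDy,
    build_weak_system,
    identify,
    sr3_l1,
)

TERMS = list(CandidateLibrary().terms)


def _exp_trajectory(rate=1.0, n=200):
    t = np.linspace(0.0, 3.0, n)
    x = np.exp(-rate * t)
    states = np.stack([x, x], axis=1)
    fields = -rate * states
    return Trajectory(t, states, fields)


class TestWeakSystem:
    def test_exponential_weak_ratio(self):
        """For x(t)=exp(-t), the weak target equals minus the weak feature
        of the linear term to quadrature accuracy."""
        ws = build_weak_system(_exp_trajectory(), K=200)
        j = TERMS.index("c")
        ratio = ws.targets[:, 0] / ws.features[:, j]
        np.testing.assert_allclose(ratio, -1.0, atol=1e-6)

    def test_constant_trajectory_has_zero_targets(self):
        t = np.linspace(0, 1, 50)
        traj = Trajectory(t, np.full((50, 2), 2.0))
        ws = build_weak_system(traj, K=100)
        np.testing.assert_allclose(ws.targets, 0.0, atol=1e-7)

    def test_doubling_K_leaves_solution_stable(self):
        """More test-function placements must not move the identifiable part
        of the least-squares solution (the system is already over-determined;
        only near-null collinear directions are allowed to wiggle)."""
        traj = make_fixture("case2", "rQSSA")
        c_col = TERMS.index("c")
        s_cols = [TERMS.index("s"), TERMS.index("s^2")]
        sols = []
        for K in (1000, 2000):
            ws = build_weak_system(traj, K=K)
            c_fit = np.linalg.lstsq(ws.features[:, [c_col]],
                                    ws.targets[:, 0], rcond=None)[0]
            s_fit = np.linalg.lstsq(ws.features[:, s_cols],
                                    ws.targets[:, 1], rcond=None)[0]
            sols.append(np.concatenate([c_fit, s_fit]))
        np.testing.assert_allclose(sols[0], sols[1], atol=1e-8)

    def test_support_must_fit_inside_trajectory(self):
        with pytest.raises(ValueError):
            build_weak_system(_exp_trajectory(), support_frac=1.5)


class TestSparseSolver:
    def test_exact_linear_recovery(self):
        ws = build_weak_system(_exp_trajectory(rate=0.5), K=200)
        coefs = sr3_l1(ws, threshold=0.01)
        j = TERMS.index("c")
        assert coefs[j, 0] == pytest.approx(-0.5, abs=1e-6)
        assert np.count_nonzero(coefs[:, 0]) == 1

    def test_over_thresholding_yields_empty_model(self):
        ws = build_weak_system(_exp_trajectory(rate=0.5), K=200)
        coefs = sr3_l1(ws, threshold=5.0)
        assert not np.any(coefs)

    def test_case2_reduced_model_recovered_exactly(self):
        ws = build_weak_system(make_fixture("case2", "rQSSA"))
        coefs = sr3_l1(ws, threshold=0.1)
        c_eq = {TERMS[j]: coefs[j, 0] for j in np.nonzero(coefs[:, 0])[0]}
        s_eq = {TERMS[j]: coefs[j, 1] for j in np.nonzero(coefs[:, 1])[0]}
        assert set(c_eq) == {"c"} and c_eq["c"] == pytest.approx(-0.5, abs=1e-3)
        assert set(s_eq) == {"s", "s^2"}
        assert s_eq["s"] == pytest.approx(-0.5, abs=1e-3)
        assert s_eq["s^2"] == pytest.approx(-0.5, abs=1e-3)

    def test_invalid_arguments(self):
        ws = build_weak_system(_exp_trajectory(), K=50)
        with pytest.raises(ValueError):
            sr3_l1(ws, threshold=0.0)
        with pytest.raises(ValueError):
            sr3_l1(ws, threshold=0.1, max_iter=0)


class TestRSquared:
    def test_hand_examples(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, np.zeros(3)) == pytest.approx(-6.0)

    def test_zero_variance_flagged_as_minus_inf(self):
        assert r_squared(np.ones(5), np.ones(5)) == -np.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(4), np.ones(5))

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        pred = y + 0.3 * rng.normal(size=40)
        a = r_squared(y, pred)
        b = r_squared(scale * y + shift, scale * pred + shift)
        assert a == pytest.approx(b, rel=1e-9)


class TestIdentify:
    @pytest.mark.parametrize("coeffs, ic, t_end", [
        # (c-equation, s-equation) as {term: value}; stable polynomial
        # systems whose two variables follow distinct temporal shapes (a
        # trajectory with c(t) ~ s(t) is genuinely non-identifiable)
        (({"c": -1.5}, {"c": 0.5, "s": -0.2}), (1.0, 0.1), 15.0),
        (({"c": -0.4, "c^2": -0.2}, {"s": -1.2, "c*s": 0.3}), (1.2, 0.8), 8.0),
    ])
    def test_polynomial_fields_in_span_are_recovered(self, coeffs, ic, t_end):
        lib = CandidateLibrary()
        cols = np.zeros((len(lib), 2))
        for v, eq in enumerate(coeffs):
            for term, val in eq.items():
                cols[TERMS.index(term), v] = val

        def rhs(state, params):
            return lib.evaluate(np.asarray(state)) @ cols

        params = derive_constants(1.0, 0.0, 1.0, 10.0)  # unused by rhs
        traj = simulate(rhs, ic, t_end, 100, params)
        res = identify(traj)
        for v, eq in enumerate(coeffs):
            found = {TERMS[j]: res.coefficients[j, v]
                     for j in np.nonzero(res.coefficients[:, v])[0]}
            assert set(found) == set(eq)
            for term, val in eq.items():
                assert found[term] == pytest.approx(val, rel=1e-2)

    def test_case1_full_model_identified(self):
        res = identify(make_fixture("case1", "full"))
        c_eq = res.active_terms["c"]
        assert set(c_eq) == {"c", "s", "c*s"}
        assert c_eq["c"] == pytest.approx(-101.0, rel=0.02)
        assert c_eq["s"] == pytest.approx(5.0, rel=0.02)
        assert c_eq["c*s"] == pytest.approx(-10.0, rel=0.02)

    def test_case2_full_model_variance_fully_explained(self):
        res = identify(make_fixture("case2", "full"))
        assert round(min(res.r2), 1) == 1.0

    def test_case2_reduced_identified_exactly(self):
        res = identify(make_fixture("case2", "rQSSA"))
        assert res.active_terms["c"] == pytest.approx({"c": -0.5}, abs=1e-3)
        assert res.active_terms["s"] == pytest.approx(
            {"s": -0.5, "s^2": -0.5}, abs=1e-3)

    def test_composite_nonlinearity_defeats_polynomial_library(self):
        """The partial-equilibrium reduction has rational terms outside the
        library span; the fit of the complex equation must carry a negative
        variance-explained score (the failure signal the pipeline keys on)."""
        res = identify(make_fixture("case3", "PEA"))
        assert res.r2[0] < 0

    def test_multiplicative_noise_direct_fit_still_passes(self):
        """1% field-proportional noise leaves the weak-form fit of the
        single-regime reduced model usable (both equations' R^2 high)."""
        res = identify(make_fixture("case2", "rQSSA",
                                    NoiseSpec("multiplicative", 0.01, seed=6)))
        assert min(res.r2) > 0.5
        # the substrate equation keeps its true quadratic structure
        assert set(res.active_terms["s"]) == {"s", "s^2"}

    def test_sweep_log_is_complete(self):
        res = identify(make_fixture("case2", "rQSSA"))
        assert len(res.sweep) == 20
        assert res.summary().startswith("Weak-form sparse identification")
        d = res.to_dict()
        assert set(d) >= {"equations", "r2", "threshold", "sweep"}
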