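"""Deterministic and stochastic trajectory generation."""

import numpy as np
import pytest

from msid import (
    case_initial_state,
    case_parameters,
    case_t_end,
    full_rhs,
    make_fixture,
    reduced_rhs,
    simulate,
    simulate_noisy,
)
from msid.simulate import ConfigurationError, NoiseSpec, Trajectory


class TestDeterministic:
    def test_case2_reduced_complex_is_pure_exponential(self, case2_params):
        # dc/dt = -k2 c decouples, so c(t) = c0 exp(-0.5 t) exactly
        traj = make_fixture("case2", "rQSSA")
        np.testing.assert_allclose(traj.c, 910.0 * np.exp(-0.5 * traj.times),
                                   rtol=1e-7)

    def test_case1_substrate_decays_monotonically(self):
        traj = make_fixture("case1", "full")
        assert np.all(np.diff(traj.s) < 0)
        assert traj.s[-1] < 1e-2 * traj.s[0] * 1.05

    @pytest.mark.parametrize("case, ic", [
        ("case1", (0.045045, 1.0)),
        ("case2", (910.0, 10.11111)),
        ("case3", (9.999999, 10.0)),
    ])
    def test_fixture_initial_conditions(self, case, ic):
        traj = make_fixture(case, "full")
        np.testing.assert_allclose(traj.states[0], ic)
        assert len(traj) == 100

    @pytest.mark.parametrize("case, model", [
        ("case1", "full"), ("case1", "sQSSA"), ("case1", "PEA"),
        ("case2", "full"), ("case2", "rQSSA"),
        ("case3", "full"), ("case3", "PEA"),
    ])
    def test_states_stay_physical(self, case, model):
        traj = make_fixture(case, model)
        p = case_parameters(case)
        assert np.all(traj.c <= p.e0 + 1e-9)
        assert np.all(traj.c >= -1e-12)
        assert np.all(traj.s >= -1e-12)

    def test_invalid_case_model_combination(self):
        with pytest.raises(ConfigurationError):
            make_fixture("case1", "rQSSA")

    def test_two_point_grid_is_accepted(self, case1_params):
        traj = simulate(full_rhs, (0.045045, 1.0), 1.0, 2, case1_params)
        assert len(traj) == 2

    def test_fixtures_are_reproducible(self):
        a = make_fixture("case2", "full")
        b = make_fixture("case2", "full")
        np.testing.assert_array_equal(a.states, b.states)

    def test_csv_roundtrip_is_exact(self, tmp_path):
        traj = make_fixture("case1", "full")
        path = tmp_path / "t.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        np.testing.assert_array_equal(traj.times, back.times)
        np.testing.assert_array_equal(traj.states, back.states)
        np.testing.assert_array_equal(traj.fields, back.fields)


class TestStochastic:
    def test_zero_noise_fraction_matches_deterministic(self, case1_params):
        t_end = case_t_end("case1")
        det = simulate(full_rhs, case_initial_state("case1"), t_end, 50,
                       case1_params)
        noisy = simulate_noisy(case_initial_state("case1"), case1_params,
                               NoiseSpec("additive", 0.0, seed=1), t_end, 50)
        np.testing.assert_allclose(noisy.states, det.states, rtol=1e-3,
                                   atol=1e-8)

    def test_fixed_seed_reproducible(self, case1_params):
        spec = NoiseSpec("additive", 0.02, seed=9)
        a = make_fixture("case1", "full", spec)
        b = make_fixture("case1", "full", spec)
        np.testing.assert_array_equal(a.states, b.states)

    def test_additive_noise_is_unbiased(self, case3_params):
        """Zero-mean forcing: the ensemble mean tracks the deterministic
        path within Monte-Carlo error. Near the regime switch the noise
        jitters the switching time itself, skewing the local ensemble, so
        the bound there is a few percent of the state scale rather than
        pure Monte-Carlo error."""
        t_end = case_t_end("case3")
        ic = case_initial_state("case3")
        n = 40
        det = simulate(full_rhs, ic, t_end, n, case3_params)
        ens = simulate_noisy(ic, case3_params,
                             NoiseSpec("additive", 0.02, seed=4), t_end, n,
                             n_ensemble=200)
        states = np.stack([tr.states for tr in ens])       # (200, n, 2)
        mean = states.mean(axis=0)
        se = states.std(axis=0, ddof=1) / np.sqrt(states.shape[0])
        resid = np.abs(mean - det.states)
        # first-order unbiased; the drift's curvature leaves an O(sigma^2)
        # remainder, bounded here at 5e-4 of each variable's RMS scale
        scale = np.sqrt(np.mean(det.states**2, axis=0))
        within = resid <= 3 * se + 5e-4 * scale
        assert within.mean() >= 0.95
        assert np.all(resid <= 3 * se + 0.03 * scale)

    def test_noise_amplitude_scales_linearly_with_D(self, case1_params):
        t_end = case_t_end("case1")
        ic = case_initial_state("case1")
        det = simulate(full_rhs, ic, t_end, 100, case1_params)
        sds = []
        levels = [0.01, 0.02, 0.04]
        for D in levels:
            ens = simulate_noisy(ic, case1_params,
                                 NoiseSpec("additive", D, seed=11), t_end,
                                 100, n_ensemble=20)
            dev = np.stack([tr.states - det.states for tr in ens])
            sds.append(dev.std())
        r = np.corrcoef(levels, sds)[0, 1]
        assert r**2 > 0.95

    def test_multiplicative_noise_scales_with_the_field(self, case3_params):
        """Field-proportional noise vanishes where the dynamics are quiet
        (the complex is near steady state early on), while additive noise
        jitters quiet phases indiscriminately."""
        t_end = case_t_end("case3")
        ic = case_initial_state("case3")
        det = simulate(full_rhs, ic, t_end, 40, case3_params)
        early = det.times < 5.0   # c ~ const, dc/dt ~ 0

        def median_early_c_dev(kind, D, seed):
            ens = simulate_noisy(ic, case3_params, NoiseSpec(kind, D, seed),
                                 t_end, 40, n_ensemble=15)
            return np.median([np.max(np.abs(tr.c[early] - det.c[early]))
                              for tr in ens])

        add = median_early_c_dev("additive", 0.02, 21)
        mult = median_early_c_dev("multiplicative", 0.01, 22)
        assert mult < 0.2 * add

    def test_clip_counting(self, case1_params):
        traj = make_fixture("case1", "full",
                            NoiseSpec("additive", 0.3, seed=2))
        assert traj.meta["clip_count"] > 0
        assert np.all(traj.s >= 0) and np.all(traj.c <= case1_params.e0)

    def test_reduced_model_noisy_fixture(self):
        traj = make_fixture("case2", "rQSSA", NoiseSpec("additive", 0.02, 3))
        assert traj.fields is None
        assert len(traj) == 100
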