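import numpy as np
import pytest

from gaitgem import (
    ControllerConfig,
    NonpositiveStateError,
    check_belt_constraint,
    optimal_control_input,
    run_model_experiment,
    simulate,
    step,
)
from gaitgem.controllers import expected_cost

from oracles import brute_force_optimal_u, expected_cost_quadrature

PRESETS = ["MIP", "POP", "OVC"]


def random_states(rng, n):
    """States scattered around the operating point, on and off the GEM."""
    return np.column_stack(
        [1.105 + 0.2 * rng.standard_normal(n), 1.337 + 0.2 * rng.standard_normal(n)]
    )


class TestOptimalControlInput:
    @pytest.mark.parametrize("variant", PRESETS)
    def test_no_intervention_at_operating_point(self, variant):
        cfg = ControllerConfig.preset(variant)
        u = optimal_control_input(cfg.x_star, cfg)
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_mip_exerts_no_effort_anywhere_on_gem(self):
        cfg = ControllerConfig.preset("MIP")
        for T in (0.8, 1.105, 1.4):
            u = optimal_control_input(np.array([T, cfg.v * T]), cfg)
            np.testing.assert_allclose(u, 0.0, atol=1e-12)

    @pytest.mark.parametrize("variant", PRESETS)
    def test_expected_error_is_cancelled(self, variant):
        # the planned (unit-gain) expected next state lies exactly on the GEM
        cfg = ControllerConfig.preset(variant)
        rng = np.random.default_rng(1)
        for x in random_states(rng, 50):
            u = optimal_control_input(x, cfg)
            x_planned = x + u
            assert x_planned[1] - cfg.v * x_planned[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("variant", PRESETS)
    def test_matches_brute_force_expected_cost_minimum(self, variant):
        cfg = ControllerConfig.preset(variant)
        rng = np.random.default_rng(2)
        for x in random_states(rng, 200):
            u = optimal_control_input(x, cfg)
            u_oracle = brute_force_optimal_u(x, cfg)
            np.testing.assert_allclose(u, u_oracle, atol=1e-6)

    def test_analytic_expected_cost_matches_quadrature(self):
        cfg = ControllerConfig.preset("POP")
        rng = np.random.default_rng(3)
        for x in random_states(rng, 20):
            u = rng.standard_normal(2) * 0.05
            assert expected_cost(x, u, cfg) == pytest.approx(
                expected_cost_quadrature(x, u, cfg), rel=1e-10
            )


class TestStep:
    def test_without_control_and_noise_strides_repeat(self):
        cfg = ControllerConfig.preset("OVC")
        x = np.array([1.0, 1.3])
        np.testing.assert_array_equal(step(x, np.zeros(2), np.zeros(4), cfg), x)

    def test_unit_gains_zero_noise_add_control(self):
        cfg = ControllerConfig.preset("POP")
        x = np.array([1.0, 1.3])
        u = np.array([0.02, -0.01])
        np.testing.assert_allclose(step(x, u, np.zeros(4), cfg), x + u)

    def test_gains_scale_executed_control(self):
        cfg = ControllerConfig.preset("OVC")  # g1 = g2 = 1.24
        x = np.array([1.0, 1.3])
        u = np.array([0.02, -0.01])
        np.testing.assert_allclose(step(x, u, np.zeros(4), cfg), x + 1.24 * u)

    def test_nonpositive_state_aborts(self):
        cfg = ControllerConfig.preset("POP")
        with pytest.raises(NonpositiveStateError):
            step(np.array([0.01, 1.3]), np.zeros(2), np.array([0, 0, -5.0, 0]), cfg)


class TestSimulate:
    def test_zero_noise_run_is_constant_at_operating_point(self):
        cfg = ControllerConfig.preset(
            "OVC", sigma_mult=(0.0, 0.0), sigma_add=(0.0, 0.0), n_strides=50
        )
        series = simulate(cfg)
        np.testing.assert_allclose(series.T, cfg.Tstar, atol=1e-14)
        np.testing.assert_allclose(series.L, cfg.Lstar, atol=1e-14)

    def test_fixed_seed_is_bitwise_reproducible(self):
        cfg = ControllerConfig.preset("OVC", n_strides=100, seed=11)
        a = simulate(cfg, rep_index=3)
        b = simulate(cfg, rep_index=3)
        np.testing.assert_array_equal(a.T, b.T)
        np.testing.assert_array_equal(a.L, b.L)

    def test_reps_are_distinct_streams(self):
        cfg = ControllerConfig.preset("OVC", n_strides=100, seed=11)
        a = simulate(cfg, rep_index=0)
        b = simulate(cfg, rep_index=1)
        assert not np.array_equal(a.T, b.T)


@pytest.fixture(scope="module")
def mip_result():
    return run_model_experiment(ControllerConfig.preset("MIP", seed=1))


class TestModelExperiments:
    def test_mip_variance_concentrates_along_gem(self, mip_result):
        agg = mip_result.aggregate
        assert agg["sd_delta_T"] / agg["sd_delta_P"] > 3.0
        assert agg["anova_sd"]["p"] < 1e-6

    def test_mip_tangent_deviations_are_brownian(self, mip_result):
        assert mip_result.aggregate["alpha_delta_T"] == pytest.approx(1.5, abs=0.1)
        assert mip_result.aggregate["alpha_delta_P"] == pytest.approx(0.5, abs=0.1)

    def test_belt_enforcement_reports_attempts(self, mip_result):
        per_rep = mip_result.per_rep
        assert per_rep["belt_ok"].all()
        assert (per_rep["max_dnet"] <= 0.864).all()
        assert (per_rep["min_dnet"] >= -0.864).all()
        assert mip_result.aggregate["total_attempts"] >= 20

    def test_gain_monotonically_tunes_anti_persistence(self):
        # over-correcting gains (g > 1) push alpha(delta_P) below 1/2,
        # under-correcting gains (g < 1) above
        means = []
        for g in (0.8, 1.0, 1.24):
            cfg = ControllerConfig.preset("POP", g1=g, g2=g, seed=4, n_reps=10)
            res = run_model_experiment(cfg)
            means.append(res.aggregate["alpha_delta_P"])
        assert means[0] > means[1] > means[2]
        assert means[1] == pytest.approx(0.5, abs=0.1)

    def test_most_raw_ovc_runs_stay_on_belt(self):
        # belt compliance is common enough for rejection to converge fast:
        # raw (unenforced) OVC runs stay within the half-belt bound ~93% of
        # the time at the printed noise amplitudes
        cfg = ControllerConfig.preset("OVC", seed=8)
        ok = [
            check_belt_constraint(simulate(cfg, rep_index=r)).ok for r in range(40)
        ]
        assert np.mean(ok) >= 0.8


class TestConfigValidation:
    def test_pop_operating_point_lies_on_gem(self):
        cfg = ControllerConfig.preset("POP")
        assert cfg.Lstar == pytest.approx(cfg.v * cfg.Tstar)

    def test_non_coercive_cost_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(variant="MIP", w_p=0.0, w_u1=0.0, w_u2=0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig.preset("XYZ")
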