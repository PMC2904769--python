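import numpy as np
import pytest

from gaitgem import (
    DegenerateSeriesError,
    InvalidSeriesError,
    StrideSeries,
    decompose,
    fit_gem_frame,
    reconstruct,
)
from gaitgem.dfa import dfa
from gaitgem.gem import GemFrame


def make(T, L, v=1.21):
    return StrideSeries(T=np.asarray(T, float), L=np.asarray(L, float), v=v)


class TestFitGemFrame:
    def test_symmetric_scales_give_diagonal_basis(self, rng):
        # equal SDs at v=1 put the GEM at 45 degrees in normalized coordinates
        base = rng.standard_normal(200)
        s = make(1.5 + 0.1 * base, 1.5 + 0.1 * base[::-1], v=1.0)
        frame = fit_gem_frame(s)
        assert frame.m_hat == pytest.approx(1.0)
        np.testing.assert_allclose(frame.e_T, [1, 1] / np.sqrt(2))
        np.testing.assert_allclose(frame.e_P, [-1, 1] / np.sqrt(2))

    def test_basis_is_orthonormal_and_forward(self, humanlike_trial):
        frame = fit_gem_frame(humanlike_trial)
        assert np.linalg.norm(frame.e_T) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(frame.e_P) == pytest.approx(1.0, abs=1e-12)
        assert abs(frame.e_T @ frame.e_P) < 1e-12
        assert (frame.e_T > 0).all()  # tangent points toward longer, slower strides

    def test_slope_matches_independent_recomputation(self, humanlike_trial):
        frame = fit_gem_frame(humanlike_trial)
        sd = lambda x: (np.sum((x - x.mean()) ** 2) / (len(x) - 1)) ** 0.5
        expected = humanlike_trial.v * sd(humanlike_trial.T) / sd(humanlike_trial.L)
        assert frame.m_hat == pytest.approx(expected, rel=1e-12)

    def test_constant_series_is_degenerate(self):
        s = make(np.full(10, 1.1), 1.3 + 0.01 * np.arange(10))
        with pytest.raises(DegenerateSeriesError):
            fit_gem_frame(s)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidSeriesError):
            fit_gem_frame(make([1.0, 1.1], [1.2, 1.3]))

    def test_json_round_trip(self, humanlike_trial):
        frame = fit_gem_frame(humanlike_trial)
        back = GemFrame.from_json(frame.to_json())
        np.testing.assert_allclose(back.e_T, frame.e_T)
        assert back.m_hat == frame.m_hat


class TestDecompose:
    def test_operating_point_maps_to_origin(self, random_series):
        frame = fit_gem_frame(random_series)
        dev = decompose(
            StrideSeries(T=np.full(3, frame.Tstar), L=np.full(3, frame.Lstar),
                         v=random_series.v),
            frame,
        )
        np.testing.assert_allclose(dev.delta_T, 0.0, atol=1e-12)
        np.testing.assert_allclose(dev.delta_P, 0.0, atol=1e-12)

    def test_on_gem_strides_have_zero_perpendicular_deviation(self, rng):
        T = 1.1 + 0.05 * rng.standard_normal(100)
        s = make(T, 1.21 * T)
        frame = fit_gem_frame(s, operating_point="projected-to-gem")
        dev = decompose(s, frame)
        np.testing.assert_allclose(dev.delta_P, 0.0, atol=1e-10)

    def test_perpendicular_deviation_matches_point_to_line_oracle(self, random_series):
        frame = fit_gem_frame(random_series)
        dev = decompose(random_series, frame)
        # signed distance from normalized point to the line L' = m_hat * T'
        Tp = (random_series.T - frame.Tstar) / frame.sigma_T
        Lp = (random_series.L - frame.Lstar) / frame.sigma_L
        oracle = (Lp - frame.m_hat * Tp) / np.sqrt(1 + frame.m_hat**2)
        np.testing.assert_allclose(dev.delta_P, oracle, rtol=1e-12, atol=1e-12)

    def test_positive_delta_p_means_faster_than_belt(self, random_series):
        frame = fit_gem_frame(random_series, operating_point="projected-to-gem")
        fast = StrideSeries(T=np.full(3, 1.0), L=np.full(3, 1.3), v=1.21)
        assert (decompose(fast, frame).delta_P > 0).all()

    def test_rotation_preserves_normalized_dispersion(self, humanlike_trial):
        # Var(delta_T) + Var(delta_P) = 2 under unit-variance normalization
        frame = fit_gem_frame(humanlike_trial)
        dev = decompose(humanlike_trial, frame)
        total = np.var(dev.delta_T, ddof=1) + np.var(dev.delta_P, ddof=1)
        assert total == pytest.approx(2.0, abs=1e-9)

    def test_operating_point_choice_shifts_delta_p_by_a_constant(self, humanlike_trial):
        f1 = fit_gem_frame(humanlike_trial, operating_point="sample-mean")
        f2 = fit_gem_frame(humanlike_trial, operating_point="projected-to-gem")
        d1 = decompose(humanlike_trial, f1)
        d2 = decompose(humanlike_trial, f2)
        diff = d1.delta_P - d2.delta_P
        np.testing.assert_allclose(diff, diff[0], atol=1e-10)
        assert np.std(d1.delta_P, ddof=1) == pytest.approx(
            np.std(d2.delta_P, ddof=1), abs=1e-12
        )
        assert dfa(d1.delta_P).alpha == pytest.approx(dfa(d2.delta_P).alpha, abs=1e-9)

    def test_common_rescaling_leaves_deviations_unchanged(self, random_series):
        frame = fit_gem_frame(random_series)
        dev = decompose(random_series, frame)
        scaled = StrideSeries(T=10 * random_series.T, L=10 * random_series.L,
                              v=random_series.v)
        frame_scaled = fit_gem_frame(scaled)
        dev_scaled = decompose(scaled, frame_scaled)
        np.testing.assert_allclose(dev_scaled.delta_T, dev.delta_T, atol=1e-10)
        np.testing.assert_allclose(dev_scaled.delta_P, dev.delta_P, atol=1e-10)


class TestReconstruct:
    def test_round_trip_series_to_deviations_and_back(self, humanlike_trial):
        frame = fit_gem_frame(humanlike_trial)
        dev = decompose(humanlike_trial, frame)
        back = reconstruct(dev)
        np.testing.assert_allclose(back.T, humanlike_trial.T, atol=1e-10)
        np.testing.assert_allclose(back.L, humanlike_trial.L, atol=1e-10)
        dev2 = decompose(back, frame)
        np.testing.assert_allclose(dev2.delta_T, dev.delta_T, atol=1e-10)
        np.testing.assert_allclose(dev2.delta_P, dev.delta_P, atol=1e-10)

    def test_origin_maps_to_operating_point(self, random_series):
        frame = fit_gem_frame(random_series)
        from gaitgem.gem import GemDeviations

        s = reconstruct(GemDeviations(np.zeros(1), np.zeros(1), frame))
        assert s.T[0] == pytest.approx(frame.Tstar)
        assert s.L[0] == pytest.approx(frame.Lstar)

    def test_unit_perpendicular_step_has_unit_normalized_length(self, random_series):
        frame = fit_gem_frame(random_series)
        from gaitgem.gem import GemDeviations

        s = reconstruct(GemDeviations(np.zeros(1), np.ones(1), frame))
        dT_norm = (s.T[0] - frame.Tstar) / frame.sigma_T
        dL_norm = (s.L[0] - frame.Lstar) / frame.sigma_L
        assert np.hypot(dT_norm, dL_norm) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose([dT_norm, dL_norm], frame.e_P, atol=1e-12)
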