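import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vertebeam as vb
from vertebeam.coherence import (KernelSpec, build_tv_operators, coherence_stack,
                                 lwslsc_hessian, lwslsc_image, slsc_image,
                                 solve_lag_weights, verify_objective_equivalence)
from vertebeam.io_core import ValidationError


def brute_force_simplex_min(H, step=0.01):
    """Exhaustive 3-lag simplex grid search of w^T H w (test oracle)."""
    best = np.inf
    for w1 in np.arange(0, 1 + step / 2, step):
        for w2 in np.arange(0, 1 - w1 + step / 2, step):
            w = np.array([w1, w2, 1.0 - w1 - w2])
            if w[2] < -1e-12:
                continue
            w[2] = max(w[2], 0.0)
            best = min(best, float(w @ H @ w))
    return best


class TestCoherenceStack:
    def test_identical_channels_fully_coherent(self):
        rng = np.random.default_rng(0)
        ap = np.tile(rng.standard_normal((64, 1, 1)), (1, 3, 8))
        st_ = coherence_stack(ap, n_lags=4, kernel_length=16)
        assert np.allclose(st_.values, 1.0, atol=1e-12)

    def test_alternating_sign_channels(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(64)
        ap = np.stack([s * (-1) ** i for i in range(8)], axis=-1)[:, None, :]
        st_ = coherence_stack(ap, n_lags=2, kernel_length=16)
        assert np.allclose(st_.values[:, :, 0], -1.0, atol=1e-12)
        assert np.allclose(st_.values[:, :, 1], 1.0, atol=1e-12)

    def test_white_noise_mean_near_zero(self):
        """Monte-Carlo: i.i.d. channels give |mean R(m)| < 0.05 per lag."""
        rng = np.random.default_rng(42)
        ap = rng.standard_normal((1016, 1, 16))
        st_ = coherence_stack(ap, n_lags=5, kernel_length=16)
        means = st_.values[8:-8, 0, :].mean(axis=0)  # ~1000 interior pixels
        assert np.all(np.abs(means) < 0.05)

    def test_all_zero_pixel_is_exactly_zero(self):
        ap = np.zeros((32, 2, 8))
        st_ = coherence_stack(ap, n_lags=3, kernel_length=8)
        assert np.all(st_.values == 0.0)

    def test_too_many_lags_rejected(self):
        with pytest.raises(ValidationError):
            coherence_stack(np.zeros((16, 1, 4)), n_lags=4, kernel_length=4)

    def test_bounded_by_cauchy_schwarz(self):
        rng = np.random.default_rng(3)
        ap = rng.standard_normal((128, 4, 12)) * rng.lognormal(size=(1, 1, 12))
        st_ = coherence_stack(ap, n_lags=6, kernel_length=10)
        assert np.all(np.abs(st_.values) <= 1.0)


class TestSlscImage:
    def _stack(self, values):
        from vertebeam.coherence import CoherenceStack
        return CoherenceStack(values=values, kernel_length=8,
                              n_lags=values.shape[-1])

    def test_all_ones_sum_to_m(self):
        st_ = self._stack(np.ones((4, 4, 12)))
        img = slsc_image(st_, m_lag=9)
        assert np.allclose(img.linear_amplitude, 9.0)

    def test_triangle_partial_sum_closed_form(self):
        """R(m) = 1 - m/64 summed over m=1..5 equals 5 - 15/64."""
        m = np.arange(1, 29)
        vals = np.tile(1.0 - m / 64.0, (3, 3, 1))
        img = slsc_image(self._stack(vals), m_lag=5)
        assert np.allclose(img.linear_amplitude, 4.765625, atol=1e-12)

    def test_noise_stack_clamped_mean(self):
        """Clamped all-noise image mean matches the half-normal oracle."""
        rng = np.random.default_rng(7)
        sigma = 0.05
        vals = rng.normal(0.0, sigma, size=(40, 40, 10))
        img = slsc_image(self._stack(vals), m_lag=4)
        # sum of 4 lags ~ N(0, sigma*2); clamp -> mean = sigma*2/sqrt(2*pi)
        expect = sigma * 2 / np.sqrt(2 * np.pi)
        assert img.linear_amplitude.mean() == pytest.approx(expect, rel=0.1)

    def test_monotone_in_m_for_nonnegative_stacks(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, size=(6, 6, 8))
        st_ = self._stack(vals)
        sums = [slsc_image(st_, m).linear_amplitude for m in range(1, 9)]
        for a, b in zip(sums, sums[1:]):
            assert np.all(b >= a - 1e-12)


class TestTVOperators:
    def test_three_lag_difference_matrix(self):
        ops = build_tv_operators(3, 2, 2, 0.5)
        np.testing.assert_array_equal(ops.D, [[-1, 1, 0], [0, -1, 1]])

    def test_b_dimensions_2x2(self):
        ops = build_tv_operators(3, 2, 2, 0.5)
        assert ops.B.shape == (4, 4)  # 2*2*2 - 2 - 2 rows

    def test_operators_annihilate_constants(self):
        ops = build_tv_operators(6, 4, 3, 1.0)
        assert np.allclose(ops.D @ np.ones(6), 0)
        assert np.allclose(ops.B @ np.ones(12), 0)

    def test_rows_have_one_plus_minus_pair(self):
        ops = build_tv_operators(5, 3, 4, 1.0)
        for M in (ops.D, ops.B):
            assert np.all((M == 0).sum(axis=1) == M.shape[1] - 2)
            assert np.all(M.sum(axis=1) == 0)
            assert np.all(np.abs(M).sum(axis=1) == 2)

    def test_penalty_hessian_psd(self):
        ops = build_tv_operators(8, 3, 3, 0.7)
        evals = np.linalg.eigvalsh(ops.H_penalty)
        assert np.all(evals >= -1e-12)
        assert np.allclose(ops.H_penalty, 0.49 * ops.D.T @ ops.D)


class TestObjectiveEquivalence:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_direct_and_quadratic_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        ops = build_tv_operators(5, 4, 4, rng.uniform(0, 2))
        K = rng.standard_normal((16, 5))
        w = rng.dirichlet(np.ones(5))
        a, b = verify_objective_equivalence(K, ops, w)
        assert b == pytest.approx(a, rel=1e-10, abs=1e-14)

    def test_zero_weights_zero_objective(self):
        ops = build_tv_operators(5, 4, 4, 0.3)
        a, b = verify_objective_equivalence(np.ones((16, 5)), ops, np.zeros(5))
        assert a == 0.0 and b == 0.0

    def test_alpha_zero_reduces_to_fidelity(self):
        rng = np.random.default_rng(5)
        ops = build_tv_operators(5, 4, 4, 0.0)
        K = rng.standard_normal((16, 5))
        w = rng.dirichlet(np.ones(5))
        a, _ = verify_objective_equivalence(K, ops, w)
        assert a == pytest.approx(float(np.sum((ops.B @ K @ w) ** 2)), rel=1e-12)


class TestSolveLagWeights:
    def test_penalty_dominated_limit_is_uniform(self):
        rng = np.random.default_rng(0)
        ops = build_tv_operators(6, 3, 3, 1e6)
        for _ in range(5):
            K = rng.standard_normal((9, 6))
            res = solve_lag_weights(K, ops)
            assert np.max(np.abs(res.w - 1 / 6)) < 1e-3

    def test_constant_lag_slice_takes_all_weight(self):
        """With a spatially constant lag-1 slice, a varying lag-2 slice and
        alpha = 0, the vertex w = (1, 0) achieves objective exactly 0."""
        rng = np.random.default_rng(1)
        ops = build_tv_operators(2, 3, 3, 0.0)
        K = np.column_stack([np.full(9, 0.7), rng.standard_normal(9)])
        res = solve_lag_weights(K, ops)
        assert res.w[0] == pytest.approx(1.0, abs=1e-4)
        assert res.objective == pytest.approx(0.0, abs=1e-6)

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(2)
        ops = build_tv_operators(3, 3, 3, 0.1)
        for _ in range(5):
            K = rng.standard_normal((9, 3))
            res = solve_lag_weights(K, ops)
            H = lwslsc_hessian(K, ops)
            assert res.w @ H @ res.w <= brute_force_simplex_min(H) + 1e-4

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_simplex_constraints_always_hold(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        ops = build_tv_operators(n, 3, 3, rng.uniform(0, 3))
        K = rng.standard_normal((9, n)) * rng.lognormal()
        res = solve_lag_weights(K, ops)
        assert res.w.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(res.w >= -1e-9) and np.all(res.w <= 1 + 1e-9)

    def test_beats_uniform_and_vertices(self):
        rng = np.random.default_rng(4)
        ops = build_tv_operators(5, 4, 4, 0.2)
        for _ in range(5):
            K = rng.standard_normal((16, 5))
            H = lwslsc_hessian(K, ops)
            res = solve_lag_weights(K, ops)
            obj = res.w @ H @ res.w
            assert obj <= np.full(5, 0.2) @ H @ np.full(5, 0.2) + 1e-8
            for m in range(5):
                e = np.zeros(5)
                e[m] = 1.0
                assert obj <= e @ H @ e + 1e-8

    def test_degenerate_kernel_gives_uniform(self):
        ops = build_tv_operators(4, 3, 3, 0.0)
        res = solve_lag_weights(np.zeros((9, 4)), ops)
        assert np.allclose(res.w, 0.25)
        assert res.objective == 0.0


class TestLwslscImage:
    def _stack(self, values):
        from vertebeam.coherence import CoherenceStack
        return CoherenceStack(values=values, kernel_length=8,
                              n_lags=values.shape[-1])

    def test_all_ones_stack_gives_ones(self):
        st_ = self._stack(np.ones((12, 10, 5)))
        ops = build_tv_operators(5, 4, 4, 0.12)
        img = lwslsc_image(st_, KernelSpec(kz=4, kx=4, overlap=0.5), ops)
        assert np.allclose(img.linear_amplitude, 1.0, atol=1e-6)

    def test_non_overlapping_kernels_are_local(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (8, 8, 4))
        st_ = self._stack(vals)
        ops = build_tv_operators(4, 4, 4, 0.5)
        spec = KernelSpec(kz=4, kx=4, overlap=0.0)
        img = lwslsc_image(st_, spec, ops)
        # each pixel is covered by exactly one kernel: recompute block 0,0
        km = vals[:4, :4, :].reshape(16, 4, order="F")
        w = solve_lag_weights(km, ops).w
        np.testing.assert_allclose(img.raw[:4, :4], vals[:4, :4, :] @ w, rtol=1e-9)

    def test_uniform_weight_override_matches_scaled_slsc(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(-0.2, 1, (10, 9, 6))
        st_ = self._stack(vals)
        ops = build_tv_operators(6, 3, 3, 0.12)
        img = lwslsc_image(st_, KernelSpec(kz=3, kx=3, overlap=0.5), ops,
                           weights_override=np.full(6, 1 / 6))
        slsc = slsc_image(st_, m_lag=6)
        np.testing.assert_allclose(img.raw, slsc.raw / 6.0, rtol=1e-9, atol=1e-12)

    def test_kernel_larger_than_image_rejected(self):
        st_ = self._stack(np.ones((3, 3, 4)))
        ops = build_tv_operators(4, 8, 8, 0.1)
        with pytest.raises(ValidationError):
            lwslsc_image(st_, KernelSpec(kz=8, kx=8, overlap=0.5), ops)


def test_kernel_spec_mm_conversion():
    grid = vb.ImageGrid.from_extent(-5, 5, 10, 30, 0.3, 0.04)
    spec = KernelSpec.from_mm(1.92, 1.20, grid, overlap=0.5)
    assert spec.kz == 48 and spec.kx == 4
    assert spec.stride == (24, 2)
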