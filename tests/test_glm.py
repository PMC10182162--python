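import numpy as np
import pytest
import statsmodels.api as sm

from channeltrend import (bernoulli_loglik, build_design_matrix, fit_single_glm,
                          make_cosine_basis, simulate_spikes_from_glm)
from channeltrend._exceptions import InvalidInputError
from channeltrend.glm import DesignMatrix, GLMParams
from conftest import make_glm_dataset


class TestDesignMatrix:
    def test_zero_stimulus_gives_zero_stimulus_columns(self, small_bases):
        bK, bH = small_bases
        spikes = np.zeros((2, 100), dtype=int)
        spikes[:, 40] = 1
        d = build_design_matrix(np.zeros((2, 100)), spikes, bK, bH)
        assert np.all(d.X[:, :bK.n_bases] == 0.0)

    def test_baseline_column_is_ones(self, small_bases):
        bK, bH = small_bases
        d = build_design_matrix(np.zeros((1, 50)), np.zeros((1, 50), dtype=int), bK, bH)
        np.testing.assert_array_equal(d.X[:, bK.n_bases], 1.0)

    def test_single_spike_history_impulse_response(self, small_bases):
        bK, bH = small_bases
        spikes = np.zeros((1, 80), dtype=int)
        spikes[0, 10] = 1
        d = build_design_matrix(np.zeros((1, 80)), spikes, bK, bH)
        hist = d.X[:, bK.n_bases + 1:]
        for m in range(bH.n_bases):
            for lag in range(1, 30):
                assert hist[10 + lag, m] == pytest.approx(bH.matrix[m, lag - 1])
        # strictly causal: nothing at or before the spike bin
        assert np.all(hist[:11] == 0.0)

    def test_matches_naive_double_loop_convolution(self, small_bases):
        bK, bH = small_bases
        rng = np.random.Generator(np.random.PCG64(2))
        stim = rng.standard_normal((1, 200))
        spikes = (rng.random((1, 200)) < 0.1).astype(int)
        d = build_design_matrix(stim, spikes, bK, bH)
        for m in range(bK.n_bases):
            naive = np.zeros(200)
            for j in range(200):
                for t in range(len(bK.matrix[m])):
                    if j - t >= 0:
                        naive[j] += bK.matrix[m, t] * stim[0, j - t]
            np.testing.assert_allclose(d.X[:, m], naive, atol=1e-12)

    def test_trial_boundaries_reset_history(self, small_bases):
        bK, bH = small_bases
        spikes = np.zeros((2, 60), dtype=int)
        spikes[0, 55] = 1  # late spike in trial 0 must not leak into trial 1
        d = build_design_matrix(np.zeros((2, 60)), spikes, bK, bH)
        hist = d.X[:, bK.n_bases + 1:]
        assert np.all(hist[60:] == 0.0)

    def test_history_columns_ignore_future_spikes(self, small_bases):
        # causality: shuffling spikes after bin j leaves columns at j unchanged
        bK, bH = small_bases
        rng = np.random.Generator(np.random.PCG64(3))
        spikes = (rng.random((1, 120)) < 0.15).astype(int)
        d1 = build_design_matrix(np.zeros((1, 120)), spikes, bK, bH)
        j = 60
        shuffled = spikes.copy()
        shuffled[0, j:] = shuffled[0, j:][::-1]
        d2 = build_design_matrix(np.zeros((1, 120)), shuffled, bK, bH)
        np.testing.assert_allclose(d1.X[:j + 1, bK.n_bases + 1:],
                                   d2.X[:j + 1, bK.n_bases + 1:])

    def test_shape_mismatch_rejected(self, small_bases):
        bK, bH = small_bases
        with pytest.raises(InvalidInputError):
            build_design_matrix(np.zeros((2, 100)), np.zeros((2, 90), dtype=int), bK, bH)


class TestLoglik:
    def test_zero_coefficients_give_minus_T_log2(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.3, 0, 0, -2.0, -1.0, 0, 0], seed=4)
        ll = bernoulli_loglik(np.zeros(d.n_params), d, with_grad=False)
        assert ll == pytest.approx(-d.n_obs * np.log(2.0), rel=1e-12)

    def test_gradient_at_zero_closed_form(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.3, 0, 0, -2.0, -1.0, 0, 0], seed=5)
        _, grad = bernoulli_loglik(np.zeros(d.n_params), d)
        np.testing.assert_allclose(grad, d.X.T @ (d.y - 0.5), atol=1e-10)

    def test_gradient_matches_finite_differences(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.5, -0.2, 0, -2.2, -1.5, 0.3, 0],
                                   n_trials=2, n_bins=150, seed=6)
        beta = np.array([0.4, -0.1, 0.2, -1.8, -0.9, 0.1, -0.3])
        _, grad = bernoulli_loglik(beta, d)
        eps = 1e-6
        for q in range(len(beta)):
            e = np.zeros_like(beta)
            e[q] = eps
            fd = (bernoulli_loglik(beta + e, d, with_grad=False)
                  - bernoulli_loglik(beta - e, d, with_grad=False)) / (2 * eps)
            assert grad[q] == pytest.approx(fd, abs=1e-5 * max(1, abs(fd)))

    def test_numerically_stable_at_extreme_logits(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.3, 0, 0, -2.0, -1.0, 0, 0], seed=7)
        beta = np.full(d.n_params, 50.0)
        ll = bernoulli_loglik(beta, d, with_grad=False)
        assert np.isfinite(ll)

    def test_non_binary_response_rejected(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.3, 0, 0, -2.0, -1.0, 0, 0], seed=8)
        bad = DesignMatrix(X=d.X, y=d.y + 0.5, d_K=d.d_K, d_H=d.d_H,
                           n_trials=d.n_trials, n_bins=d.n_bins)
        with pytest.raises(InvalidInputError):
            bernoulli_loglik(np.zeros(d.n_params), bad)


class TestFitSingleGLM:
    def test_intercept_only_recovers_logit_rate(self):
        rng = np.random.Generator(np.random.PCG64(9))
        y = (rng.random(5000) < 0.12).astype(float)
        d = DesignMatrix(X=np.ones((5000, 1)), y=y, d_K=0, d_H=0, n_trials=1,
                         n_bins=5000)
        fit = fit_single_glm(d)
        r = y.mean()
        assert fit.beta_baseline == pytest.approx(np.log(r / (1 - r)), abs=1e-8)

    def test_matches_independent_logistic_solver(self, small_bases):
        _, _, d = make_glm_dataset(small_bases, [0.6, 0.2, -0.1, -2.3, -1.4, 0.2, 0],
                                   n_trials=4, n_bins=600, seed=10)
        mine = fit_single_glm(d).vector
        oracle = sm.Logit(d.y, d.X).fit(disp=0, method="newton").params
        np.testing.assert_allclose(mine, oracle, atol=1e-5)

    def test_recovers_truth_within_three_se(self, small_bases):
        truth = np.array([0.7, 0.3, -0.2, -2.5, -2.0, -0.6, 0.3])
        _, _, d = make_glm_dataset(small_bases, truth, n_trials=10, n_bins=30_000,
                                   seed=11)
        fit = fit_single_glm(d)
        res = sm.Logit(d.y, d.X).fit(disp=0, method="newton")
        se = res.bse
        assert np.all(np.abs(fit.vector - truth) < 3.0 * se)

    def test_all_zero_response_rejected(self, small_bases):
        bK, bH = small_bases
        d = build_design_matrix(np.zeros((1, 100)), np.zeros((1, 100), dtype=int),
                                bK, bH)
        with pytest.raises(InvalidInputError):
            fit_single_glm(d)


class TestSimulator:
    def test_baseline_only_gives_half_spike_fraction(self, small_bases):
        bK, bH = small_bases
        params = GLMParams(np.zeros(3), 0.0, np.zeros(3))
        spikes = simulate_spikes_from_glm(params, bK, bH, np.zeros((1, 10_000)), seed=12)
        frac = spikes.mean()
        assert abs(frac - 0.5) < 3.0 * np.sqrt(0.25 / 10_000)

    def test_hard_refractory_history_blocks_short_isis(self):
        bK = make_cosine_basis("stimulus", n_bases=2, span=20)
        bH = make_cosine_basis("history", n_bases=2, span=20)
        # first history basis covers lags 1-5 ms; make it prohibitively negative
        params = GLMParams(np.zeros(2), 0.0, np.array([-200.0, 0.0]))
        h = params.history_filter(bH)
        assert np.all(h[:5] <= -20.0)
        spikes = simulate_spikes_from_glm(params, bK, bH, np.zeros((1, 5000)), seed=13)
        isis = np.diff(np.flatnonzero(spikes[0]))
        blocked = np.flatnonzero(h <= -20.0)[-1] + 1
        assert spikes.sum() > 10
        assert np.all(isis > blocked)

    def test_reproducible_by_seed(self, small_bases):
        bK, bH = small_bases
        params = GLMParams(np.array([0.5, 0, 0]), -2.0, np.array([-3.0, 0, 0]))
        rng = np.random.Generator(np.random.PCG64(14))
        stim = rng.standard_normal((3, 400))
        a = simulate_spikes_from_glm(params, bK, bH, stim, seed=99)
        b = simulate_spikes_from_glm(params, bK, bH, stim, seed=99)
        np.testing.assert_array_equal(a, b)


def test_filter_reconstruction_consistency(small_bases):
    bK, bH = small_bases
    params = GLMParams(np.array([1.0, -0.5, 0.2]), -2.0, np.array([0.3, 0.1, -0.2]))
    np.testing.assert_allclose(params.stimulus_filter(bK),
                               params.beta_stim @ bK.matrix)
    np.testing.assert_allclose(params.history_filter(bH),
                               params.beta_hist @ bH.matrix)


def test_params_vector_round_trip():
    vec = np.arange(7.0)
    p = GLMParams.from_vector(vec, 3, 3)
    np.testing.assert_array_equal(p.vector, vec)
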