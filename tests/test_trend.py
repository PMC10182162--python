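import numpy as np
import pytest

from channeltrend import (build_lambda_grid, compute_lambda_max, fit_joint,
                          fit_lambda_path, joint_objective, select_lambda,
                          split_trials)
from channeltrend._exceptions import InvalidInputError, InvalidParameterError
from channeltrend.glm import fit_single_glm
from channeltrend.trend import ConductanceGrid, LambdaPath, pooled_design
from conftest import make_glm_dataset
from helpers import bisect_lambda_max, generic_convex_objective


class TestConductanceGrid:
    def test_weights_are_inverse_gaps(self):
        g = ConductanceGrid(np.array([0.5, 1.0, 2.0, 4.0]))
        np.testing.assert_allclose(g.weights, [2.0, 1.0, 0.5])

    @pytest.mark.parametrize("factors", [[1.0], [2.0, 1.0], [0.0, 1.0], [-1.0, 1.0]])
    def test_invalid_grids_rejected(self, factors):
        with pytest.raises(InvalidParameterError):
            ConductanceGrid(np.array(factors))


class TestJointObjective:
    def test_lambda_zero_is_sum_of_nll(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        coeffs = np.zeros((3, designs[0].n_params))
        expect = sum(d.n_obs for d in designs) * np.log(2.0)
        assert joint_objective(coeffs, designs, grid, 0.0) == pytest.approx(expect)

    def test_equal_rows_have_zero_penalty(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        coeffs = np.tile(np.linspace(-1, 1, designs[0].n_params), (3, 1))
        a = joint_objective(coeffs, designs, grid, 0.0)
        b = joint_objective(coeffs, designs, grid, 1e6)
        assert a == pytest.approx(b)

    def test_penalty_matches_hand_computation(self):
        # B=3 conditions, hand-set rows; the likelihood part cancels when
        # comparing the objective at two lambda values
        grid = ConductanceGrid(np.array([1.0, 2.0, 4.0]))
        from channeltrend.basis import make_cosine_basis
        from channeltrend.glm import build_design_matrix
        bK = make_cosine_basis("stimulus", n_bases=1, span=10)
        bH = make_cosine_basis("history", n_bases=0 + 1, span=10)
        spikes = np.zeros((1, 50), dtype=int)
        spikes[0, 25] = 1
        design = build_design_matrix(np.zeros((1, 50)), spikes, bK, bH)
        designs = [design, design, design]
        coeffs = np.array([[0.0, 1.0, 0.0],
                           [2.0, 1.0, 0.0],
                           [2.0, 4.0, 1.0]])
        # hand evaluation: w = (1, 1/2);
        # pair 1: |0-2| * 1 = 2 ; pair 2: (|2-2| + |1-4| + |0-1|) * 1/2 = 2
        lam = 3.0
        base = joint_objective(coeffs, designs, grid, 0.0)
        assert joint_objective(coeffs, designs, grid, lam) == pytest.approx(
            base + lam * 4.0)

    def test_mismatched_counts_rejected(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        with pytest.raises(InvalidInputError):
            joint_objective(np.zeros((2, designs[0].n_params)), designs[:2], grid, 0.0)


class TestFitJoint:
    def test_lambda_zero_matches_independent_mles(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        fit = fit_joint(designs, grid, 0.0)
        independent = np.array([fit_single_glm(d).vector for d in designs])
        assert fit.converged
        np.testing.assert_allclose(fit.coeffs, independent, atol=1e-4)

    def test_huge_lambda_matches_pooled_mle(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        lam_max = compute_lambda_max(designs, grid)
        fit = fit_joint(designs, grid, 10.0 * lam_max)
        pooled = fit_single_glm(pooled_design(designs)).vector
        assert fit.max_row_spread() <= 1e-8
        np.testing.assert_allclose(fit.coeffs, np.tile(pooled, (3, 1)), atol=1e-4)

    @pytest.mark.parametrize("frac", [0.1, 0.5, 1.0])
    def test_objective_matches_generic_convex_solver(self, frac):
        # independent oracle: epigraph NLP solved by a generic solver
        from channeltrend.basis import make_cosine_basis
        bases = (make_cosine_basis("stimulus", n_bases=2, span=20),
                 make_cosine_basis("history", n_bases=2, span=20))
        grid = ConductanceGrid(np.array([0.5, 1.0, 2.0]))
        designs = []
        for i, shift in enumerate([-0.3, 0.0, 0.3]):
            beta = np.array([0.6 + shift, 0.2, -2.3, -1.5, 0.1])
            _, _, d = make_glm_dataset(bases, beta, n_trials=2, n_bins=400,
                                       seed=200 + i)
            designs.append(d)
        lam = frac * compute_lambda_max(designs, grid)
        mine = joint_objective(fit_joint(designs, grid, lam).coeffs, designs, grid, lam)
        oracle = generic_convex_objective(designs, grid, lam)
        assert mine == pytest.approx(oracle, rel=1e-4)

    def test_negative_lambda_rejected(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        with pytest.raises(InvalidParameterError):
            fit_joint(designs, grid, -1.0)

    def test_reversal_symmetry(self, tiny_joint_problem):
        # relabeling conditions in reverse, with a reversed grid of equal
        # gaps, must reverse the solution rows
        grid, designs = tiny_joint_problem
        g = grid.factors
        rev_factors = np.sort(g[0] + g[-1] - g)
        rev_grid = ConductanceGrid(rev_factors)
        lam = 0.3 * compute_lambda_max(designs, grid)
        a = fit_joint(designs, grid, lam)
        b = fit_joint(designs[::-1], rev_grid, lam)
        np.testing.assert_allclose(a.coeffs, b.coeffs[::-1], atol=1e-5)


class TestLambdaMax:
    def test_identical_datasets_give_zero(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        same = [designs[0]] * 3
        assert compute_lambda_max(same, grid) == pytest.approx(0.0, abs=1e-6)

    def test_collapse_boundary(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        lam_max = compute_lambda_max(designs, grid)
        assert fit_joint(designs, grid, lam_max * 1.001).max_row_spread() < 1e-6
        assert fit_joint(designs, grid, lam_max * 0.5).max_row_spread() > 1e-4

    def test_matches_bisection_oracle(self, tiny_joint_problem):
        grid, designs = tiny_joint_problem
        kkt = compute_lambda_max(designs, grid)
        bis = bisect_lambda_max(designs, grid)
        assert abs(bis - kkt) / kkt < 0.01

    def test_halving_grid_gaps_halves_lambda_max(self, tiny_joint_problem):
        # doubling all weights w_i (halving every gap) halves lambda_max
        grid, designs = tiny_joint_problem
        g = grid.factors
        half_gap = ConductanceGrid(g[0] + 0.5 * (g - g[0]))
        assert compute_lambda_max(designs, half_gap) == pytest.approx(
            0.5 * compute_lambda_max(designs, grid), rel=1e-9)


class TestLambdaGrid:
    def test_geometric_grid_values(self):
        grid = build_lambda_grid(1.0)
        assert len(grid) == 23
        assert grid[0] == 1.0
        assert grid[1] == pytest.approx(np.exp(-1.0))
        assert grid[-2] == pytest.approx(np.exp(-21.0))
        assert grid[-1] == 0.0
        ratios = grid[1:-1] / grid[:-2]
        np.testing.assert_allclose(ratios, np.exp(-1.0))

    def test_zero_lambda_max_degenerate_grid(self):
        grid = build_lambda_grid(0.0)
        assert len(grid) == 23
        assert np.all(grid == 0.0)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_lambda_grid(-1.0)


class TestSplitTrials:
    def test_seventy_thirty(self):
        train, val = split_trials(100, 0.7, seed=0)
        assert len(train) == 70 and len(val) == 30
        assert np.intersect1d(train, val).size == 0

    def test_small_count(self):
        train, val = split_trials(10, 0.7, seed=1)
        assert len(train) == 7 and len(val) == 3

    def test_reproducible(self):
        a = split_trials(50, 0.7, seed=42)
        b = split_trials(50, 0.7, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(InvalidParameterError):
            split_trials(10, frac, seed=0)


@pytest.fixture(scope="module")
def fitted_path(tiny_joint_problem):
    grid, designs = tiny_joint_problem
    return grid, designs, fit_lambda_path(designs, grid, val_datasets=designs)


class TestLambdaPath:
    def test_path_length_and_ordering(self, fitted_path):
        _, _, path = fitted_path
        assert len(path.lambdas) == 23
        assert np.all(np.diff(path.lambdas[:-1]) < 0)
        assert path.lambdas[-1] == 0.0

    def test_penalty_nonincreasing_in_lambda(self, fitted_path):
        grid, _, path = fitted_path
        pens = [float(np.sum(grid.weights[:, None]
                             * np.abs(np.diff(f.coeffs, axis=0))))
                for f in path.fits]
        # lambdas decrease along the path, so penalties increase along it
        assert np.all(np.diff(pens) >= -1e-8)

    def test_fusion_count_nonincreasing_in_lambda(self, fitted_path):
        _, _, path = fitted_path
        def n_distinct(fit):
            return sum(len(np.unique(np.round(fit.coeffs[:, q], 6)))
                       for q in range(fit.coeffs.shape[1]))
        counts = [n_distinct(f) for f in path.fits]
        assert counts[0] <= counts[-1]
        assert np.all(np.diff(counts) >= -2)  # small solver-noise slack

    def test_zero_endpoint_is_independent_fits(self, fitted_path):
        _, designs, path = fitted_path
        independent = np.array([fit_single_glm(d).vector for d in designs])
        np.testing.assert_allclose(path.fits[-1].coeffs, independent, atol=1e-4)


class TestSelectLambda:
    def _make_path(self, val):
        lambdas = build_lambda_grid(1.0)
        return LambdaPath(lambdas=lambdas, fits=[None] * 23,
                          val_loglik=np.asarray(val, dtype=float))

    def test_flat_validation_selects_lambda_max(self):
        path = self._make_path(np.full(23, -100.0))
        assert select_lambda(path) == 1.0

    def test_steeply_decreasing_in_lambda_selects_zero(self):
        # validation likelihood drops by much more than zeta per grid step
        val = -100.0 - 10.0 * np.arange(23)[::-1]
        path = self._make_path(val)
        assert select_lambda(path) == 0.0

    def test_zeta_widens_feasible_set(self):
        val = np.full(23, -100.0)
        val[0] = -100.4  # lambda_max slightly worse than the rest
        path = self._make_path(val)
        assert select_lambda(path, zeta=np.log(1.0005)) == pytest.approx(np.exp(-1.0))
        path2 = self._make_path(val)
        assert select_lambda(path2, zeta=1.0) == 1.0

    def test_invalid_zeta_rejected(self):
        path = self._make_path(np.zeros(23))
        with pytest.raises(InvalidParameterError):
            select_lambda(path, zeta=0.0)

    def test_missing_validation_rejected(self):
        path = LambdaPath(lambdas=build_lambda_grid(1.0), fits=[None] * 23)
        with pytest.raises(InvalidInputError):
            select_lambda(path)
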