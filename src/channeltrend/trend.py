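"""Joint GLM estimation across a conductance grid with a fused-l1 penalty.

For an ordered grid of conductance scaling factors g_1 < ... < g_B, one
spike-train dataset per grid point, the joint estimate solves

    min over beta(g_1..g_B)   sum_i -ell_i(beta(g_i))
        + lambda * sum_{i<B} 1/(g_{i+1} - g_i) * ||beta(g_i) - beta(g_{i+1})||_1

i.e. trend filtering (a weighted fused lasso) on the coefficient
trajectories: the l1 penalty on successive differences drives small
conductance-driven changes exactly to zero, and the 1/(g_{i+1}-g_i) weights
normalize for unequal grid steps.  At lambda = 0 the problem decouples into
independent per-condition MLEs; at lambda >= lambda_max every coefficient
trajectory is constant and equals the pooled-data MLE.

The solver is proximal Newton: each outer iteration expands the
log-likelihoods to second order and solves the resulting fused-lasso
quadratic subproblem exactly through its box-constrained dual (a small
bound-constrained QP over the difference multipliers), with a line search
on the true penalized objective.  Fused coefficients come out exactly
equal, and the whole solve needs only a handful of passes over the data.

The penalty strength lambda is chosen on a 23-point geometric grid
{lambda_max * e^-j, j=0..21} plus 0, by the largest-lambda rule: take the
largest lambda whose summed held-out log-likelihood is within zeta
(default log 1.0005, a likelihood-ratio bound) of the best over the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from ._exceptions import InvalidInputError, InvalidParameterError
from .glm import DesignMatrix, GLMParams, bernoulli_loglik, fit_single_glm

__all__ = [
    "ConductanceGrid",
    "JointFit",
    "LambdaPath",
    "joint_objective",
    "fit_joint",
    "compute_lambda_max",
    "build_lambda_grid",
    "split_trials",
    "fit_lambda_path",
    "select_lambda",
    "pooled_design",
]

N_LAMBDA_POWERS = 22  # geometric grid exponents 0..21, ratio e^-1, plus 0
LAMBDA_RATIO = np.exp(-1.0)
DEFAULT_ZETA = float(np.log(1.0005))


@dataclass(frozen=True)
class ConductanceGrid:
    """Ordered conductance scaling factors with step-normalizing weights."""

    factors: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if f.ndim != 1 or len(f) < 2:
            raise InvalidParameterError("grid needs at least two factors")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise InvalidParameterError("factors must be positive and strictly increasing")
        object.__setattr__(self, "factors", f)

    @property
    def n_points(self) -> int:
        return len(self.factors)

    @property
    def weights(self) -> np.ndarray:
        """w_i = 1 / (g_{i+1} - g_i) for i = 1..B-1."""
        return 1.0 / np.diff(self.factors)


@dataclass
class JointFit:
    """Solution of the fused-penalty joint problem at one lambda value."""

    coeffs: np.ndarray  # (B, P), row i = beta(g_i)
    lam: float
    grid: ConductanceGrid
    converged: bool
    n_iter: int
    primal_residual: float
    dual_residual: float
    train_loglik: np.ndarray | None = None  # per condition
    val_loglik: np.ndarray | None = None
    dual: np.ndarray | None = None  # difference multipliers at the solution

    @property
    def n_conditions(self) -> int:
        return self.coeffs.shape[0]

    def params(self, i: int, d_K: int, d_H: int) -> GLMParams:
        return GLMParams.from_vector(self.coeffs[i], d_K, d_H)

    def max_row_spread(self) -> float:
        return float(np.max(self.coeffs.max(axis=0) - self.coeffs.min(axis=0)))


def _check_datasets(datasets: list[DesignMatrix], grid: ConductanceGrid) -> None:
    if len(datasets) != grid.n_points:
        raise InvalidInputError(
            f"{len(datasets)} datasets for a grid of {grid.n_points} points")
    p = datasets[0].n_params
    if any(d.n_params != p for d in datasets):
        raise InvalidInputError("all datasets must share the same coefficient dimension")


def joint_objective(coeffs: np.ndarray, datasets: list[DesignMatrix],
                    grid: ConductanceGrid, lam: float) -> float:
    """Evaluate the penalized joint objective at a coefficient matrix."""
    _check_datasets(datasets, grid)
    coeffs = np.asarray(coeffs, dtype=float)
    nll = -sum(bernoulli_loglik(coeffs[i], d, with_grad=False)
               for i, d in enumerate(datasets))
    diffs = coeffs[:-1] - coeffs[1:]
    penalty = float(np.sum(grid.weights[:, None] * np.abs(diffs)))
    return nll + lam * penalty


def pooled_design(datasets: list[DesignMatrix]) -> DesignMatrix:
    """Stack conditions into one design (the lambda -> infinity limit fit)."""
    X = np.vstack([d.X for d in datasets])
    y = np.concatenate([d.y for d in datasets])
    d0 = datasets[0]
    return DesignMatrix(X=X, y=y, d_K=d0.d_K, d_H=d0.d_H,
                        n_trials=sum(d.n_trials for d in datasets), n_bins=d0.n_bins)


class _JointLikelihood:
    """Batched likelihood/gradient/Hessian over all conditions.

    Stacks per-condition design matrices into a (B, T, P) tensor when trial
    counts agree (the common case), so likelihood values and gradients cost
    a couple of batched matmuls and the per-condition Hessian blocks one
    batched rank-k update.
    """

    def __init__(self, datasets: list[DesignMatrix]):
        self.datasets = datasets
        self.B = len(datasets)
        self.P = datasets[0].n_params
        shapes = {d.X.shape for d in datasets}
        self.homogeneous = len(shapes) == 1
        if self.homogeneous:
            self.X = np.stack([d.X for d in datasets])   # (B, T, P)
            self.y = np.stack([d.y for d in datasets])   # (B, T)
        self.n_obs = sum(d.n_obs for d in datasets)

    def nll_grad(self, b: np.ndarray):
        """(sum of negative log-likelihoods, per-condition gradient rows)."""
        if self.homogeneous:
            xb = np.einsum("btp,bp->bt", self.X, b)
            nll = float(np.sum(np.maximum(xb, 0.0) + np.log1p(np.exp(-np.abs(xb)))
                               - self.y * xb))
            grad = np.einsum("btp,bt->bp", self.X, expit(xb) - self.y)
            return nll, grad
        nll, rows = 0.0, np.empty((self.B, self.P))
        for i, d in enumerate(self.datasets):
            ll, g = bernoulli_loglik(b[i], d)
            nll -= ll
            rows[i] = -g
        return nll, rows

    def nll(self, b: np.ndarray) -> float:
        if self.homogeneous:
            xb = np.einsum("btp,bp->bt", self.X, b)
            return float(np.sum(np.maximum(xb, 0.0) + np.log1p(np.exp(-np.abs(xb)))
                                - self.y * xb))
        return -sum(bernoulli_loglik(b[i], d, with_grad=False)
                    for i, d in enumerate(self.datasets))

    def hessian_blocks(self, b: np.ndarray) -> np.ndarray:
        """Per-condition logistic Hessians X_i' W_i X_i, shape (B, P, P)."""
        if self.homogeneous:
            w = expit(np.einsum("btp,bp->bt", self.X, b))
            w = w * (1.0 - w)
            return np.matmul(self.X.transpose(0, 2, 1), self.X * w[:, :, None])
        out = np.empty((self.B, self.P, self.P))
        for i, d in enumerate(self.datasets):
            p = expit(d.X @ b[i])
            w = p * (1.0 - p)
            out[i] = (d.X * w[:, None]).T @ d.X
        return out


def _fused_quadratic_dual(hinv: np.ndarray, c: np.ndarray, bounds: np.ndarray,
                          eta0: np.ndarray | None = None):
    """Solve min_x 1/2 x'Hx - c'x + sum_iq bounds_iq |(Dx)_iq| exactly.

    H is block-diagonal (one P x P logistic Hessian per condition; its
    explicit blockwise inverse ``hinv`` is passed in); D takes successive
    differences between condition rows.  The problem is solved through its
    box-constrained dual

        min_eta 1/2 (c - D'eta)' H^-1 (c - D'eta),   |eta_iq| <= bounds_iq,

    with L-BFGS-B (each gradient is one batched matmul).  Returns
    (x, eta): the primal solution and the dual variables; by complementary
    slackness, pairs whose dual coordinate is strictly inside the box are
    fused (equal) in x.
    """
    B, P = c.shape

    def apply_hinv(r):
        return np.einsum("bpq,bq->bp", hinv, r)

    def dt_apply(eta):
        out = np.zeros((B, P))
        out[:-1] += eta
        out[1:] -= eta
        return out

    def objective(eta_flat):
        eta = eta_flat.reshape(B - 1, P)
        r = c - dt_apply(eta)
        x = apply_hinv(r)
        val = 0.5 * float(np.sum(r * x))
        grad = -(x[:-1] - x[1:])  # -D x
        return val, grad.reshape(-1)

    lb = -bounds.reshape(-1)
    ub = bounds.reshape(-1)
    x0 = np.zeros((B - 1) * P) if eta0 is None else np.clip(eta0.reshape(-1), lb, ub)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=np.column_stack([lb, ub]),
                   options=dict(maxiter=1500, ftol=1e-15, gtol=1e-11))
    eta = res.x.reshape(B - 1, P)
    x = apply_hinv(c - dt_apply(eta))
    return x, eta


def _snap_fused(x: np.ndarray, eta: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Make pairs whose dual coordinate is interior exactly equal.

    Complementary slackness holds only approximately in floating point; the
    snap replaces each fused run of a trajectory by its mean so that fused
    successive values are bit-identical (the adjustment is on the order of
    the solver tolerance).
    """
    x = x.copy()
    B, P = x.shape
    interior = (np.abs(eta) < bounds * (1.0 - 1e-9)) & (bounds > 0)
    for q in range(P):
        i = 0
        while i < B:
            j = i
            while j < B - 1 and interior[j, q]:
                j += 1
            if j > i:
                x[i:j + 1, q] = x[i:j + 1, q].mean()
            i = j + 1
    return x


def fit_joint(datasets: list[DesignMatrix], grid: ConductanceGrid, lam: float,
              init: np.ndarray | None = None, init_dual: np.ndarray | None = None,
              obj_tol: float = 1e-12, step_tol: float = 1e-8,
              max_iter: int = 100) -> JointFit:
    """Minimize the fused-penalty joint objective at one lambda.

    Proximal Newton: at each outer iteration the per-condition Bernoulli
    log-likelihoods are replaced by their exact second-order expansions and
    the resulting fused-lasso quadratic program is solved exactly through
    its box-constrained dual (:func:`_fused_quadratic_dual`); a
    backtracking line search on the true penalized objective guards each
    step.  The likelihood term is smooth and strictly convex in practice,
    so a handful of outer iterations reach the minimizer to near machine
    precision; fused successive coefficients in the returned solution are
    exactly equal (dual complementary slackness, plus a tolerance-level
    snap).

    ``init`` (and optionally ``init_dual``) warm-start the solve, e.g.
    from the previous solution along a lambda path.  Non-convergence
    within ``max_iter`` outer iterations returns ``converged=False``
    rather than raising.
    """
    _check_datasets(datasets, grid)
    if lam < 0:
        raise InvalidParameterError("lambda must be >= 0")
    B, P = grid.n_points, datasets[0].n_params
    lik = _JointLikelihood(datasets)
    bounds = lam * np.tile(grid.weights[:, None], (1, P))

    beta = np.zeros((B, P)) if init is None else np.asarray(init, dtype=float).reshape(B, P).copy()
    eta = init_dual

    def penalty(b):
        return float(np.sum(grid.weights[:, None] * np.abs(b[:-1] - b[1:])))

    nll, grad = lik.nll_grad(beta)
    obj = nll + lam * penalty(beta)
    converged = False
    step_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        hess = lik.hessian_blocks(beta)
        # tiny ridge keeps the blocks positive definite under near-separation
        ridge = 1e-8 * (1.0 + np.trace(hess.sum(axis=0)) / (B * P))
        hess += ridge * np.eye(P)[None]
        hinv = np.linalg.inv(hess)
        c = np.einsum("bpq,bq->bp", hess, beta) - grad
        x, eta = _fused_quadratic_dual(hinv, c, bounds, eta0=eta)
        # snap first: the inexact dual leaves tiny unfused residuals whose
        # penalty cost would otherwise corrupt the model-decrease measure
        x = _snap_fused(x, eta, bounds)
        d = x - beta
        step_norm = float(np.max(np.abs(d)))
        # decrease of the second-order model: the natural optimality measure
        model_dec = -(float(np.sum(grad * d))
                      + 0.5 * float(np.einsum("bp,bpq,bq->", d, hess, d))
                      + lam * (penalty(x) - penalty(beta)))
        if (model_dec <= obj_tol * (1.0 + abs(obj))
                or step_norm < step_tol * (1.0 + float(np.max(np.abs(beta))))):
            cand_obj = lik.nll(x) + lam * penalty(x)
            if cand_obj <= obj:
                beta, obj = x, cand_obj
            converged = True
            break
        # backtracking line search with an Armijo bound on the model decrease
        t, accepted = 1.0, False
        for _ in range(40):
            cand = beta + t * d
            cand_obj = lik.nll(cand) + lam * penalty(cand)
            if cand_obj <= obj - 1e-4 * t * model_dec:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # no further progress representable at this solver precision
            converged = True
            break
        prev_obj = obj
        beta, obj = cand, cand_obj
        nll, grad = lik.nll_grad(beta)
        if prev_obj - obj <= obj_tol * (1.0 + abs(prev_obj)):
            converged = True
            break
        if np.max(np.abs(beta)) > 30.0:
            # per-bin logits beyond +/-30 mean the (penalized) MLE is drifting
            # to infinity: the data are (near-)separable at this lambda
            warnings.warn(f"coefficients diverging at lambda={lam:.3g}; data look "
                          "separable, returning the current iterate unconverged",
                          stacklevel=2)
            break

    if not converged:
        warnings.warn(f"joint fit did not converge in {max_iter} outer iterations "
                      f"(last step {step_norm:.2e}) at lambda={lam:.3g}", stacklevel=2)

    train_ll = np.array([bernoulli_loglik(beta[i], d_, with_grad=False)
                         for i, d_ in enumerate(datasets)])
    fit = JointFit(coeffs=beta, lam=float(lam), grid=grid, converged=converged,
                   n_iter=it, primal_residual=step_norm,
                   dual_residual=float(np.max(np.abs(eta) / np.maximum(bounds, 1e-300)))
                   if lam > 0 else 0.0,
                   train_loglik=train_ll, dual=eta)
    return fit


def compute_lambda_max(datasets: list[DesignMatrix], grid: ConductanceGrid) -> float:
    """Smallest lambda at which the fully fused solution is optimal.

    At the pooled MLE beta_bar, stationarity of the fused problem requires
    subgradient vectors t_j = -sum_{i<=j} grad ell_i(beta_bar) with
    |t_j[q]| <= lambda * w_j for every cut point j and coefficient q, so

        lambda_max = max_{j,q} |sum_{i<=j} d(-ell_i)/d beta_q (beta_bar)| / w_j.
    """
    _check_datasets(datasets, grid)
    pooled = pooled_design(datasets)
    beta_bar = fit_single_glm(pooled).vector
    grads = np.array([-bernoulli_loglik(beta_bar, d)[1] for d in datasets])  # d(-ell)/dbeta
    cum = np.cumsum(grads, axis=0)[:-1]  # cut points j = 1..B-1
    return float(np.max(np.abs(cum) / grid.weights[:, None]))


def build_lambda_grid(lambda_max: float) -> np.ndarray:
    """Geometric penalty grid: {lambda_max * e^-j, j=0..21} followed by 0."""
    if lambda_max < 0:
        raise InvalidParameterError("lambda_max must be >= 0")
    grid = lambda_max * LAMBDA_RATIO ** np.arange(N_LAMBDA_POWERS)
    return np.concatenate([grid, [0.0]])


def split_trials(n_trials: int, fraction_train: float = 0.7, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/validation trial split (70/30 by default).

    The same index sets must be applied to every conductance condition so
    held-out likelihoods are comparable across the grid.
    """
    if not 0.0 < fraction_train < 1.0:
        raise InvalidParameterError(f"fraction_train must be in (0, 1), got {fraction_train}")
    n_train = int(round(n_trials * fraction_train))
    if n_train < 1 or n_train >= n_trials:
        raise InvalidInputError(f"cannot split {n_trials} trials at fraction {fraction_train}")
    perm = np.random.Generator(np.random.PCG64(seed)).permutation(n_trials)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class LambdaPath:
    """Regularization path: one joint fit per lambda plus the selected one."""

    lambdas: np.ndarray
    fits: list[JointFit]
    val_loglik: np.ndarray | None = None  # summed over conditions, per lambda
    lambda_star: float | None = None
    selected_index: int | None = None
    zeta: float = DEFAULT_ZETA

    @property
    def selected_fit(self) -> JointFit:
        if self.selected_index is None:
            raise InvalidInputError("no lambda selected yet; run select_lambda")
        return self.fits[self.selected_index]

    def fit_at(self, lam: float) -> JointFit:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.fits[idx]


def fit_lambda_path(train_datasets: list[DesignMatrix], grid: ConductanceGrid,
                    val_datasets: list[DesignMatrix] | None = None,
                    lambdas: np.ndarray | None = None, **fit_kwargs) -> LambdaPath:
    """Fit the joint model along the lambda grid, largest lambda first.

    Each fit warm-starts (primal and dual) from the previous solution; a
    warm start that fails to converge is retried cold.  When validation
    datasets are given, the summed held-out log-likelihood is recorded per
    lambda.
    """
    if lambdas is None:
        lambdas = build_lambda_grid(compute_lambda_max(train_datasets, grid))
    fits: list[JointFit] = []
    init = init_dual = None
    for lam in lambdas:
        fit = fit_joint(train_datasets, grid, lam, init=init, init_dual=init_dual,
                        **fit_kwargs)
        if not fit.converged and init is not None:
            cold = fit_joint(train_datasets, grid, lam, **fit_kwargs)
            if cold.converged:
                fit = cold
        if val_datasets is not None:
            fit.val_loglik = np.array([
                bernoulli_loglik(fit.coeffs[i], d, with_grad=False)
                for i, d in enumerate(val_datasets)])
        fits.append(fit)
        init = fit.coeffs
        init_dual = fit.dual
    val = (np.array([f.val_loglik.sum() for f in fits])
           if val_datasets is not None else None)
    return LambdaPath(lambdas=np.asarray(lambdas, dtype=float), fits=fits, val_loglik=val)


def select_lambda(path: LambdaPath, zeta: float = DEFAULT_ZETA,
                  per_observation: bool = False,
                  n_val_obs: int | None = None) -> float:
    """Largest-lambda selection rule on held-out likelihood.

    lambda* is the largest lambda in the grid whose summed validation
    log-likelihood exceeds (best over the grid) - zeta.  zeta is a total
    log-likelihood-ratio bound (default log 1.0005); with
    ``per_observation=True`` it is scaled by the number of validation
    observations instead.  The argmax itself always satisfies the bound, so
    the feasible set is never empty.
    """
    if path.val_loglik is None:
        raise InvalidInputError("path has no validation log-likelihoods")
    if zeta <= 0:
        raise InvalidParameterError("zeta must be > 0")
    thresh = zeta
    if per_observation:
        if n_val_obs is None:
            raise InvalidParameterError("per_observation selection needs n_val_obs")
        thresh = zeta * n_val_obs
    best = path.val_loglik.max()
    feasible = np.flatnonzero(path.val_loglik > best - thresh)
    idx = feasible[np.argmax(path.lambdas[feasible])]
    path.selected_index = int(idx)
    path.lambda_star = float(path.lambdas[idx])
    path.zeta = zeta
    return path.lambda_star
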