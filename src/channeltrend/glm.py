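"""Point-process GLM core: design matrices, Bernoulli likelihood, fitting,
and bin-by-bin GLM spike simulation.

The encoding model for one conductance condition is a Bernoulli GLM with a
logit link: the probability of a spike in 1 ms bin j is

    logit(p_j) = [k (*) s]_j + b + [h (*) y]_j

where k is the stimulus filter, h the post-spike-history filter (both
expanded in raised-cosine bases), b the baseline, s the binned stimulus and
y the binary spike train.  The logit link is used rather than a log link
because bins are binary: counts above one are clipped, and Poisson
regression on right-censored counts is biased at high rates.

The coefficient vector stacks d_K stimulus weights, 1 baseline and d_H
history weights (21 by default).  History covariates use lags >= 1 bin only:
a bin's own spike never predicts itself, and trial boundaries reset all
convolution state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import expit

from ._exceptions import InvalidInputError, InvalidParameterError, PerfectSeparationError
from .basis import CosineBasisSet

__all__ = [
    "GLMParams",
    "DesignMatrix",
    "build_design_matrix",
    "bernoulli_loglik",
    "fit_single_glm",
    "simulate_spikes_from_glm",
]


@dataclass
class GLMParams:
    """Coefficients of one condition's PP-GLM (units: logit spikes per bin)."""

    beta_stim: np.ndarray
    beta_baseline: float
    beta_hist: np.ndarray

    def __post_init__(self):
        self.beta_stim = np.asarray(self.beta_stim, dtype=float)
        self.beta_hist = np.asarray(self.beta_hist, dtype=float)
        vec = self.vector
        if not np.all(np.isfinite(vec)):
            raise InvalidParameterError("GLM coefficients must be finite")

    @property
    def vector(self) -> np.ndarray:
        """Stacked coefficient vector (d_K stimulus, baseline, d_H history)."""
        return np.concatenate([self.beta_stim, [self.beta_baseline], self.beta_hist])

    @classmethod
    def from_vector(cls, vec: np.ndarray, d_K: int, d_H: int) -> "GLMParams":
        vec = np.asarray(vec, dtype=float)
        if len(vec) != d_K + 1 + d_H:
            raise InvalidParameterError(f"expected {d_K + 1 + d_H} coefficients, got {len(vec)}")
        return cls(vec[:d_K], float(vec[d_K]), vec[d_K + 1:])

    def stimulus_filter(self, basis: CosineBasisSet) -> np.ndarray:
        return basis.reconstruct(self.beta_stim)

    def history_filter(self, basis: CosineBasisSet) -> np.ndarray:
        return basis.reconstruct(self.beta_hist)


@dataclass
class DesignMatrix:
    """Stacked per-trial design matrix X and binary response y.

    Column layout: d_K stimulus-convolution columns, one all-ones baseline
    column, d_H history-convolution columns.  History columns at bin j
    depend only on spikes strictly before j.
    """

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    d_K: int
    d_H: int
    n_trials: int
    n_bins: int

    def __post_init__(self):
        if self.X.shape[0] != self.y.shape[0]:
            raise InvalidInputError("X and y row counts differ")
        if self.X.shape[1] != self.d_K + 1 + self.d_H:
            raise InvalidInputError("X column count does not match d_K + 1 + d_H")

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def _causal_columns(signal: np.ndarray, basis: CosineBasisSet) -> np.ndarray:
    """Causal convolution of each trial with each basis row.

    ``signal`` has shape (n_trials, n_bins).  For stimulus bases (lags from
    0) column m at bin j is sum_l phi_m(l) * s[j - l]; for history bases the
    lag grid starts at one bin, so only strictly-past samples enter.
    Returns shape (n_trials, n_bins, n_bases).
    """
    n_trials, n_bins = signal.shape
    if basis.kind == "history":
        # binary input: accumulate shifted kernels at spike positions, which
        # is exact (zeros stay exactly zero, preserving strict causality)
        L = basis.n_lags
        ker = basis.matrix.T  # (n_lags, n_bases)
        out = np.zeros((n_trials, n_bins, basis.n_bases))
        for i in range(n_trials):
            for s in np.flatnonzero(signal[i]):
                hi = min(n_bins, s + 1 + L)
                out[i, s + 1:hi, :] += ker[: hi - (s + 1)]
        return out
    out = np.empty((n_trials, n_bins, basis.n_bases))
    for m in range(basis.n_bases):
        conv = fftconvolve(signal, basis.matrix[m][None, :], mode="full",
                           axes=1)[:, :n_bins]
        out[:, :, m] = conv
    return out


def build_design_matrix(stimulus: np.ndarray, spikes: np.ndarray,
                        basis_K: CosineBasisSet, basis_H: CosineBasisSet) -> DesignMatrix:
    """Assemble the PP-GLM design matrix from binned stimulus and spikes.

    Parameters
    ----------
    stimulus : ndarray, (n_trials, n_bins) or (n_bins,)
        Stimulus averaged into GLM bins (1 ms).  A single row is broadcast
        to every trial (frozen-stimulus shortcut).
    spikes : ndarray, (n_trials, n_bins)
        Binary spike trains aligned with the stimulus bins.
    """
    spikes = np.atleast_2d(np.asarray(spikes))
    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    if stimulus.shape[0] == 1 and spikes.shape[0] > 1:
        stimulus = np.broadcast_to(stimulus, spikes.shape)
    if stimulus.shape != spikes.shape:
        raise InvalidInputError(
            f"stimulus shape {stimulus.shape} does not match spikes shape {spikes.shape}")
    if not np.isin(spikes, (0, 1)).all():
        raise InvalidInputError("spike trains must be binary")

    n_trials, n_bins = spikes.shape
    stim_cols = _causal_columns(stimulus, basis_K)
    hist_cols = _causal_columns(spikes.astype(float), basis_H)
    X = np.concatenate([
        stim_cols,
        np.ones((n_trials, n_bins, 1)),
        hist_cols,
    ], axis=2).reshape(n_trials * n_bins, -1)
    y = spikes.reshape(-1).astype(float)
    return DesignMatrix(X=X, y=y, d_K=basis_K.n_bases, d_H=basis_H.n_bases,
                        n_trials=n_trials, n_bins=n_bins)


def bernoulli_loglik(beta: np.ndarray, design: DesignMatrix,
                     with_grad: bool = True):
    """Bernoulli log-likelihood and gradient under the logit link.

    ell(beta) = sum_j [ y_j x_j'beta - log(1 + exp(x_j'beta)) ], evaluated
    with log1p/expit so it is stable for |x'beta| well beyond 30.
    """
    y = design.y
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("responses must be binary")
    xb = design.X @ np.asarray(beta, dtype=float)
    # log(1 + e^t) = max(t, 0) + log1p(e^{-|t|})
    ll = float(y @ xb - np.sum(np.maximum(xb, 0.0) + np.log1p(np.exp(-np.abs(xb)))))
    if not with_grad:
        return ll
    grad = design.X.T @ (y - expit(xb))
    return ll, grad


def neg_loglik_hessian(beta: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Hessian of the NEGATIVE log-likelihood: X' diag(p(1-p)) X (PSD)."""
    p = expit(design.X @ np.asarray(beta, dtype=float))
    w = p * (1.0 - p)
    return (design.X * w[:, None]).T @ design.X


def fit_single_glm(design: DesignMatrix, beta0: np.ndarray | None = None,
                   grad_tol: float = 1e-6, rel_tol: float = 1e-9,
                   max_iter: int = 100) -> GLMParams:
    """Maximum-likelihood fit of one condition's GLM by damped Newton.

    The likelihood is concave, so Newton steps with halving are globally
    convergent; iteration stops when the gradient infinity-norm falls below
    ``grad_tol`` or the relative log-likelihood change below ``rel_tol``.
    A coefficient norm exceeding 1e4 is taken as evidence of perfect
    separation (unbounded MLE) and raises, suggesting the trend-filtered
    joint fit or a ridge jitter instead.
    """
    y = design.y
    if y.sum() == 0 or y.sum() == len(y):
        raise InvalidInputError("need at least one spike bin and one non-spike bin")
    beta = np.zeros(design.n_params) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad = bernoulli_loglik(beta, design)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            break
        H = neg_loglik_hessian(beta, design)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(H)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking line search on the concave log-likelihood
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            ll_new = bernoulli_loglik(cand, design, with_grad=False)
            if ll_new >= ll:
                break
            t *= 0.5
        beta = beta + t * step
        ll_prev = ll
        ll, grad = bernoulli_loglik(beta, design)
        if np.linalg.norm(beta) > 1e4:
            raise PerfectSeparationError(
                "logistic MLE appears unbounded (separable data); consider the "
                "trend-filtered joint fit or adding ridge jitter")
        if abs(ll - ll_prev) < rel_tol * (abs(ll_prev) + 1e-12):
            break
    return GLMParams.from_vector(beta, design.d_K, design.d_H)


def simulate_spikes_from_glm(params: GLMParams, basis_K: CosineBasisSet,
                             basis_H: CosineBasisSet, stimulus: np.ndarray,
                             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample binary spike trains from a fitted (or constructed) PP-GLM.

    Sequential bin-by-bin sampling: the spike probability in bin j combines
    the precomputed stimulus drive with the history drive from spikes drawn
    in earlier bins of the same trial; each bin is a Bernoulli draw.
    Vectorized across trials, reproducible by seed.

    Parameters
    ----------
    stimulus : ndarray, (n_trials, n_bins) or (n_bins,)
        Binned stimulus; one row per trial to simulate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    n_trials, n_bins = stimulus.shape

    stim_cols = _causal_columns(stimulus, basis_K)
    drive = stim_cols @ params.beta_stim + params.beta_baseline  # (n_trials, n_bins)

    h_filter = params.history_filter(basis_H)  # values at lags 1..L bins
    L = len(h_filter)
    hist_drive = np.zeros((n_trials, n_bins + L))
    spikes = np.zeros((n_trials, n_bins), dtype=np.int8)
    for j in range(n_bins):
        p = expit(drive[:, j] + hist_drive[:, j])
        draw = rng.random(n_trials) < p
        if draw.any():
            spikes[draw, j] = 1
            hist_drive[draw, j + 1: j + 1 + L] += h_filter[None, :][0]
        # (no-op when no trial spikes this bin)
    return spikes
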