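"""Model/results interface tying the pipeline stages together.

:class:`ConductanceTrendGLM` is built from one spike-train dataset per
conductance scaling factor plus the shared binned stimulus; ``fit()`` runs
the train/validation split, the lambda path of fused-penalty joint fits,
the largest-lambda selection rule, and returns a
:class:`ConductanceTrendResults` carrying the coefficient trajectories,
held-out likelihoods, solver diagnostics, the sum-of-slopes vector and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError
from .basis import CosineBasisSet, make_cosine_basis
from .glm import DesignMatrix, GLMParams, build_design_matrix, simulate_spikes_from_glm
from .neuron import SpikeTrainSet
from .screen import SSVector, sum_of_slopes
from .trend import (DEFAULT_ZETA, ConductanceGrid, LambdaPath, build_lambda_grid,
                    compute_lambda_max, fit_lambda_path, select_lambda, split_trials)

__all__ = ["ConductanceTrendGLM", "ConductanceTrendResults"]


class ConductanceTrendGLM:
    """Joint trend-filtered PP-GLM across a conductance scaling grid.

    Parameters
    ----------
    spike_trains : dict[float, SpikeTrainSet]
        One binary trials x bins spike matrix per scaling factor; keys form
        the conductance grid.  Conditions with no spikes at all cannot be
        fitted and are dropped with a warning (the grid weights are then
        recomputed over the surviving consecutive pairs).
    stimulus : ndarray
        Binned stimulus, shape (n_trials, n_bins) or (n_bins,), shared by
        all conditions (the same frozen ensemble drives every factor).
    basis_K, basis_H : CosineBasisSet, optional
        Stimulus / history bases; default 10 raised-cosine bumps over
        100 ms each, giving 21 coefficients per condition.
    """

    def __init__(self, spike_trains: dict[float, SpikeTrainSet], stimulus: np.ndarray,
                 basis_K: CosineBasisSet | None = None,
                 basis_H: CosineBasisSet | None = None,
                 channel: str | None = None):
        if len(spike_trains) < 2:
            raise InvalidInputError("need spike trains for at least two scaling factors")
        self.basis_K = basis_K or make_cosine_basis("stimulus")
        self.basis_H = basis_H or make_cosine_basis("history")
        self.stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
        self.channel = channel

        kept: dict[float, SpikeTrainSet] = {}
        for factor in sorted(spike_trains):
            sts = spike_trains[factor]
            if sts.spikes.sum() == 0:
                warnings.warn(
                    f"dropping factor {factor}: no spikes in any trial, the GLM "
                    "cannot be trained on this condition", stacklevel=2)
                continue
            kept[factor] = sts
        if len(kept) < 2:
            raise InvalidInputError("fewer than two conditions have spikes; cannot fit a trend")
        self.spike_trains = kept
        self.grid = ConductanceGrid(np.array(sorted(kept)))
        n_trials = {s.n_trials for s in kept.values()}
        if len(n_trials) != 1:
            raise InvalidInputError("all conditions must have the same number of trials")
        self.n_trials = n_trials.pop()

    @classmethod
    def from_experiment(cls, spike_trains: dict[float, SpikeTrainSet], ensemble,
                        bin_width: float = 1.0, **kwargs) -> "ConductanceTrendGLM":
        """Build from run_scaling_experiment output plus a StimulusEnsemble."""
        return cls(spike_trains, ensemble.bin_average(bin_width), **kwargs)

    # -- design construction -------------------------------------------------

    def _designs(self, trial_idx: np.ndarray) -> list[DesignMatrix]:
        out = []
        stim = self.stimulus
        stim_rows = stim if stim.shape[0] == 1 else stim[trial_idx]
        for factor in self.grid.factors:
            sts = self.spike_trains[factor]
            out.append(build_design_matrix(stim_rows, sts.spikes[trial_idx],
                                           self.basis_K, self.basis_H))
        return out

    # -- fitting -------------------------------------------------------------

    def fit(self, fraction_train: float = 0.7, split_seed: int = 0,
            zeta: float = DEFAULT_ZETA, lambdas: np.ndarray | None = None,
            **fit_kwargs) -> "ConductanceTrendResults":
        """Run the full joint-estimation procedure and select lambda*."""
        train_idx, val_idx = split_trials(self.n_trials, fraction_train, split_seed)
        train = self._designs(train_idx)
        val = self._designs(val_idx)
        lambda_max = compute_lambda_max(train, self.grid)
        if lambdas is None:
            lambdas = build_lambda_grid(lambda_max)
        path = fit_lambda_path(train, self.grid, val_datasets=val, lambdas=lambdas,
                               **fit_kwargs)
        select_lambda(path, zeta=zeta)
        return ConductanceTrendResults(model=self, path=path, lambda_max=lambda_max,
                                       train_idx=train_idx, val_idx=val_idx, zeta=zeta)


@dataclass
class ConductanceTrendResults:
    """Fitted trend-filtered PP-GLM family with the selected penalty."""

    model: ConductanceTrendGLM
    path: LambdaPath
    lambda_max: float
    train_idx: np.ndarray
    val_idx: np.ndarray
    zeta: float

    @property
    def lambda_star(self) -> float:
        return self.path.lambda_star

    @property
    def coeffs(self) -> np.ndarray:
        """Coefficient matrix (B x 21) at the selected lambda*."""
        return self.path.selected_fit.coeffs

    @property
    def grid(self) -> ConductanceGrid:
        return self.model.grid

    def params(self, factor: float) -> GLMParams:
        i = int(np.argmin(np.abs(self.grid.factors - factor)))
        return GLMParams.from_vector(self.coeffs[i], self.model.basis_K.n_bases,
                                     self.model.basis_H.n_bases)

    def ss(self, at_lambda: str = "selected") -> SSVector:
        """Sum-of-slopes vector at lambda* (or the unpenalized endpoint)."""
        fit = self.path.selected_fit if at_lambda == "selected" else self.path.fit_at(0.0)
        return sum_of_slopes(fit, self.grid, basis_K=self.model.basis_K,
                             basis_H=self.model.basis_H)

    def simulate(self, factor: float, stimulus: np.ndarray | None = None,
                 seed: int = 0) -> np.ndarray:
        """Sample spike trains from the fitted GLM for one grid factor."""
        stim = self.model.stimulus if stimulus is None else np.atleast_2d(stimulus)
        return simulate_spikes_from_glm(self.params(factor), self.model.basis_K,
                                        self.model.basis_H, stim, seed=seed)

    def summary_frame(self) -> pd.DataFrame:
        return self.ss().to_frame()

    def summary(self) -> str:
        """Human-readable fit report (statsmodels-flavored)."""
        m = self.model
        sel = self.path.selected_fit
        lines = [
            "Conductance Trend-Filtered PP-GLM Results",
            "=" * 57,
            f"channel:              {m.channel or '<unnamed>'}",
            f"conditions (B):       {self.grid.n_points}",
            f"grid:                 {np.array2string(self.grid.factors, precision=2)}",
            f"coefficients/cond:    {m.basis_K.n_bases + 1 + m.basis_H.n_bases} "
            f"({m.basis_K.n_bases} stimulus + 1 baseline + {m.basis_H.n_bases} history)",
            f"trials (train/val):   {len(self.train_idx)}/{len(self.val_idx)}",
            f"lambda_max:           {self.lambda_max:.6g}",
            f"lambda*:              {self.lambda_star:.6g}",
            f"zeta:                 {self.zeta:.6g}",
            f"val loglik at lambda*:{self.path.val_loglik[self.path.selected_index]:.4f}",
            f"solver converged:     {sel.converged} ({sel.n_iter} outer iterations)",
            "-" * 57,
            "sum of slopes at lambda* (logit spikes/bin per unit factor):",
        ]
        frame = self.summary_frame()
        lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_coefficient_trajectories(self, ax=None):
        """beta(g) per coefficient across the grid, at lambda*."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for q in range(self.coeffs.shape[1]):
            ax.plot(self.grid.factors, self.coeffs[:, q], marker="o", ms=3)
        ax.set_xscale("log")
        ax.set_xlabel("conductance scaling factor g")
        ax.set_ylabel("coefficient (logit spikes/bin)")
        return ax
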