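"""Sum-of-slopes: conductance sensitivity of each encoding feature.

For coefficient q with trajectory beta(g_1)...beta(g_B) across the
conductance grid, the sum of slopes is the step-normalized total variation

    SS_q = sum_{j=1}^{B-1} |beta(g_j)_q - beta(g_{j+1})_q| / (g_{j+1} - g_j)

in units of logit spikes per bin per unit scaling factor.  A coefficient
fused to a constant trajectory by trend filtering has SS exactly 0; a large
SS marks an encoding feature (a stimulus-filter lag range, the baseline, or
a history-filter lag range) strongly modulated by the scaled channel.  The
channel screen tabulates SS at each channel's selected penalty lambda*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError
from .basis import CosineBasisSet
from .trend import ConductanceGrid, JointFit, LambdaPath

__all__ = ["SSVector", "sum_of_slopes", "screen_channels"]


@dataclass
class SSVector:
    """Per-coefficient sum-of-slopes values with block and lag annotations."""

    values: np.ndarray
    d_K: int
    d_H: int
    peak_lags_stim: np.ndarray | None = None
    peak_lags_hist: np.ndarray | None = None
    lam: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.d_K + 1 + self.d_H:
            raise InvalidInputError("SS vector length must be d_K + 1 + d_H")
        if np.any(self.values < -1e-12):
            raise InvalidInputError("SS values must be nonnegative")

    @property
    def blocks(self) -> np.ndarray:
        return np.array(["stimulus"] * self.d_K + ["baseline"] + ["history"] * self.d_H)

    @property
    def stimulus(self) -> np.ndarray:
        return self.values[: self.d_K]

    @property
    def baseline(self) -> float:
        return float(self.values[self.d_K])

    @property
    def history(self) -> np.ndarray:
        return self.values[self.d_K + 1:]

    def to_frame(self) -> pd.DataFrame:
        lags = np.full(len(self.values), np.nan)
        if self.peak_lags_stim is not None:
            lags[: self.d_K] = self.peak_lags_stim
        if self.peak_lags_hist is not None:
            lags[self.d_K + 1:] = self.peak_lags_hist
        return pd.DataFrame({
            "coefficient": np.arange(len(self.values)),
            "block": self.blocks,
            "peak_lag_ms": lags,
            "ss": self.values,
        })


def sum_of_slopes(joint_fit: JointFit, grid: ConductanceGrid | None = None,
                  d_K: int | None = None, d_H: int | None = None,
                  basis_K: CosineBasisSet | None = None,
                  basis_H: CosineBasisSet | None = None) -> SSVector:
    """Evaluate the sum of slopes of a joint fit's coefficient trajectories."""
    grid = grid if grid is not None else joint_fit.grid
    coeffs = joint_fit.coeffs
    if coeffs.shape[0] != grid.n_points:
        raise InvalidInputError("joint fit rows do not align with the grid")
    if grid.n_points < 2:
        raise InvalidInputError("sum of slopes needs at least two grid points")
    P = coeffs.shape[1]
    if d_K is None or d_H is None:
        if basis_K is not None and basis_H is not None:
            d_K, d_H = basis_K.n_bases, basis_H.n_bases
        else:
            # default symmetric layout: (P - 1) / 2 stimulus and history bases
            d_K = d_H = (P - 1) // 2
            if d_K + 1 + d_H != P:
                raise InvalidInputError("cannot infer d_K/d_H from coefficient count")
    values = np.sum(grid.weights[:, None] * np.abs(np.diff(coeffs, axis=0)), axis=0)
    return SSVector(
        values=values, d_K=d_K, d_H=d_H,
        peak_lags_stim=None if basis_K is None else basis_K.peak_lags,
        peak_lags_hist=None if basis_H is None else basis_H.peak_lags,
        lam=joint_fit.lam,
    )


def screen_channels(paths: dict[str, LambdaPath], grid: ConductanceGrid,
                    basis_K: CosineBasisSet | None = None,
                    basis_H: CosineBasisSet | None = None,
                    at_lambda: str = "selected") -> pd.DataFrame:
    """Assemble the multi-channel screen table of SS values.

    One row per (channel, coefficient), with block labels and basis peak
    lags, evaluated at each channel's own selected lambda* (default) or at
    the unpenalized endpoint (``at_lambda='zero'``).  Channels are ranked
    by their total SS.
    """
    rows = []
    for channel, path in paths.items():
        if at_lambda == "selected":
            fit = path.selected_fit
        elif at_lambda == "zero":
            fit = path.fit_at(0.0)
        else:
            raise InvalidInputError("at_lambda must be 'selected' or 'zero'")
        ss = sum_of_slopes(fit, grid, basis_K=basis_K, basis_H=basis_H)
        frame = ss.to_frame()
        frame.insert(0, "channel", channel)
        frame["lambda"] = fit.lam
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    totals = table.groupby("channel")["ss"].sum().sort_values(ascending=False)
    rank = {ch: r + 1 for r, ch in enumerate(totals.index)}
    table["channel_rank"] = table["channel"].map(rank)
    return table
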