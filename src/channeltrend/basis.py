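"""Raised-cosine filter bases for stimulus and post-spike-history filters.

Following the standard construction for spike-train encoding models, each
basis element is a bell-shaped bump

    phi_m(t) = (1 + cos(min(max((psi(t) - c_m) * pi / (2 d), -pi), pi))) / 2

on a log-stretched time axis psi(t) = log(t + stretch), with peak centers
c_m equally spaced in psi and spacing d = c_{m+1} - c_m.  The log stretch
makes bases narrow near lag zero (fast dynamics around the spike) and wide
at long lags, and every basis peaks at exactly 1.

Stimulus-filter bases start at lag 0; history-filter bases start at lag 1
bin, since the current bin's own spike cannot predict itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidParameterError

__all__ = ["CosineBasisSet", "make_cosine_basis"]


@dataclass(frozen=True)
class CosineBasisSet:
    """A bank of raised-cosine bases sampled on a 1 ms (or dt) lag grid.

    Attributes
    ----------
    kind : {"stimulus", "history"}
        History bases are sampled from lag ``dt`` onward (strictly causal).
    matrix : ndarray, (n_bases, n_lags)
        Basis samples; row m is basis m over the lag grid.
    lags : ndarray
        Lag times in ms for the columns of ``matrix``.
    peak_lags : ndarray
        Lag (ms) at which each basis attains its maximum of 1.
    """

    kind: str
    n_bases: int
    span: float
    stretch: float
    dt: float
    matrix: np.ndarray = field(repr=False)
    lags: np.ndarray = field(repr=False)
    peak_lags: np.ndarray = field(repr=False)

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[1]

    def reconstruct(self, coeffs: np.ndarray) -> np.ndarray:
        """Filter values sum_m coeffs[m] * phi_m(t) over the lag grid."""
        return np.asarray(coeffs) @ self.matrix

    def fwhm(self) -> np.ndarray:
        """Full width at half maximum (ms) of each basis, by linear interpolation."""
        widths = np.empty(self.n_bases)
        for m in range(self.n_bases):
            row = self.matrix[m]
            above = row >= 0.5
            idx = np.flatnonzero(above)
            lo, hi = idx[0], idx[-1]
            t_lo = self.lags[lo]
            if lo > 0:
                t_lo = np.interp(0.5, [row[lo - 1], row[lo]], [self.lags[lo - 1], self.lags[lo]])
            t_hi = self.lags[hi]
            if hi < self.n_lags - 1:
                t_hi = np.interp(0.5, [row[hi + 1], row[hi]], [self.lags[hi + 1], self.lags[hi]])
            widths[m] = t_hi - t_lo
        return widths


def make_cosine_basis(kind: str = "stimulus", n_bases: int = 10, span: float = 100.0,
                      stretch: float = 1.0, dt: float = 1.0,
                      first_peak: float | None = None) -> CosineBasisSet:
    """Build a raised-cosine basis set.

    Parameters
    ----------
    kind : {"stimulus", "history"}
    n_bases : int
        Number of bases (10 per filter by default).
    span : float
        Total filter length in ms; every basis' support lies inside
        ``[0, span]`` (``[dt, span]`` for history).
    stretch : float
        Log-axis offset (ms).  Smaller values concentrate more bases at
        short lags; the default 1.0 gives first/last widths of roughly
        2 and 30 ms for the default 10-basis, 100 ms configuration.
    dt : float
        Lag sampling step in ms (the GLM bin width).
    first_peak : float, optional
        Lag of the first basis peak; defaults to ``dt`` so the first bump
        sits right at the shortest causal lag.
    """
    if kind not in ("stimulus", "history"):
        raise InvalidParameterError(f"kind must be 'stimulus' or 'history', got {kind!r}")
    if n_bases < 1 or span <= 0 or stretch <= 0 or dt <= 0:
        raise InvalidParameterError("n_bases >= 1 and span, stretch, dt > 0 required")

    def psi(t):
        return np.log(t + stretch)

    p1 = dt if first_peak is None else first_peak
    u1 = psi(p1)
    u_span = psi(span)
    if n_bases == 1:
        un = u1
        delta = (u_span - u1) / 2.0
    else:
        # place the last peak so its support (peak + 2*spacing in psi) ends at span
        un = (u_span * (n_bases - 1) + 2.0 * u1) / (n_bases + 1)
        delta = (un - u1) / (n_bases - 1)
    if un <= u1 and n_bases > 1 or delta <= 0:
        raise InvalidParameterError(
            f"span {span} ms too short for {n_bases} bases with first peak at {p1} ms")

    centers = np.linspace(u1, un, n_bases)
    lag0 = dt if kind == "history" else 0.0
    lags = np.arange(lag0, span + 0.5 * dt, dt)
    lags = lags[lags <= span]
    if len(lags) < n_bases:
        raise InvalidParameterError(
            f"span {span} ms at dt {dt} ms has only {len(lags)} lags, fewer than "
            f"{n_bases} bases")
    arg = (psi(lags)[None, :] - centers[:, None]) * np.pi / (2.0 * delta)
    matrix = 0.5 * (1.0 + np.cos(np.clip(arg, -np.pi, np.pi)))
    if np.any(matrix.max(axis=1) <= 0.0):
        raise InvalidParameterError(
            f"span {span} ms too short to place {n_bases} distinct bases")
    # renormalize to unit peak on the sampled lag grid
    matrix = matrix / matrix.max(axis=1, keepdims=True)
    peak_lags = np.exp(centers) - stretch
    return CosineBasisSet(kind=kind, n_bases=n_bases, span=span, stretch=stretch,
                          dt=dt, matrix=matrix, lags=lags, peak_lags=peak_lags)
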