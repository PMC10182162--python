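"""Independent oracles used by the trend-solver tests.

These deliberately avoid the package's own solver path: the joint objective
is minimized as a generic smooth NLP via an epigraph reformulation of the
l1 terms, and lambda_max is found by bisection on the observed collapse of
the fit, so that both can certify the package's specialized routines.
"""

import numpy as np
from scipy.optimize import LinearConstraint, minimize
from scipy.special import expit

from channeltrend.trend import ConductanceGrid, fit_joint


def generic_convex_objective(datasets, grid: ConductanceGrid, lam: float) -> float:
    """Minimum of the penalized joint objective by a generic NLP solver.

    Epigraph form: auxiliary t_iq >= +/-(beta_i - beta_{i+1})_q turn the l1
    penalty into a linear objective with linear constraints; the smooth
    problem is solved with trust-constr and analytic gradients.
    """
    B = grid.n_points
    P = datasets[0].n_params
    w = grid.weights
    nb, npair = B * P, (B - 1) * P

    def fun(zvar):
        b = zvar[:nb].reshape(B, P)
        t = zvar[nb:].reshape(B - 1, P)
        val = 0.0
        gb = np.zeros((B, P))
        for i, d in enumerate(datasets):
            xb = d.X @ b[i]
            val += float(np.sum(np.maximum(xb, 0) + np.log1p(np.exp(-np.abs(xb)))
                                - d.y * xb))
            gb[i] = d.X.T @ (expit(xb) - d.y)
        val += lam * float(w @ t.sum(axis=1))
        gt = lam * np.tile(w[:, None], (1, P))
        return val, np.concatenate([gb.ravel(), gt.ravel()])

    rows = []
    for sgn in (1.0, -1.0):
        A = np.zeros((npair, nb + npair))
        for i in range(B - 1):
            for q in range(P):
                r = i * P + q
                A[r, i * P + q] = sgn
                A[r, (i + 1) * P + q] = -sgn
                A[r, nb + r] = -1.0
        rows.append(A)
    cons = LinearConstraint(np.vstack(rows), -np.inf, 0.0)
    z0 = np.zeros(nb + npair)
    z0[nb:] = 1.0
    res = minimize(fun, z0, jac=True, method="trust-constr", constraints=[cons],
                   options=dict(gtol=1e-10, xtol=1e-12, maxiter=3000))
    return float(res.fun)


def bisect_lambda_max(datasets, grid: ConductanceGrid, tol_frac: float = 0.002,
                      spread_tol: float = 1e-6) -> float:
    """Smallest lambda whose joint fit collapses, by bisection on the solver."""
    def collapsed(lam):
        return fit_joint(datasets, grid, lam).max_row_spread() < spread_tol

    lo, hi = 0.0, 1.0
    while not collapsed(hi):
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("bisection bracket failed")
    while (hi - lo) / hi > tol_frac:
        mid = 0.5 * (lo + hi)
        if collapsed(mid):
            hi = mid
        else:
            lo = mid
    return hi
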