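"""Coordinate descent for the minimax concave penalty (MCP).

Solves, for a decreasing ladder of penalties lambda with warm starts,

    min_b  (1/(2n)) * ||y - X b||^2  +  sum_j P(b_j; lambda, a)

where P(t; lambda, a) = lambda |t| - t^2 / (2a) for |t| <= a*lambda and
a*lambda^2 / 2 beyond, with concavity parameter a > 1.  Columns of X are
assumed standardized so that x_j'x_j / n = 1 and y is centered; under that
scaling the single-coordinate update is the firm-thresholding operator

    t(z) = sign(z) * max(|z| - lambda, 0) / (1 - 1/a)   for |z| <= a*lambda
    t(z) = z                                            otherwise

applied to the partial residual correlation z_j = x_j'r/n + b_j.

Each lambda is solved by cyclic full sweeps interleaved with active-set
sweeps over the current nonzero coordinates; convergence is declared when
the largest coefficient change in a full sweep falls below
tol * max(1, ||b||_inf).
"""

import numpy as np
from numba import njit

__all__ = ["mcp_path", "firm_threshold"]


def firm_threshold(z, lam, a):
    """Closed-form MCP solution for a single standardized coordinate."""
    z = np.asarray(z, dtype=float)
    inner = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0) / (1.0 - 1.0 / a)
    return np.where(np.abs(z) <= a * lam, inner, z)


@njit(cache=True)
def _update(z, lam, a):
    if abs(z) <= a * lam:
        az = abs(z) - lam
        if az <= 0.0:
            return 0.0
        s = 1.0 if z > 0.0 else -1.0
        return s * az * (a / (a - 1.0))
    return z


@njit(cache=True)
def _sweep(X, r, beta, lam, a, active_only):
    """One coordinate-descent sweep in place; returns max |coef change|."""
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        z = 0.0
        for i in range(n):
            z += X[i, j] * r[i]
        z = z / n + bj
        bnew = _update(z, lam, a)
        d = bj - bnew
        if d != 0.0:
            for i in range(n):
                r[i] += X[i, j] * d
            beta[j] = bnew
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd


@njit(cache=True)
def _mcp_path_cd(X, y, lambdas, a, tol, max_sweeps, stop_size):
    n, p = X.shape
    n_lam = lambdas.shape[0]
    out = np.zeros((n_lam, p))
    beta = np.zeros(p)
    r = y.copy()
    n_done = 0
    for li in range(n_lam):
        lam = lambdas[li]
        sweeps = 0
        while sweeps < max_sweeps:
            maxd = _sweep(X, r, beta, lam, a, False)
            sweeps += 1
            scale = max(1.0, np.abs(beta).max())
            if maxd < tol * scale:
                break
            # active-set refinement until the nonzero set stabilizes
            while sweeps < max_sweeps:
                maxd_in = _sweep(X, r, beta, lam, a, True)
                sweeps += 1
                scale = max(1.0, np.abs(beta).max())
                if maxd_in < tol * scale:
                    break
        out[li] = beta
        n_done = li + 1
        if stop_size > 0 and (beta != 0.0).sum() > stop_size:
            break
    return out, n_done


def mcp_path(X, y, lambdas, a=3.0, tol=1e-7, max_sweeps=10_000,
             stop_size=None, return_n_done=False):
    """Fit the MCP path by warm-started coordinate descent.

    Parameters
    ----------
    X : ndarray (n, p)
        Standardized design (column mean 0, column x'x/n = 1; columns of
        exactly zero variance must be passed as all-zero columns, which
        simply stay out of the model).
    y : ndarray (n,)
        Centered response.
    lambdas : ndarray
        Penalty ladder, visited in the given order (decreasing recommended).
    a : float
        MCP concavity parameter, must exceed 1.
    stop_size : int, optional
        Stop descending the ladder once the support exceeds this size
        (the first offending point is still computed); later path entries
        are returned as zero rows.
    return_n_done : bool
        Also return the number of path points actually computed.

    Returns
    -------
    ndarray (len(lambdas), p) of coefficients on the standardized scale,
    and optionally the number of computed path points.
    """
    if a <= 1.0:
        raise ValueError("MCP concavity parameter a must be > 1")
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if lambdas.size == 0:
        raise ValueError("empty lambda path")
    stop = 0 if stop_size is None else int(stop_size)
    out, n_done = _mcp_path_cd(X, y, lambdas, float(a), float(tol),
                               int(max_sweeps), stop)
    if return_n_done:
        return out, n_done
    return out
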