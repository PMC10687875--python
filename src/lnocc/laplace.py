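"""Factorizations of orbital-energy denominators.

Two interchangeable factorizations of 1/x on a positive interval are
provided:

* Laplace quadrature: 1/x ~ sum_w w_w exp(-x t_w), fitted by discretized
  least squares on a logarithmic grid, with the smallest number of points
  meeting the requested sup-norm relative error T_LT.  A single
  spin-independent quadrature serves all spin cases of a domain, which is
  what makes mixed-spin amplitudes assemblable from dressed one-index
  factors.
* Pivoted Cholesky of the Cauchy kernel 1/(x_p + x_q) over the pooled
  single-excitation gaps (cross-check path).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares


@dataclasses.dataclass
class LaplaceQuadrature:
    points: np.ndarray       # t_w
    weights: np.ndarray      # w_w
    x_min: float
    x_max: float
    tol: float               # T_LT, sup-norm relative error bound

    @property
    def n(self) -> int:
        return len(self.points)

    def eval(self, x: np.ndarray) -> np.ndarray:
        """Quadrature approximation to 1/x."""
        x = np.atleast_1d(np.asarray(x, float))
        return np.einsum("w,xw->x", self.weights,
                         np.exp(-np.outer(x, self.points)))

    def max_rel_error(self, ngrid: int = 400) -> float:
        x = np.geomspace(self.x_min, self.x_max, ngrid)
        return float(np.abs(self.eval(x) * x - 1.0).max())


class QuadratureError(RuntimeError):
    pass


def _fit_n(n: int, x_min: float, x_max: float):
    """Least-squares fit of n exponentials to 1/x on [x_min, x_max]."""
    grid = np.geomspace(x_min, x_max, max(200, 40 * n))

    def resid(p):
        t = np.exp(np.clip(p[:n], -50, 50))
        w = np.exp(np.clip(p[n:], -50, 50))
        return np.einsum("w,xw->x", w, np.exp(-np.outer(grid, t))) * grid - 1.0

    # start from the trapezoid discretization of int_0^inf e^{-xt} dt
    # under t = e^u, which is accurate for well-chosen u ranges
    u = np.linspace(np.log(0.05 / x_max), np.log(30.0 / x_min), n + 2)[1:-1]
    du = u[1] - u[0] if n > 1 else np.log(30.0 / x_min) - np.log(0.05 / x_max)
    p0 = np.concatenate([u, u + np.log(du)])
    sol = least_squares(resid, p0, method="lm", max_nfev=4000)
    t, w = np.exp(sol.x[:n]), np.exp(sol.x[n:])
    err = float(np.abs(resid(sol.x)).max())
    order = np.argsort(t)
    return t[order], w[order], err


def laplace_quadrature(x_min: float, x_max: float,
                       tol: float = 1e-2, n_max: int = 16) -> LaplaceQuadrature:
    """Smallest quadrature meeting the sup-norm relative error `tol`."""
    if not (0.0 < x_min <= x_max):
        raise QuadratureError(
            f"invalid denominator range [{x_min}, {x_max}]: non-positive "
            "gap signals near-degeneracy")
    if x_min == x_max:
        # one point reproduces 1/x exactly at the single x:
        # w exp(-x t) = 1/x with t = 1/x, w = e/x
        return LaplaceQuadrature(np.array([1.0 / x_min]),
                                 np.array([np.e / x_min]),
                                 x_min, x_max, tol)
    for n in range(1, n_max + 1):
        t, w, err = _fit_n(n, x_min, x_max)
        if err <= tol:
            return LaplaceQuadrature(t, w, x_min, x_max, tol)
    raise QuadratureError(
        f"no {n_max}-point quadrature reaches T_LT={tol} on "
        f"[{x_min}, {x_max}]")


def cauchy_cholesky(x: np.ndarray, tol: float = 1e-10):
    """Pivoted Cholesky factors of M_pq = 1/(x_p + x_q).

    Returns L (n, rank) with M ~ L L^T; deterministic pivot order
    (largest residual diagonal, ties by index).
    """
    x = np.asarray(x, float)
    n = len(x)
    M = 1.0 / (x[:, None] + x[None, :])
    d = np.diag(M).copy()
    L = np.zeros((n, n))
    dmax0 = float(d.max())
    for k in range(n):
        p = int(np.argmax(d))
        if d[p] <= tol * dmax0:
            return L[:, :k]
        L[:, k] = (M[:, p] - L[:, :k] @ L[p, :k]) / np.sqrt(d[p])
        d = np.maximum(d - L[:, k] ** 2, 0.0)
        d[p] = 0.0
    return L
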