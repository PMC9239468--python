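"""Cubic regression spline bases with curvature penalties, and the
tensor-product functional design.

The basis is the classic value-parameterised natural cubic regression
spline: coefficient k is the spline's value at knot k, the second
derivatives at the knots follow from the natural boundary conditions, and
the curvature penalty integral(f'')^2 is an exact quadratic form in the
coefficients.  Evaluation outside the knot range extrapolates linearly
(the natural-spline continuation).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CubicRegressionSpline",
    "knots_from_quantiles",
    "build_functional_design",
    "trapezoid_weights",
]


def knots_from_quantiles(values: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at empirical quantiles, boundary knots at the observed min/max."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if np.unique(values).size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct values to place {n_knots} knots"
        )
    q = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(values, q)
    # quantile ties (heavily repeated values) would collapse knots
    knots = np.unique(knots)
    if knots.size < n_knots:
        raise ValueError("quantile knots collapsed; too many tied values")
    return knots


class CubicRegressionSpline:
    """Natural cubic regression spline on fixed knots.

    Parameters
    ----------
    knots:
        Strictly increasing array of length K >= 4.

    Notes
    -----
    With coefficients beta (values at the knots), the interior second
    derivatives are ``delta = F beta`` where F solves the standard
    tridiagonal natural-spline system, and the curvature penalty is
    ``beta' S beta = integral (f'')^2`` with ``S = D' B^{-1} D``.
    The penalty null space is exactly the linear functions.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 4:
            raise ValueError("need at least 4 strictly increasing knots")
        if (np.diff(knots) <= 0).any():
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        K = knots.size
        h = np.diff(knots)
        D = np.zeros((K - 2, K))
        B = np.zeros((K - 2, K - 2))
        for i in range(K - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < K - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        self._h = h
        #: (K, K) map from coefficients to knot second derivatives
        self.F = np.zeros((K, K))
        self.F[1:-1] = np.linalg.solve(B, D)
        #: (K, K) curvature penalty, symmetric positive semidefinite
        self.penalty = D.T @ np.linalg.solve(B, D)
        self.penalty = 0.5 * (self.penalty + self.penalty.T)

    @property
    def n_basis(self) -> int:
        return self.knots.size

    def _eval_inside(self, x: np.ndarray, deriv: int) -> np.ndarray:
        """Basis (or first-derivative) rows for x within the knot range."""
        K = self.knots.size
        k = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0, K - 2)
        h = self._h[k]
        xm = x - self.knots[k]          # distance above left knot
        xp = self.knots[k + 1] - x      # distance below right knot
        rows = np.zeros((x.size, K))
        if deriv == 0:
            a_l, a_r = xp / h, xm / h
            c_l = (xp ** 3 / h - h * xp) / 6.0
            c_r = (xm ** 3 / h - h * xm) / 6.0
        else:
            a_l, a_r = -1.0 / h, 1.0 / h
            c_l = (-3.0 * xp ** 2 / h + h) / 6.0
            c_r = (3.0 * xm ** 2 / h - h) / 6.0
        idx = np.arange(x.size)
        rows[idx, k] += a_l
        rows[idx, k + 1] += a_r
        rows += c_l[:, None] * self.F[k] + c_r[:, None] * self.F[k + 1]
        return rows

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the K basis functions at x (linear extrapolation outside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.knots[0], self.knots[-1]
        inside = (x >= lo) & (x <= hi)
        out = np.empty((x.size, self.knots.size))
        if inside.any():
            out[inside] = self._eval_inside(x[inside], deriv=0)
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if mask.any():
                b = np.array([bound])
                base = self._eval_inside(b, deriv=0)
                slope = self._eval_inside(b, deriv=1)
                out[mask] = base + (x[mask] - bound)[:, None] * slope
        return out


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for a (possibly non-uniform) grid."""
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += 0.5 * d
    w[1:] += 0.5 * d
    return w


def build_functional_design(
    curves: np.ndarray,
    s_grid: np.ndarray,
    basis_s: CubicRegressionSpline,
    basis_x: CubicRegressionSpline,
) -> np.ndarray:
    """Per-subject tensor design V_i with entries
    integral B_j(s) B_k(X_i(s)) ds, by trapezoid quadrature on ``s_grid``.

    ``curves`` is (N, L) with curve values X_i(s_l); ``s_grid`` has length L
    (assumed already scaled to the fitting domain, conventionally [0, 1]).
    Entries are ordered j * K_x + k, matching a kron(S_s, I) / kron(I, S_x)
    penalty embedding.  Curve values outside the x-basis knot range are
    handled by the basis's linear extrapolation, with a warning.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if not np.isfinite(curves).all():
        raise ValueError("curves must be finite")
    n, L = curves.shape
    if s_grid.size != L:
        raise ValueError("s_grid length does not match the curve matrix")
    lo, hi = basis_x.knots[0], basis_x.knots[-1]
    n_out = int(((curves < lo) | (curves > hi)).sum())
    if n_out:
        logger.warning(
            "%d curve value(s) outside the x-basis knot range "
            "[%g, %g]; extending linearly", n_out, lo, hi,
        )
    w = trapezoid_weights(s_grid)
    Bs = basis_s.design_matrix(s_grid)                      # (L, Ks)
    Bx = basis_x.design_matrix(curves.ravel())              # (N*L, Kx)
    Bx = Bx.reshape(n, L, basis_x.n_basis)
    V = np.einsum("lj,l,nlk->njk", Bs, w, Bx)
    return V.reshape(n, -1)
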