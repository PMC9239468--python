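"""Functional principal component analysis of summary curves.

Eigen-decomposition of the sample covariance surface with trapezoid
quadrature weights: eigenfunctions are orthonormal with respect to the
grid quadrature, eigenvalues estimate the Karhunen-Loeve score variances.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .basis import trapezoid_weights

__all__ = ["FunctionalPCA"]


class FunctionalPCA(BaseEstimator, TransformerMixin):
    """FPCA of curves observed on a common grid.

    Parameters
    ----------
    pve:
        Proportion of variance explained; the number of retained components
        is the smallest M reaching it (unless ``n_components`` is set).
    n_components:
        Fixed number of components, overriding ``pve``.

    Attributes
    ----------
    grid_:
        The common grid.
    mean_:
        Mean function on the grid.
    eigenvalues_:
        Retained eigenvalues, nonnegative and nonincreasing.
    components_:
        (M, L) eigenfunctions, orthonormal w.r.t. the quadrature weights.
    pve_:
        Cumulative proportion of variance explained per retained component.
    """

    def __init__(self, pve: float = 0.99, n_components: int | None = None):
        self.pve = pve
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None, grid: np.ndarray | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, L = X.shape
        if n < 2:
            raise ValueError("need at least 2 curves for FPCA")
        if grid is None:
            grid = np.linspace(0.0, 1.0, L)
        grid = np.asarray(grid, dtype=float)
        if grid.size != L:
            raise ValueError("grid length does not match the curves")
        w = trapezoid_weights(grid)
        self.grid_ = grid
        self.quad_w_ = w
        self.mean_ = X.mean(axis=0)
        C = np.cov(X, rowvar=False, ddof=1)
        # quadrature-weighted eigenproblem: W^1/2 C W^1/2 u = e u,
        # phi = W^-1/2 u  =>  integral phi_a phi_b dW = delta_ab
        sw = np.sqrt(w)
        M = sw[:, None] * C * sw[None, :]
        evals, evecs = np.linalg.eigh(0.5 * (M + M.T))
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        phis = (evecs[:, order] / sw[:, None]).T
        total = evals.sum()
        cum = np.cumsum(evals) / total if total > 0 else np.ones_like(evals)
        if self.n_components is not None:
            m = int(self.n_components)
        elif total == 0:
            m = 0
        else:
            m = int(np.searchsorted(cum, self.pve) + 1)
            m = min(m, evals.size)
        self.eigenvalues_all_ = evals
        self.eigenvalues_ = evals[:m]
        self.components_ = phis[:m]
        self.pve_ = cum[:m]
        self.n_components_ = m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Quadrature inner products of centered curves with eigenfunctions."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        centered = X - self.mean_
        return (centered * self.quad_w_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean_ + scores @ self.components_
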