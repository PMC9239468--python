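"""Additive functional Cox regression.

The log hazard for subject i is modelled as

    log lambda_i(t) = log lambda_0(t) + Z_i' beta + integral F(s, X_i(s)) ds

with Z_i scalar covariates, X_i(s) a functional covariate on a shared grid,
and F a smooth surface expanded in a tensor product of cubic regression
splines, F(s, x) = sum_jk theta_jk B_j(s) B_k(x).  Writing V_i for the
vector of quadrature integrals of B_j(s) B_k(X_i(s)), the linear predictor
is W_i' gamma with W_i = (Z_i, V_i) and gamma = (beta, theta).

Estimation maximizes the Breslow-ties penalized partial log-likelihood

    l_p(gamma | lambda) = sum_i delta_i { W_i'gamma
        - log sum_{Y_j >= Y_i} exp(W_j'gamma) } - 1/2 gamma' D_lambda gamma

by Newton-Raphson with step halving, where D_lambda embeds the marginal
curvature penalties of the two spline bases (one smoothing parameter per
margin by default).  Smoothing parameters maximize the log Laplace
approximate marginal likelihood

    V(lambda) = l_p(gamma_hat) + 1/2 log|D_lambda|_+ - 1/2 log|H_p|
                + (M_p / 2) log(2 pi)

with |.|_+ the product of positive eigenvalues, H_p the penalized negative
Hessian at the optimum and M_p the penalty null-space dimension.  The
surface carries identifiability constraints: its contributions sum to zero
over the training subjects (the partial likelihood cannot identify an
additive constant), and the linear-in-s, constant-in-x component -- whose
contribution is subject-independent yet penalty-free -- is removed (see
``_functional_constraints``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .basis import (
    CubicRegressionSpline,
    build_functional_design,
    knots_from_quantiles,
    trapezoid_weights,
)
from .hazard import StepCumulativeHazard

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "cox_partial_loglik",
    "penalized_cox_newton",
    "laml_value",
    "select_smoothing_laml",
    "AdditiveFunctionalCoxModel",
    "fit_afcm",
    "predict_linear_predictor",
    "evaluate_surface",
    "breslow_cumulative_baseline",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the step trace for diagnosis."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# partial likelihood


def _parse_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (N, 2) [time, event], a structured array, or a 2-tuple."""
    if isinstance(y, tuple) and len(y) == 2:
        time, event = y
    elif hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        time, event = y[names[0]], y[names[1]]
        if np.issubdtype(np.asarray(time).dtype, np.bool_):
            time, event = event, time
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("y must be (N, 2) [time, event] or equivalent")
        time, event = arr[:, 0], arr[:, 1]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


@dataclass(frozen=True)
class _RiskStructure:
    """Sort order and tie-group bookkeeping for risk-set sums."""

    order: np.ndarray        # ascending-time permutation
    time: np.ndarray         # sorted times
    event: np.ndarray        # sorted indicators
    group_start: np.ndarray  # per sorted index, first index of its tie group

    @classmethod
    def build(cls, time: np.ndarray, event: np.ndarray) -> "_RiskStructure":
        order = np.argsort(time, kind="stable")
        t = time[order]
        uniq, first = np.unique(t, return_index=True)
        group_start = first[np.searchsorted(uniq, t)]
        return cls(order=order, time=t, event=event[order], group_start=group_start)


def cox_partial_loglik(
    W: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    gamma: np.ndarray,
    risk: _RiskStructure | None = None,
    want_hess: bool = True,
):
    """Breslow-ties Cox partial log-likelihood with gradient and Hessian.

    Risk-set sums are reverse cumulative sums over subjects sorted by time,
    evaluated at each event's tie-group start so that tied subjects remain
    in each other's risk sets.
    """
    if risk is None:
        risk = _RiskStructure.build(time, event)
    Ws = W[risk.order]
    eta = Ws @ gamma
    shift = eta.max()
    w = np.exp(eta - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Ws)[::-1], axis=0)[::-1]
    ev = risk.event == 1
    g = risk.group_start[ev]
    if g.size == 0:
        raise ValueError("no events in the data")
    loglik = float(eta[ev].sum() - (np.log(S0[g]) + shift).sum())
    mu = S1[g] / S0[g, None]
    grad = Ws[ev].sum(axis=0) - mu.sum(axis=0)
    if not want_hess:
        return loglik, grad, None
    WW = np.einsum("ni,nj->nij", Ws, Ws)
    S2 = np.cumsum((w[:, None, None] * WW)[::-1], axis=0)[::-1]
    hess = -(
        np.einsum("kij->ij", S2[g] / S0[g, None, None])
        - np.einsum("ki,kj->ij", mu, mu)
    )
    return loglik, grad, hess


def penalized_cox_newton(
    W: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    penalty: np.ndarray | None = None,
    gamma0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    risk: _RiskStructure | None = None,
) -> dict:
    """Maximize the penalized partial log-likelihood by damped Newton steps.

    ``penalty`` is the full quadratic-form matrix D_lambda (zero block for
    unpenalized coefficients); the objective is l(gamma) - 1/2 gamma' D gamma.
    Steps that do not increase the objective are halved (up to 30 times).
    Convergence requires the penalized gradient's max-norm to fall below
    ``tol * (1 + |l_p|)``.
    """
    W = np.asarray(W, dtype=float)
    n, d = W.shape
    if penalty is None:
        penalty = np.zeros((d, d))
    if gamma0 is None:
        gamma0 = np.zeros(d)
    if risk is None:
        risk = _RiskStructure.build(time, event)
    gamma = np.asarray(gamma0, dtype=float).copy()
    trace: list[dict] = []

    def objective(gm, want_hess=True):
        ll, gr, hs = cox_partial_loglik(
            W, time, event, gm, risk=risk, want_hess=want_hess
        )
        lp = ll - 0.5 * gm @ penalty @ gm
        return ll, lp, gr - penalty @ gm, hs

    loglik, lp, grad_p, hess = objective(gamma)
    converged = False
    for it in range(max_iter):
        if np.max(np.abs(grad_p)) < tol * (1.0 + abs(lp)):
            converged = True
            break
        A = -hess + penalty
        # symmetric Jacobi equilibration: keeps the solve accurate when the
        # penalty dwarfs the likelihood curvature in some directions
        scale = 1.0 / np.sqrt(np.maximum(np.diag(A), 1e-12))
        As = scale[:, None] * A * scale[None, :]
        try:
            step = scale * np.linalg.solve(As, scale * grad_p)
        except np.linalg.LinAlgError:
            As += 1e-8 * np.eye(d)
            step = scale * np.linalg.solve(As, scale * grad_p)
        if not np.isfinite(step).all():
            raise ConvergenceError("non-finite Newton step", trace)
        # step halving: accept only ascent of the penalized objective
        # (Hessian deferred until a step is accepted)
        alpha, accepted = 1.0, False
        for _ in range(30):
            cand = gamma + alpha * step
            ll_c, lp_c, gp_c, _ = objective(cand, want_hess=False)
            if np.isfinite(lp_c) and lp_c >= lp - 1e-12 * (1 + abs(lp)):
                gamma, loglik, lp, grad_p = cand, ll_c, lp_c, gp_c
                hess = objective(gamma, want_hess=True)[3]
                accepted = True
                break
            alpha *= 0.5
        trace.append({"iter": it, "lp": lp, "grad_max": float(np.max(np.abs(grad_p))),
                      "step_scale": alpha})
        if not accepted:
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad_p)) >= tol * (1.0 + abs(lp)):
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(|grad|_inf = {np.max(np.abs(grad_p)):.3e})",
            trace,
        )
    return {
        "gamma": gamma,
        "loglik": loglik,
        "penalized_loglik": lp,
        "grad": grad_p,
        "hess": hess,
        "n_iter": len(trace),
        "converged": True,
        "trace": trace,
    }


# ---------------------------------------------------------------------------
# smoothing selection


def laml_value(fit: dict, penalty: np.ndarray, rank_tol: float = 1e-8) -> float:
    """Log Laplace approximate marginal likelihood of a converged fit.

    V = l_p + 1/2 log|D_lambda|_+ - 1/2 log|H_p| + (M_p / 2) log(2 pi),
    with H_p = -(H - D_lambda) the penalized negative Hessian and M_p the
    number of zero eigenvalues of D_lambda.
    """
    eigvals = np.linalg.eigvalsh(penalty)
    cutoff = rank_tol * max(eigvals.max(), 1e-300)
    positive = eigvals[eigvals > cutoff]
    m_p = int((eigvals <= cutoff).sum())
    log_pdet = float(np.sum(np.log(positive))) if positive.size else 0.0
    Hp = -fit["hess"] + penalty
    sign, logdet = np.linalg.slogdet(Hp)
    if sign <= 0:
        raise np.linalg.LinAlgError("penalized Hessian not positive definite")
    return (
        fit["penalized_loglik"]
        + 0.5 * log_pdet
        - 0.5 * logdet
        + 0.5 * m_p * np.log(2.0 * np.pi)
    )


def select_smoothing_laml(
    W: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    penalty_parts: list[np.ndarray],
    tie_lambdas: bool = False,
    log10_bounds: tuple[float, float] = (-8.0, 8.0),
    coarse_grid: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Choose smoothing parameters by maximizing the LAML criterion.

    A coarse tied grid over log10(lambda) seeds a Nelder-Mead refinement of
    the per-margin log smoothing parameters (joint over margins unless
    ``tie_lambdas``).  Fits are warm-started across candidates.  Candidates
    whose inner Newton fails score -inf; if every candidate fails, an error
    is raised.
    """
    if coarse_grid is None:
        coarse_grid = np.array([-3.0, -1.0, 1.0, 3.0, 5.0])
    risk = _RiskStructure.build(time, event)
    n_parts = len(penalty_parts)
    state = {"gamma": None, "best": (-np.inf, None, None)}

    def penalty_of(log10_lams: np.ndarray) -> np.ndarray:
        lams = 10.0 ** np.clip(log10_lams, *log10_bounds)
        if tie_lambdas or lams.size == 1:
            lams = np.full(n_parts, lams[0] if lams.size else 1.0)
        return sum(l * P for l, P in zip(lams, penalty_parts))

    def score(log10_lams: np.ndarray):
        log10_lams = np.atleast_1d(log10_lams)
        D = penalty_of(log10_lams)
        try:
            fit = penalized_cox_newton(
                W, time, event, D, gamma0=state["gamma"],
                max_iter=max_iter, tol=tol, risk=risk,
            )
        except (ConvergenceError, np.linalg.LinAlgError):
            return -np.inf
        state["gamma"] = fit["gamma"]
        try:
            value = laml_value(fit, D)
        except np.linalg.LinAlgError:
            return -np.inf
        if value > state["best"][0]:
            state["best"] = (value, log10_lams.copy(), fit)
        return value

    grid_scores = np.array([score(np.array([lg])) for lg in coarse_grid])
    if not np.isfinite(grid_scores).any():
        raise ConvergenceError("no smoothing candidate produced a converged fit")
    best = coarse_grid[int(np.nanargmax(grid_scores))]
    x0 = np.full(1 if tie_lambdas else n_parts, float(best))

    minimize(
        lambda v: -score(v),
        x0,
        method="Nelder-Mead",
        options={"maxfev": 40, "xatol": 0.05, "fatol": 1e-4},
    )
    v_best, x_best, fit_best = state["best"]
    if fit_best is None:
        raise ConvergenceError("LAML optimum did not produce a converged fit")
    lams = 10.0 ** np.clip(np.atleast_1d(x_best), *log10_bounds)
    if tie_lambdas or lams.size == 1:
        lams = np.full(n_parts, lams[0])
    at_edge = bool(
        np.any(np.abs(np.atleast_1d(x_best) - log10_bounds[0]) < 1e-6)
        or np.any(np.abs(np.atleast_1d(x_best) - log10_bounds[1]) < 1e-6)
    )
    return {
        "lambdas": lams,
        "penalty": penalty_of(np.atleast_1d(x_best)),
        "fit": fit_best,
        "laml": v_best,
        "coarse_grid": coarse_grid,
        "coarse_values": grid_scores,
        "at_boundary": at_edge,
    }


# ---------------------------------------------------------------------------
# identifiability constraints for the tensor surface


def _functional_constraints(
    V: np.ndarray, basis_s: CubicRegressionSpline, basis_x: CubicRegressionSpline
) -> np.ndarray:
    """Constraint matrix (columns) for the tensor surface coefficients.

    The partial likelihood sees the surface only through between-subject
    differences of the functional contributions V_i' theta, so coefficient
    directions in the null space of the *centered* design are
    unidentifiable.  Those of them that the curvature penalty also cannot
    see (e.g. the constant surface -- always, since sum-to-zero centering
    removes it -- and the linear-in-s, constant-in-x component, whose
    contribution is subject-independent because the x-basis is a partition
    of unity) would make the penalized Hessian exactly singular.  This
    routine returns an orthonormal basis of exactly that
    jointly-null subspace; the fit proceeds in its orthogonal complement.
    Unidentifiable but penalized directions are kept: the penalty shrinks
    them to zero on its own.
    """
    Vc = V - V.mean(axis=0)
    d = V.shape[1]
    _, svals, Vt = np.linalg.svd(Vc, full_matrices=True)
    # directions this far below the design's scale are numerically invisible
    # to the likelihood even if not exact zeros; the uncentered magnitude
    # guards the fully degenerate case (all curves identical)
    scale_v = max(float(svals.max()) if svals.size else 0.0, float(np.abs(V).max()))
    tol = 1e-10 * (scale_v if scale_v > 0 else 1.0)
    n_pos = int((svals > tol).sum())
    N = Vt[n_pos:].T                     # basis of the design null space
    if N.shape[1] == 0:
        return np.empty((d, 0))
    Kx = basis_x.n_basis
    P = np.kron(basis_s.penalty, np.eye(Kx)) + np.kron(
        np.eye(basis_s.n_basis), basis_x.penalty
    )
    Pn = N.T @ P @ N
    evals, evecs = np.linalg.eigh(0.5 * (Pn + Pn.T))
    scale = max(np.abs(evals).max(), np.trace(P) / d)
    degenerate = evals < 1e-9 * scale
    return N @ evecs[:, degenerate]


def _null_space_basis(constraints: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of the constraints."""
    d, k = constraints.shape
    if k == 0:
        return np.eye(d)
    q, _ = np.linalg.qr(np.hstack([constraints, np.eye(d)]))
    return q[:, k:]


# ---------------------------------------------------------------------------
# the estimator


class AdditiveFunctionalCoxModel(BaseEstimator):
    """Additive functional Cox model with penalized tensor-product surface.

    Parameters
    ----------
    n_scalar:
        Number of leading columns of ``X`` holding scalar covariates; the
        remaining columns are the functional covariate sampled on ``s_grid``.
    s_grid:
        Distance grid of the functional covariate (required when functional
        columns are present).  Internally rescaled to [0, 1].
    n_basis_s, n_basis_x:
        Marginal cubic-regression-spline dimensions (default 5 and 5, i.e.
        25 tensor coefficients, keeping small cohorts estimable).
    tie_lambdas:
        Share one smoothing parameter across both margins.
    lambda_grid:
        Optional coarse grid of log10(lambda) values seeding LAML search.

    The design is column-centered internally (improves conditioning; the
    partial likelihood is invariant).  Fitted attributes follow sklearn
    conventions (trailing underscore).
    """

    def __init__(
        self,
        n_scalar: int = 0,
        s_grid: np.ndarray | None = None,
        n_basis_s: int = 5,
        n_basis_x: int = 5,
        tie_lambdas: bool = False,
        lambda_grid: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-8,
    ):
        self.n_scalar = n_scalar
        self.s_grid = s_grid
        self.n_basis_s = n_basis_s
        self.n_basis_x = n_basis_x
        self.tie_lambdas = tie_lambdas
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter
        self.tol = tol

    # -- design construction ------------------------------------------------

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = int(self.n_scalar)
        if p < 0 or p > X.shape[1]:
            raise ValueError("n_scalar out of range for the design matrix")
        Z = X[:, :p]
        curves = X[:, p:] if X.shape[1] > p else None
        return Z, curves

    def _functional_design(self, curves: np.ndarray) -> np.ndarray:
        if curves.shape[1] != self.s01_.size:
            raise ValueError(
                f"curves have {curves.shape[1]} grid points; "
                f"model was fit on {self.s01_.size}"
            )
        return build_functional_design(curves, self.s01_, self.basis_s_, self.basis_x_)

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "AdditiveFunctionalCoxModel":
        time, event = _parse_survival(y)
        Z, curves = self._split(X)
        n = Z.shape[0]
        if time.size != n:
            raise ValueError("X and y have different lengths")
        has_functional = curves is not None and curves.shape[1] > 0
        self.has_functional_ = has_functional
        self.has_scalar_ = Z.shape[1] > 0
        if not (self.has_functional_ or self.has_scalar_):
            raise ValueError("model needs at least one covariate")

        blocks = []
        if self.has_scalar_:
            blocks.append(Z)
        if has_functional:
            if self.s_grid is None:
                raise ValueError("s_grid is required for a functional term")
            s = np.asarray(self.s_grid, dtype=float)
            if s.size != curves.shape[1]:
                raise ValueError("s_grid length does not match curve columns")
            self.s_range_ = (float(s[0]), float(s[-1]))
            self.s01_ = (s - s[0]) / (s[-1] - s[0])
            self.quad_w_ = trapezoid_weights(self.s01_)
            self.basis_s_ = CubicRegressionSpline(
                knots_from_quantiles(self.s01_, self.n_basis_s)
            )
            self.basis_x_ = CubicRegressionSpline(
                knots_from_quantiles(curves.ravel(), self.n_basis_x)
            )
            V = self._functional_design(curves)
            self.constraint_ = _functional_constraints(V, self.basis_s_, self.basis_x_)
            self.null_basis_ = _null_space_basis(self.constraint_)
            blocks.append(V @ self.null_basis_)
        design = np.hstack(blocks)
        self.design_mean_ = design.mean(axis=0)
        design = design - self.design_mean_

        p = Z.shape[1] if self.has_scalar_ else 0
        if has_functional:
            dim_theta = self.null_basis_.shape[1]
            Ks, Kx = self.basis_s_.n_basis, self.basis_x_.n_basis
            P_s = np.kron(self.basis_s_.penalty, np.eye(Kx))
            P_x = np.kron(np.eye(Ks), self.basis_x_.penalty)
            parts = []
            for P in (P_s, P_x):
                Pc = self.null_basis_.T @ P @ self.null_basis_
                full = np.zeros((p + dim_theta, p + dim_theta))
                full[p:, p:] = 0.5 * (Pc + Pc.T)
                parts.append(full)
            sel = select_smoothing_laml(
                design, time, event, parts,
                tie_lambdas=self.tie_lambdas,
                coarse_grid=self.lambda_grid,
                max_iter=self.max_iter, tol=self.tol,
            )
            fit = sel["fit"]
            self.lambda_ = sel["lambdas"]
            self.laml_ = sel["laml"]
            self.laml_grid_ = (sel["coarse_grid"], sel["coarse_values"])
            self.lambda_at_boundary_ = sel["at_boundary"]
            self.penalty_ = sel["penalty"]
        else:
            fit = penalized_cox_newton(
                design, time, event, None, max_iter=self.max_iter, tol=self.tol
            )
            self.lambda_ = np.array([])
            self.laml_ = None
            self.penalty_ = np.zeros((design.shape[1],) * 2)

        gamma = fit["gamma"]
        self.coef_ = gamma
        self.coef_scalar_ = gamma[:p].copy()
        if has_functional:
            theta = self.null_basis_ @ gamma[p:]
            self.coef_theta_ = theta.reshape(
                self.basis_s_.n_basis, self.basis_x_.n_basis
            )
        self.loglik_ = fit["loglik"]
        self.penalized_loglik_ = fit["penalized_loglik"]
        self.final_grad_norm_ = float(np.max(np.abs(fit["grad"])))
        self.n_iter_ = fit["n_iter"]
        self.converged_ = fit["converged"]
        self.n_events_ = int(event.sum())

        # Breslow baseline on the centered linear predictor scale
        eta = design @ gamma
        self.train_eta_ = eta
        self.baseline_hazard_ = _breslow(time, event, eta)
        self._train_design_cols_ = design.shape[1]
        return self

    # -- prediction ---------------------------------------------------------

    def _design_new(self, X: np.ndarray) -> np.ndarray:
        Z, curves = self._split(X)
        blocks = []
        if self.has_scalar_:
            blocks.append(Z)
        if self.has_functional_:
            if curves is None or curves.shape[1] == 0:
                raise ValueError("model has a functional term; curves required")
            V = self._functional_design(curves)
            blocks.append(V @ self.null_basis_)
        design = np.hstack(blocks)
        if design.shape[1] != self._train_design_cols_:
            raise ValueError("new design does not match the training layout")
        return design - self.design_mean_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor eta_hat = Z'beta + V'theta (training centering)."""
        return self._design_new(X) @ self.coef_

    def predict_cumulative_hazard(self, X: np.ndarray, times: np.ndarray) -> np.ndarray:
        eta = self.predict(X)
        base = self.baseline_hazard_(times)
        return np.exp(eta)[:, None] * base[None, :]

    def evaluate_surface(
        self, s: np.ndarray, x: np.ndarray, scaled: bool = False
    ) -> np.ndarray:
        """Estimated surface F_hat on the grid s (rows) by x (columns).

        ``s`` is on the original functional-domain scale unless ``scaled``.
        Evaluation outside the knot ranges extrapolates linearly, with a
        warning.
        """
        if not self.has_functional_:
            raise ValueError("model has no functional term")
        s = np.atleast_1d(np.asarray(s, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not scaled:
            lo, hi = self.s_range_
            s = (s - lo) / (hi - lo)
        for vals, basis, name in ((s, self.basis_s_, "s"), (x, self.basis_x_, "x")):
            if vals.min() < basis.knots[0] - 1e-12 or vals.max() > basis.knots[-1] + 1e-12:
                logger.warning("extrapolating the surface beyond the %s knots", name)
        Bs = self.basis_s_.design_matrix(s)
        Bx = self.basis_x_.design_matrix(x)
        return Bs @ self.coef_theta_ @ Bx.T


def _breslow(time: np.ndarray, event: np.ndarray, eta: np.ndarray) -> StepCumulativeHazard:
    """Breslow step estimator of the cumulative baseline hazard."""
    risk = _RiskStructure.build(time, event)
    eta_s = eta[risk.order]
    shift = eta_s.max() if eta_s.size else 0.0
    w = np.exp(eta_s - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    ev = risk.event == 1
    if not ev.any():
        return StepCumulativeHazard(np.array([]), np.array([]))
    t_ev = risk.time[ev]
    g_ev = risk.group_start[ev]
    uniq, first, counts = np.unique(t_ev, return_index=True, return_counts=True)
    jumps = counts / (S0[g_ev[first]] * np.exp(shift))
    return StepCumulativeHazard(uniq, np.cumsum(jumps))


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_afcm(
    time: np.ndarray,
    event: np.ndarray,
    scalars: np.ndarray | None = None,
    curves: np.ndarray | None = None,
    s_grid: np.ndarray | None = None,
    **params,
) -> AdditiveFunctionalCoxModel:
    """Convenience wrapper assembling X = [scalars | curves] and fitting."""
    blocks = []
    p = 0
    if scalars is not None:
        Z = np.atleast_2d(np.asarray(scalars, dtype=float))
        if Z.shape[0] == 1 and np.asarray(time).size != 1:
            Z = Z.T
        p = Z.shape[1]
        blocks.append(Z)
    if curves is not None:
        blocks.append(np.atleast_2d(np.asarray(curves, dtype=float)))
    if not blocks:
        raise ValueError("need scalars and/or curves")
    X = np.hstack(blocks)
    model = AdditiveFunctionalCoxModel(n_scalar=p, s_grid=s_grid, **params)
    y = np.column_stack([np.asarray(time, float), np.asarray(event, float)])
    return model.fit(X, y)


def predict_linear_predictor(
    model: AdditiveFunctionalCoxModel,
    scalars: np.ndarray | None = None,
    curves: np.ndarray | None = None,
) -> np.ndarray:
    blocks = []
    if scalars is not None:
        Z = np.atleast_2d(np.asarray(scalars, dtype=float))
        if Z.shape[0] == 1 and (curves is None or np.atleast_2d(curves).shape[0] != 1):
            Z = Z.T
        blocks.append(Z)
    if curves is not None:
        blocks.append(np.atleast_2d(np.asarray(curves, dtype=float)))
    return model.predict(np.hstack(blocks))


def evaluate_surface(model: AdditiveFunctionalCoxModel, s, x, scaled=False):
    return model.evaluate_surface(s, x, scaled=scaled)


def breslow_cumulative_baseline(model: AdditiveFunctionalCoxModel) -> StepCumulativeHazard:
    return model.baseline_hazard_


# ---------------------------------------------------------------------------
# serialization (model dump for the CLI)


def model_to_json(model: AdditiveFunctionalCoxModel) -> str:
    payload = {
        "params": model.get_params(),
        "coef": model.coef_.tolist(),
        "coef_scalar": model.coef_scalar_.tolist(),
        "lambda": np.asarray(model.lambda_).tolist(),
        "laml": model.laml_,
        "loglik": model.loglik_,
        "final_grad_norm": model.final_grad_norm_,
        "n_iter": model.n_iter_,
        "n_events": model.n_events_,
        "baseline": {
            "times": model.baseline_hazard_.times.tolist(),
            "values": model.baseline_hazard_.values.tolist(),
        },
    }
    payload["params"]["s_grid"] = (
        None if model.s_grid is None else np.asarray(model.s_grid).tolist()
    )
    payload["params"]["lambda_grid"] = (
        None if model.lambda_grid is None else np.asarray(model.lambda_grid).tolist()
    )
    if model.has_functional_:
        payload.update(
            {
                "coef_theta": model.coef_theta_.tolist(),
                "knots_s": model.basis_s_.knots.tolist(),
                "knots_x": model.basis_x_.knots.tolist(),
                "constraint": model.constraint_.tolist(),
                "s_range": list(model.s_range_),
            }
        )
    return json.dumps(payload, indent=2)
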