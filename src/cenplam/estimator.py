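"""Partially linear additive model estimation for right-censored responses.

The model for the (conditionally expected) response is

    E[z | x, t] = beta0 + x' beta + sum_j f_j(t_j),       E f_j = 0,

with a p-dimensional parametric part and q univariate smooth components
estimated by local linear regression.  Censoring in the response is handled
by one of three working-response constructions (synthetic transformation,
Kaplan–Meier weights, kNN imputation) before the least-squares machinery
runs.  Estimation proceeds by modified backfitting: per-component GCV
bandwidth selection, then alternating (weighted) least-squares updates of
``beta`` and smoother updates of each ``f_j`` against partial residuals.
An equivalent non-iterative solution via the additive smoother matrix
``S_A`` is available for moderate n and doubles as an internal oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .censoring import (
    CensoredDataset,
    fit_km_censoring,
    kaplan_meier_weights,
    knn_impute,
    select_k,
    select_reference_predictor,
    synthetic_transform,
)
from .smoothing import (
    SmootherMatrix,
    center_smoother,
    degrees_of_freedom,
    hat_matrix,
    llr_smoother,
    select_bandwidth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PLAMFit",
    "PLAMRegressor",
    "backfit",
    "fit_noniterative",
    "estimate_variance",
    "beta_bias",
    "beta_variance",
]

METHODS = ("st", "kmw", "knni")

#: size guards for materializing the additive smoother of the direct solver
DIRECT_MAX_N = 300
DIRECT_MAX_Q = 3


@dataclass
class PLAMFit:
    """Result bundle of a right-censored PLAM fit."""

    beta0: float
    beta: np.ndarray
    components: np.ndarray        # n x q, each column mean-zero
    bandwidths: np.ndarray        # q chosen bandwidths
    hat: np.ndarray               # overall hat matrix H_A (working-response scale)
    sigma2: float
    df: float
    method: str
    iterations: int
    converged: bool
    fitted_values: np.ndarray
    working_response: np.ndarray
    weights: np.ndarray | None = None
    k: int | None = None
    extras: dict = field(default_factory=dict)


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros(0)
    Xw = X if w is None else X * w[:, None]
    return np.linalg.solve(Xw.T @ X, Xw.T @ y)


def _additive_smoother(smoothers: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Solve the coupled backfitting system for the additive smoother.

    With centred per-component smoothers ``S_j`` the additive fit solves

        f_j = S_j (y - sum_{m != j} f_m),   j = 1..q,

    a linear system in the stacked components.  Applying its solution
    operator to the identity yields per-component operators ``F_j`` with
    ``f_j = F_j y``; their sum is the additive smoother ``S_A``.
    """
    q = len(smoothers)
    n = smoothers[0].shape[0]
    if q == 1:
        return smoothers[0].copy(), [smoothers[0].copy()]
    M = np.zeros((n * q, n * q))
    R = np.zeros((n * q, n))
    for j in range(q):
        R[j * n:(j + 1) * n, :] = smoothers[j]
        for m in range(q):
            M[j * n:(j + 1) * n, m * n:(m + 1) * n] = (
                np.eye(n) if m == j else smoothers[j]
            )
    try:
        F = np.linalg.solve(M, R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "the coupled backfitting system is singular (concurvity between "
            "nonparametric covariates)"
        ) from exc
    blocks = [F[j * n:(j + 1) * n, :] for j in range(q)]
    return sum(blocks), blocks


def estimate_variance(z: np.ndarray, H: np.ndarray) -> float:
    """Error-variance estimate ``z'(I-H)'(I-H)z / tr((I-H)'(I-H))``.

    ``z`` is the (centred) working response and the denominator is the
    residual degrees of freedom ``DF = n - 2 tr(H) + tr(H'H)``.
    """
    df = degrees_of_freedom(H)
    if df <= 0:
        raise ValueError(f"residual degrees of freedom must be positive, got {df}")
    r = z - H @ z
    return float(r @ r / df)


def beta_bias(
    fit: PLAMFit,
    f_true: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """Conditional bias of the coefficient estimate given true components.

    ``B = (X' W X~)^{-1} X' W f~``  with  ``f~ = sum_j (I - S_hj) f_j`` and
    ``X~ = (I - S_A) X``; ``W`` is the identity for the unweighted methods.
    Affine true components are reproduced by the local linear smoother, so
    their contribution to the bias vanishes (up to centring).
    """
    f_true = np.atleast_2d(np.asarray(f_true, dtype=float))
    if f_true.shape[0] == 1 and f_true.shape[1] == fit.components.shape[0]:
        f_true = f_true.T
    if f_true.shape != fit.components.shape:
        raise ValueError("f_true must be n x q, matching the fitted components")
    smoothers = fit.extras["component_smoothers"]
    S_A = fit.extras["S_A"]
    f_tilde = sum(
        f_true[:, j] - smoothers[j] @ f_true[:, j] for j in range(f_true.shape[1])
    )
    w = fit.weights
    Xt = X - S_A @ X
    XW = X if w is None else X * w[:, None]
    return np.linalg.solve(XW.T @ Xt, XW.T @ f_tilde)


def beta_variance(fit: PLAMFit, X: np.ndarray) -> np.ndarray:
    """Conditional covariance of the coefficient estimate.

    The sandwich ``sigma2 G^{-1} A A' G^{-T}`` with ``G = X' W X~`` and
    ``A = X' W (I - S_A)``; for ``S_A = 0, W = I`` this reduces to the OLS
    covariance ``sigma2 (X'X)^{-1}``.
    """
    S_A = fit.extras["S_A"]
    n = S_A.shape[0]
    w = fit.weights
    XW = X if w is None else X * w[:, None]
    Xt = X - S_A @ X
    G = XW.T @ Xt
    A = XW.T @ (np.eye(n) - S_A)
    Gi = np.linalg.inv(G)
    V = fit.sigma2 * Gi @ A @ A.T @ Gi.T
    asym = np.max(np.abs(V - V.T))
    if asym > 1e-8:
        raise ValueError(f"covariance asymmetry {asym:.2e} exceeds guard")
    return 0.5 * (V + V.T)


class PLAMRegressor(BaseEstimator, RegressorMixin):
    """Right-censored partially linear additive model via local linear
    backfitting.

    Parameters
    ----------
    n_parametric : int
        Number of leading columns of ``X`` forming the parametric part;
        the remaining columns are smoothed nonparametrically.
    method : {'st', 'kmw', 'knni'}
        Censorship solution: synthetic transformation, Kaplan–Meier
        weighting, or kNN imputation.
    solver : {'backfitting', 'direct'}
        Iterative modified backfitting, or the equivalent non-iterative
        solution through the additive smoother matrix (guarded to
        moderate n and q).
    kernel : str
        Kernel for the local linear smoother ('gaussian' or
        'epanechnikov').
    grid_min, grid_max, grid_len : float, float, int
        GCV bandwidth grid; the nominal endpoints apply per unit of
        covariate range and are rescaled by each covariate's range.
    bandwidths : sequence of float, optional
        Fixed per-component bandwidths, bypassing GCV selection.
    tol : float
        Convergence threshold on the mean absolute change of the
        component functions between sweeps.
    max_iter : int
        Backfitting sweep limit; non-convergence is flagged, not raised.
    reselect_bandwidths : bool
        Re-run GCV selection each sweep instead of freezing bandwidths
        after the initial selection pass.
    k : int, optional
        Neighbour count for kNN imputation; when None it is chosen from
        ``k_range`` by minimising the in-sample residual MSE of the fit.
    k_range : tuple (lo, hi)
        Inclusive search range for k.
    ridge : float
        Ridge added to near-singular local Gram matrices.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,)
    components_ : ndarray of shape (n, q)
        Fitted component functions at the training points, each mean-zero.
    bandwidths_ : ndarray of shape (q,)
    hat_matrix_ : ndarray of shape (n, n)
    sigma2_ : float
    df_ : float
    n_iter_ : int
    converged_ : bool
    k_ : int or None
    """

    def __init__(
        self,
        n_parametric: int = 0,
        method: str = "kmw",
        solver: str = "backfitting",
        kernel: str = "gaussian",
        grid_min: float = 0.01,
        grid_max: float = 1.5,
        grid_len: int = 30,
        bandwidths=None,
        tol: float = 0.05,
        max_iter: int = 100,
        reselect_bandwidths: bool = False,
        k: int | None = None,
        k_range: tuple = (2, 10),
        ridge: float = 1e-8,
    ):
        self.n_parametric = n_parametric
        self.method = method
        self.solver = solver
        self.kernel = kernel
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_len = grid_len
        self.bandwidths = bandwidths
        self.tol = tol
        self.max_iter = max_iter
        self.reselect_bandwidths = reselect_bandwidths
        self.k = k
        self.k_range = k_range
        self.ridge = ridge

    # ------------------------------------------------------------------
    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        p = int(self.n_parametric)
        if not 0 <= p <= X.shape[1]:
            raise ValueError("n_parametric out of range for the given design")
        return X[:, :p], X[:, p:]

    def fit(self, X, y, delta=None):
        """Fit the model.

        Parameters
        ----------
        X : array-like of shape (n, p + q)
            Covariates; the first ``n_parametric`` columns are parametric.
        y : array-like of shape (n,)
            Observed (possibly censored) response ``z = min(lifetime,
            censoring time)``.
        delta : array-like of shape (n,), optional
            Censoring indicator (1 = uncensored).  Defaults to all ones.
        """
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        Xp, T = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if delta is None:
            delta = np.ones(n, dtype=int)
        ds = CensoredDataset(z=y, delta=delta, X=Xp if Xp.shape[1] else np.zeros((n, 1)), T=T)
        # CensoredDataset insists on p >= 1 worth of storage; remember the
        # true parametric dimension separately
        self._p = Xp.shape[1]
        self._Xp = Xp
        self._T = T

        z_work, w, k_used = self._working_response(ds, Xp)
        fit = self._fit_core(z_work, w, Xp, T)
        fit.method = self.method
        fit.k = k_used

        self.fit_ = fit
        self.intercept_ = fit.beta0
        self.coef_ = fit.beta
        self.components_ = fit.components
        self.bandwidths_ = fit.bandwidths
        self.hat_matrix_ = fit.hat
        self.sigma2_ = fit.sigma2
        self.df_ = fit.df
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        self.fitted_values_ = fit.fitted_values
        self.k_ = k_used
        self.weights_ = w
        self.working_response_ = z_work
        return self

    # ------------------------------------------------------------------
    def _working_response(self, ds: CensoredDataset, Xp: np.ndarray):
        """Turn (z, delta) into a least-squares-ready response per method."""
        k_used = None
        w = None
        if self.method == "st":
            curve = fit_km_censoring(ds)
            z_work = synthetic_transform(ds, curve)
        elif self.method == "kmw":
            ds_sorted, order = ds.sort_by_z()
            w_sorted = kaplan_meier_weights(ds_sorted).w
            w = np.empty(ds.n)
            w[order] = w_sorted
            z_work = ds.z.copy()
        else:  # knni
            if ds.delta.all():
                z_work = ds.z.copy()
            elif self.k is not None:
                z_work = knn_impute(ds, self.k)
                k_used = self.k
            else:
                ref = select_reference_predictor(ds)
                lo, hi = self.k_range

                def _callback(z_imp):
                    return self._fit_core(
                        z_imp, None, Xp, ds.T, light=True
                    ).fitted_values

                k_used, z_work = select_k(
                    ds, _callback, k_range=range(lo, hi + 1), ref=ref
                )
        return z_work, w, k_used

    # ------------------------------------------------------------------
    def _fit_core(
        self,
        z_work: np.ndarray,
        w: np.ndarray | None,
        Xp: np.ndarray,
        T: np.ndarray,
        light: bool = False,
    ) -> PLAMFit:
        n = len(z_work)
        q = T.shape[1]
        p = Xp.shape[1]
        if w is not None and w.sum() <= 0:
            raise ValueError("Kaplan–Meier weights sum to zero")
        beta0 = (
            float(np.average(z_work, weights=w)) if w is not None else float(z_work.mean())
        )
        zc = z_work - beta0
        # the model assumes parametric covariates scaled around zero: centre
        # internally (weighted mean under KMW) and fold the shift back into
        # the reported intercept
        if p:
            xbar = (np.average(Xp, axis=0, weights=w) if w is not None
                    else Xp.mean(axis=0))
            Xp = Xp - xbar
        else:
            xbar = np.zeros(0)
        self._xbar = xbar

        if q == 0:
            beta = _weighted_lstsq(Xp, zc, w)
            mu = beta0 + Xp @ beta
            H = hat_matrix(np.zeros((n, n)), Xp, w) if p else np.zeros((n, n))
            sigma2 = estimate_variance(zc, H)
            fit = PLAMFit(
                beta0=beta0, beta=beta, components=np.zeros((n, 0)),
                bandwidths=np.zeros(0), hat=H, sigma2=sigma2,
                df=degrees_of_freedom(H), method=self.method, iterations=0,
                converged=True, fitted_values=mu, working_response=z_work,
                weights=w, extras={"S_A": np.zeros((n, n)),
                                   "component_smoothers": []},
            )
            fit.extras["response_center"] = beta0
            fit.extras["x_center"] = xbar
            if p:
                fit.beta0 = beta0 - float(xbar @ fit.beta)
            return fit

        smoothers, bandwidths = self._select_bandwidths(zc, Xp, T, w)

        if self.solver == "direct":
            fit = self._solve_direct(zc, beta0, z_work, w, Xp, T, smoothers, bandwidths)
        elif self.solver == "backfitting":
            fit = self._solve_backfitting(
                zc, beta0, z_work, w, Xp, T, smoothers, bandwidths, light=light
            )
        else:
            raise ValueError("solver must be 'backfitting' or 'direct'")
        # report the intercept on the raw covariate scale
        fit.extras["response_center"] = beta0
        fit.extras["x_center"] = xbar
        if p:
            fit.beta0 = beta0 - float(xbar @ fit.beta)
        return fit

    def _select_bandwidths(self, zc, Xp, T, w):
        n, q = T.shape
        Xh = Xp if Xp.shape[1] else None
        smoothers: list[SmootherMatrix] = []
        hs = np.empty(q)
        resid = zc.copy()
        fixed = None if self.bandwidths is None else np.asarray(self.bandwidths, float)
        for j in range(q):
            t = T[:, j]
            if fixed is not None:
                hs[j] = fixed[j]
            else:
                search = select_bandwidth(
                    t, resid, Xh, w,
                    kernel=self.kernel, ridge=self.ridge,
                    grid_min=self.grid_min, grid_max=self.grid_max,
                    grid_len=self.grid_len,
                )
                hs[j] = search.chosen
            Sc = center_smoother(
                llr_smoother(t, hs[j], kernel=self.kernel, ridge=self.ridge)
            )
            smoothers.append(Sc)
            if fixed is None and j < q - 1:
                # peel off a preliminary estimate of this component so the
                # next component's GCV sees a cleaner partial residual
                if Xh is not None:
                    XW = Xh if w is None else Xh * w[:, None]
                    Xt = Xh - Sc.S @ Xh
                    beta_pre = np.linalg.solve(XW.T @ Xt, XW.T @ (resid - Sc.S @ resid))
                    resid = resid - Sc.S @ (resid - Xh @ beta_pre)
                else:
                    resid = resid - Sc.S @ resid
        return smoothers, hs

    def _solve_backfitting(self, zc, beta0, z_work, w, Xp, T, smoothers, hs,
                           light=False):
        n, q = T.shape
        p = Xp.shape[1]
        S = [sm.S for sm in smoothers]
        f = np.zeros((n, q))
        beta = _weighted_lstsq(Xp, zc, w) if p else np.zeros(0)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            change = 0.0
            if self.reselect_bandwidths and it > 1:
                resid_all = zc - (Xp @ beta if p else 0.0) - f.sum(axis=1)
                for j in range(q):
                    search = select_bandwidth(
                        T[:, j], resid_all + f[:, j], Xp if p else None, w,
                        kernel=self.kernel, ridge=self.ridge,
                        grid_min=self.grid_min, grid_max=self.grid_max,
                        grid_len=self.grid_len,
                    )
                    hs[j] = search.chosen
                    smoothers[j] = center_smoother(
                        llr_smoother(T[:, j], hs[j], kernel=self.kernel,
                                     ridge=self.ridge)
                    )
                    S[j] = smoothers[j].S
            for j in range(q):
                others = f.sum(axis=1) - f[:, j]
                if p:
                    beta = _weighted_lstsq(Xp, zc - others - f[:, j], w)
                partial = zc - (Xp @ beta if p else 0.0) - others
                f_new = S[j] @ partial
                change += float(np.abs(f_new - f[:, j]).sum())
                f[:, j] = f_new
            if change / (n * q) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"backfitting did not converge in {self.max_iter} sweeps",
                RuntimeWarning,
                stacklevel=2,
            )
        if p:
            beta = _weighted_lstsq(Xp, zc - f.sum(axis=1), w)
        mu = beta0 + (Xp @ beta if p else 0.0) + f.sum(axis=1)
        logger.info("backfitting method=%s iterations=%d converged=%s",
                    self.method, it, converged)

        if light:
            # skip the O((nq)^3) diagnostics during k-selection callbacks
            return PLAMFit(
                beta0=beta0, beta=beta, components=f, bandwidths=hs,
                hat=np.empty((0, 0)), sigma2=np.nan, df=np.nan,
                method=self.method, iterations=it, converged=converged,
                fitted_values=mu, working_response=z_work, weights=w,
                extras={},
            )

        S_A, blocks = _additive_smoother(S)
        H = hat_matrix(S_A, Xp if p else None, w)
        sigma2 = estimate_variance(zc, H)
        extras = {
            "S_A": S_A,
            "component_smoothers": S,
            "component_operators": blocks,
            "partial_residuals": [
                zc - (Xp @ beta if p else 0.0) - (f.sum(axis=1) - f[:, j])
                for j in range(q)
            ],
        }
        return PLAMFit(
            beta0=beta0, beta=beta, components=f, bandwidths=hs, hat=H,
            sigma2=sigma2, df=degrees_of_freedom(H), method=self.method,
            iterations=it, converged=converged, fitted_values=mu,
            working_response=z_work, weights=w, extras=extras,
        )

    def _solve_direct(self, zc, beta0, z_work, w, Xp, T, smoothers, hs):
        n, q = T.shape
        p = Xp.shape[1]
        if n > DIRECT_MAX_N or q > DIRECT_MAX_Q:
            raise ValueError(
                f"direct solver materializes an (nq x nq) system; guarded to "
                f"n <= {DIRECT_MAX_N}, q <= {DIRECT_MAX_Q}"
            )
        S = [sm.S for sm in smoothers]
        S_A, blocks = _additive_smoother(S)
        if p:
            XW = Xp if w is None else Xp * w[:, None]
            Xt = Xp - S_A @ Xp
            zt = zc - S_A @ zc
            beta = np.linalg.solve(XW.T @ Xt, XW.T @ zt)
            r = zc - Xp @ beta
        else:
            beta = np.zeros(0)
            r = zc
        f = np.column_stack([Fj @ r for Fj in blocks])
        mu = beta0 + (Xp @ beta if p else 0.0) + f.sum(axis=1)
        H = hat_matrix(S_A, Xp if p else None, w)
        sigma2 = estimate_variance(zc, H)
        extras = {
            "S_A": S_A,
            "component_smoothers": S,
            "component_operators": blocks,
            "partial_residuals": [r - (f.sum(axis=1) - f[:, j]) for j in range(q)],
        }
        return PLAMFit(
            beta0=beta0, beta=beta, components=f, bandwidths=hs, hat=H,
            sigma2=sigma2, df=degrees_of_freedom(H), method=self.method,
            iterations=0, converged=True, fitted_values=mu,
            working_response=z_work, weights=w, extras=extras,
        )

    # ------------------------------------------------------------------
    def predict(self, X):
        """Predict ``beta0 + x' beta + sum_j f_j(t_j)`` at new covariates.

        Training rows reproduce the fitted values.  New nonparametric
        covariate values are evaluated through a fresh local linear weight
        row at the stored bandwidth; values outside the observed range
        trigger an extrapolation warning.
        """
        check_is_fitted(self, "fit_")
        Xp, T = self._split(X)
        fit = self.fit_
        out = np.full(Xp.shape[0], fit.beta0)
        if self._p:
            out = out + Xp @ fit.beta
        for j in range(T.shape[1]):
            out = out + self._predict_component(j, T[:, j])
        return out

    def _predict_component(self, j: int, t_new: np.ndarray) -> np.ndarray:
        fit = self.fit_
        t_train = self._T[:, j]
        if np.any(t_new < t_train.min()) or np.any(t_new > t_train.max()):
            warnings.warn(
                f"component {j}: prediction points outside the observed "
                f"covariate range (extrapolation)",
                RuntimeWarning,
                stacklevel=2,
            )
        partial = fit.extras["partial_residuals"][j]
        S_rows = llr_smoother(
            t_train, fit.bandwidths[j], kernel=self.kernel, ridge=self.ridge,
            eval_points=t_new,
        ).S
        # the training-time component is the centred smooth of the same
        # partial residual: subtract the identical centring constant
        S_train = llr_smoother(
            t_train, fit.bandwidths[j], kernel=self.kernel, ridge=self.ridge
        ).S
        c = float((S_train @ partial).mean())
        return S_rows @ partial - c


# ----------------------------------------------------------------------
# thin functional wrappers


def _regressor_from(data: CensoredDataset, method: str, solver: str, **config) -> PLAMRegressor:
    est = PLAMRegressor(n_parametric=data.p, method=method, solver=solver, **config)
    X = np.hstack([data.X, data.T])
    est.fit(X, data.z, data.delta)
    return est


def backfit(data: CensoredDataset, method: str = "kmw", **config) -> PLAMFit:
    """Fit by modified backfitting; see :class:`PLAMRegressor`."""
    return _regressor_from(data, method, "backfitting", **config).fit_


def fit_noniterative(data: CensoredDataset, method: str = "kmw", **config) -> PLAMFit:
    """Fit by the non-iterative additive-smoother solution (small n)."""
    return _regressor_from(data, method, "direct", **config).fit_
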