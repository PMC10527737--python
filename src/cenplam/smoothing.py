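"""Local linear smoother matrices, hat matrices and GCV bandwidth selection.

The local linear regression (LLR) smoother at evaluation point ``m`` fits a
kernel-weighted straight line to ``(t_i, y_i)`` and reports its value at
``m``.  Collecting the weight vectors for every observed ``t_m`` gives the
n-by-n smoother matrix ``S``; each row sums to 1 and the smoother
reproduces affine functions of the covariate exactly.  For use inside an
additive model the smoother is mean-centred, ``S_c = (I - 11'/n) S``, so
that fitted component functions average to zero.

For the partially linear model with design ``X`` the hat matrix combining
one smoother with the parametric projection is

    H = S + Xt (Xt' W Xt)^{-1} X' W (I - S),    Xt = (I - S) X

with ``W`` the Kaplan–Meier weight diagonal for the weighted solution and
the identity otherwise.  The generalized cross-validation score used to
choose the bandwidth is ``GCV(h) = RSS / (n (1 - tr(H)/n)^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KERNELS",
    "SmootherMatrix",
    "BandwidthSearch",
    "kernel_weights",
    "kernel_weight_matrix",
    "llr_smoother",
    "center_smoother",
    "hat_matrix",
    "degrees_of_freedom",
    "gcv_score",
    "bandwidth_grid",
    "select_bandwidth",
]


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


KERNELS = {"gaussian": _gaussian, "epanechnikov": _epanechnikov}


@dataclass
class SmootherMatrix:
    """Local linear smoother with its bandwidth and centering state."""

    S: np.ndarray
    h: float
    t: np.ndarray
    kernel: str = "gaussian"
    centered: bool = False

    def dot(self, v: np.ndarray) -> np.ndarray:
        return self.S @ v


@dataclass
class BandwidthSearch:
    """Grid search record: candidates, GCV scores and the argmin."""

    grid: np.ndarray
    scores: np.ndarray
    chosen: float = field(default=np.nan)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.scores)
        if not finite.any():
            raise ValueError(
                "every bandwidth candidate was rejected (tr(H) >= n); "
                "extend the search grid"
            )
        # ties go to the smaller bandwidth: argmin returns the first minimum
        # of an ascending grid
        self.chosen = float(self.grid[int(np.argmin(np.where(finite, self.scores, np.inf)))])


def kernel_weights(t: np.ndarray, m: float, h: float, kernel: str = "gaussian") -> np.ndarray:
    """Diagonal of the kernel weight matrix ``h^{-1} K((t_i - m)/h)``."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    w = KERNELS[kernel]((np.asarray(t, dtype=float) - m) / h) / h
    if not w.any():
        raise ValueError(
            f"all kernel weights underflowed to zero at evaluation point m={m} "
            f"(bandwidth h={h} is far too small)"
        )
    return w


def kernel_weight_matrix(t: np.ndarray, m: float, h: float, kernel: str = "gaussian") -> np.ndarray:
    """Kernel weight diagonal as an n-by-n matrix."""
    return np.diag(kernel_weights(t, m, h, kernel))


def llr_smoother(
    t: np.ndarray,
    h: float,
    kernel: str = "gaussian",
    ridge: float = 1e-8,
    eval_points: np.ndarray | None = None,
) -> SmootherMatrix:
    """Local linear smoother matrix evaluated at the observed points.

    Row ``m`` is ``d1' (T_m' W_m T_m)^{-1} T_m' W_m`` with
    ``T_m = [1, t - m]`` and ``d1 = (1, 0)'``; in closed form

        S_{m,i} = w_i (s2 - (t_i - m) s1) / (s0 s2 - s1^2),
        s_k = sum_i w_i (t_i - m)^k.

    A tiny ridge is added when the local Gram determinant degenerates
    (all kernel mass on one point).
    """
    t = np.asarray(t, dtype=float).ravel()
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct covariate values")
    m = t if eval_points is None else np.asarray(eval_points, dtype=float).ravel()
    # D[a, i] = t_i - m_a
    D = t[None, :] - m[:, None]
    Kw = KERNELS[kernel](D / h) / h
    if not Kw.any(axis=1).all():
        raise ValueError("a smoother row has all-zero kernel weights; increase h")
    s0 = Kw.sum(axis=1)
    s1 = (Kw * D).sum(axis=1)
    s2 = (Kw * D * D).sum(axis=1)
    det = s0 * s2 - s1 * s1
    bad = det <= ridge * np.maximum(s0 * s2, 1e-300)
    if bad.any():
        warnings.warn(
            "near-singular local Gram matrix; adding ridge to the 2x2 system",
            RuntimeWarning,
            stacklevel=2,
        )
        # ridge on the curvature term only: row sums stay exactly 1
        s2 = s2 + ridge
        det = s0 * s2 - s1 * s1
    S = Kw * (s2[:, None] - D * s1[:, None]) / det[:, None]
    return SmootherMatrix(S=S, h=float(h), t=t, kernel=kernel, centered=False)


def center_smoother(S: SmootherMatrix) -> SmootherMatrix:
    """Mean-centre: ``S_c = (I - 11'/n) S`` so fitted components sum to 0."""
    if S.centered:
        return S
    Sc = S.S - S.S.mean(axis=0, keepdims=True)
    return SmootherMatrix(S=Sc, h=S.h, t=S.t, kernel=S.kernel, centered=True)


def hat_matrix(S: np.ndarray | SmootherMatrix, X: np.ndarray | None, w: np.ndarray | None = None) -> np.ndarray:
    """Semiparametric hat matrix ``H = S + Xt (Xt'WXt)^{-1} X'W (I - S)``.

    ``w`` is the weight diagonal (vector) or None for the identity.  With no
    parametric design (``X`` is None or has zero columns) the hat matrix is
    the smoother itself.
    """
    Smat = S.S if isinstance(S, SmootherMatrix) else np.asarray(S, dtype=float)
    n = Smat.shape[0]
    if X is None or X.size == 0 or X.shape[1] == 0:
        return Smat.copy()
    X = np.asarray(X, dtype=float)
    ImS = np.eye(n) - Smat
    Xt = ImS @ X
    XW = X if w is None else X * w[:, None]
    # G = X' W X~ makes H Z reproduce the fitted values of the coefficient
    # estimator beta = (X'WX~)^{-1} X'W Z~, i.e. the backfitting fixed point
    G = XW.T @ Xt
    try:
        M = np.linalg.solve(G, (XW.T @ ImS))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular parametric cross-product X~'WX~; check for collinear "
            "or unscaled covariates"
        ) from exc
    return Smat + Xt @ M


def degrees_of_freedom(H: np.ndarray) -> float:
    """Residual degrees of freedom ``n - 2 tr(H) + tr(H'H)``."""
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    return float(n - 2.0 * np.trace(H) + np.sum(H * H))


def gcv_score(z: np.ndarray, mu_hat: np.ndarray, H: np.ndarray | float) -> float:
    """Generalized cross-validation: ``RSS / (n (1 - tr(H)/n)^2)``.

    ``H`` may be the hat matrix or its precomputed trace.  Candidates with
    ``tr(H) >= n`` receive an infinite score rather than raising.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    tr = float(H) if np.isscalar(H) else float(np.trace(H))
    denom = 1.0 - tr / n
    if denom <= 0:
        return np.inf
    rss = float(np.sum((z - mu_hat) ** 2))
    return rss / (n * denom * denom)


def bandwidth_grid(t: np.ndarray, grid_min: float = 0.01, grid_max: float = 1.5,
                   grid_len: int = 30, scale_by_range: bool = False) -> np.ndarray:
    """Equally spaced candidate bandwidths on ``[grid_min, grid_max]``.

    The default endpoints are in covariate units, suitable for covariates
    spanning a few units (as in this model class, where nonparametric
    covariates are scaled).  With ``scale_by_range=True`` the grid is
    multiplied by the sample range of ``t``, so the nominal endpoints apply
    per unit of range — useful for unscaled covariates.
    """
    r = float(np.ptp(np.asarray(t, dtype=float)))
    if r <= 0:
        raise ValueError("covariate has zero range")
    grid = np.linspace(grid_min, grid_max, grid_len)
    return grid * r if scale_by_range else grid


def select_bandwidth(
    t: np.ndarray,
    residual: np.ndarray,
    X: np.ndarray | None,
    w: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    kernel: str = "gaussian",
    ridge: float = 1e-8,
    grid_min: float = 0.01,
    grid_max: float = 1.5,
    grid_len: int = 30,
) -> BandwidthSearch:
    """GCV grid search for one component's bandwidth.

    For each candidate ``h`` the centred smoother is built on ``t``, the
    method-appropriate hat matrix formed with the parametric design ``X``
    (and weights ``w`` for the KMW solution), and the GCV score of the fit
    to the current partial ``residual`` evaluated.  Returns the search
    record; ties resolve to the smaller bandwidth.
    """
    if grid is None:
        grid = bandwidth_grid(t, grid_min, grid_max, grid_len)
    scores = np.full(len(grid), np.inf)
    for idx, h in enumerate(grid):
        try:
            S = center_smoother(llr_smoother(t, h, kernel=kernel, ridge=ridge))
            H = hat_matrix(S, X, w)
        except (ValueError, np.linalg.LinAlgError):
            continue
        scores[idx] = gcv_score(residual, H @ residual, H)
    return BandwidthSearch(grid=np.asarray(grid, dtype=float), scores=scores)
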