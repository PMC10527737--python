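"""Censorship solutions for right-censored responses.

A right-censored sample records ``z = min(y, c)`` together with the
indicator ``delta`` (1 when the lifetime ``y`` itself was observed, 0 when
only the censoring time ``c`` was).  Ordinary least-squares machinery
cannot be applied to ``z`` directly; this module implements the three
standard repairs used throughout the package:

* **synthetic transformation (ST)** — inverse-probability-of-censoring
  rescaling ``z_i^G = delta_i * z_i / (1 - Ghat(z_i))``, which is
  conditionally unbiased for ``E[y | x, t]``;
* **Kaplan–Meier weights (KMW)** — per-observation weights equal to the
  jumps of the product-limit estimate of the lifetime distribution, used
  downstream in weighted least squares;
* **kNN imputation (kNNI)** — each censored response is replaced by the
  mean of the ``k`` nearest uncensored responses, nearness measured on the
  parametric covariate most correlated with the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CensoredDataset",
    "KaplanMeierCurve",
    "WeightSet",
    "fit_km_censoring",
    "fit_km_lifetime",
    "synthetic_transform",
    "kaplan_meier_weights",
    "select_reference_predictor",
    "knn_impute",
    "select_k",
]

#: floor applied to 1 - Ghat(z) before division in the synthetic transform
SURVIVAL_FLOOR = 1e-10


@dataclass
class CensoredDataset:
    """Right-censored regression sample.

    Parameters
    ----------
    z : ndarray of shape (n,)
        Observed response, ``min(y, c)``.
    delta : ndarray of shape (n,)
        Censoring indicator; 1 = uncensored, 0 = censored.
    X : ndarray of shape (n, p)
        Parametric covariates.
    T : ndarray of shape (n, q)
        Nonparametric covariates.
    is_sorted : bool
        Whether rows are ordered by ascending ``z`` (uncensored first at
        ties) — required by the order-dependent Kaplan–Meier weights.
    """

    z: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    T: np.ndarray
    is_sorted: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.delta = np.asarray(self.delta).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        if self.X.shape[0] == 1 and self.n > 1:
            self.X = self.X.T
        if self.T.shape[0] == 1 and self.n > 1:
            self.T = self.T.T
        n = self.n
        if n < 3:
            raise ValueError(f"need at least 3 observations, got {n}")
        if not (len(self.delta) == n and self.X.shape[0] == n and self.T.shape[0] == n):
            raise ValueError("z, delta, X, T must have the same number of rows")
        if not np.isin(self.delta, (0, 1)).all():
            raise ValueError("delta must contain only 0 and 1")
        self.delta = self.delta.astype(int)
        if self.delta.sum() == 0:
            raise ValueError("at least one uncensored observation is required")
        for name, arr in (("z", self.z), ("X", self.X), ("T", self.T)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.z)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.T.shape[1]

    def sort_by_z(self) -> tuple["CensoredDataset", np.ndarray]:
        """Return a copy sorted by ascending z and the sorting index.

        Ties between censored and uncensored observations are broken with
        the uncensored observation first (the standard product-limit
        convention).
        """
        order = np.lexsort((-self.delta, self.z))
        ds = CensoredDataset(
            z=self.z[order],
            delta=self.delta[order],
            X=self.X[order],
            T=self.T[order],
            is_sorted=True,
        )
        return ds, order


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit step function.

    ``surv`` holds the survival value on ``[times[i], times[i+1])``; before
    the first jump the survival probability is 1.  ``kind`` records whether
    the curve estimates the censoring distribution ``G`` or the lifetime
    distribution ``F``.
    """

    times: np.ndarray
    surv: np.ndarray
    kind: str = "censoring"
    degenerate: bool = field(default=False)

    def __call__(self, u: np.ndarray | float) -> np.ndarray | float:
        """Evaluate 1 - Ghat(u) (resp. 1 - Fhat(u)) right-continuously."""
        u = np.asarray(u, dtype=float)
        if len(self.times) == 0:  # no events of this kind: flat at 1
            out = np.ones_like(u)
        else:
            idx = np.searchsorted(self.times, u, side="right") - 1
            out = np.where(
                idx < 0, 1.0, self.surv[np.clip(idx, 0, len(self.surv) - 1)]
            )
        return float(out) if out.ndim == 0 else out


def _km_survival(data, event_value: int) -> KaplanMeierCurve:
    # product over sorted ranks i with the chosen event type:
    # surv(u) = prod_{i: z_(i) <= u, event} (n - i) / (n - i + 1)
    if isinstance(data, CensoredDataset):
        ds = data if data.is_sorted else data.sort_by_z()[0]
        z, delta = ds.z, ds.delta
    else:
        # bare (z, delta) pair: needed for degenerate all-censored samples
        # that CensoredDataset itself rejects
        z = np.asarray(data[0], dtype=float).ravel()
        delta = np.asarray(data[1]).astype(int).ravel()
        order = np.lexsort((-delta, z))
        z, delta = z[order], delta[order]
    n = len(z)
    factors = np.where(
        delta == event_value,
        (n - np.arange(1, n + 1)) / (n - np.arange(1, n + 1) + 1.0),
        1.0,
    )
    surv_at_rank = np.cumprod(factors)
    is_event = delta == event_value
    times = z[is_event]
    surv = surv_at_rank[is_event]
    # collapse tied event times to their last (smallest) survival value
    keep = np.ones(len(times), dtype=bool)
    keep[:-1] = np.diff(times) > 0
    kind = "censoring" if event_value == 0 else "lifetime"
    curve = KaplanMeierCurve(times=times[keep], surv=surv[keep], kind=kind)
    if len(curve.surv) and curve.surv[-1] <= 0.0:
        curve.degenerate = True
    return curve


def fit_km_censoring(data) -> KaplanMeierCurve:
    """Product-limit estimate ``1 - Ghat`` of the censoring survival.

    ``data`` is a :class:`CensoredDataset` or a bare ``(z, delta)`` pair.
    Jumps occur only at censored observations; with no censoring the curve
    is identically 1.  The curve is flagged degenerate when it reaches 0
    (a censored observation at the sample maximum), in which case the
    synthetic transform is unusable at any later uncensored point.
    """
    return _km_survival(data, event_value=0)


def fit_km_lifetime(data) -> KaplanMeierCurve:
    """Product-limit estimate ``1 - Fhat`` of the lifetime survival."""
    return _km_survival(data, event_value=1)


def synthetic_transform(
    data: CensoredDataset, curve: KaplanMeierCurve | None = None
) -> np.ndarray:
    """Synthetic (inverse-probability-of-censoring weighted) response.

    ``z_i^G = delta_i * z_i / (1 - Ghat(z_i))``.  Censored points map to
    exactly 0; under no censoring the transform is the identity.  Because
    ``Ghat`` jumps only at censored points, evaluating it right-continuously
    at an uncensored ``z_i`` is unambiguous.
    """
    if curve is None:
        curve = fit_km_censoring(data)
    if curve.kind != "censoring":
        raise ValueError("synthetic_transform requires the censoring-distribution curve")
    surv = np.asarray(curve(data.z), dtype=float)
    if np.any(surv[data.delta == 1] < SURVIVAL_FLOOR):
        warnings.warn(
            "1 - Ghat(z) underflows at one or more uncensored points; "
            "clipping at the floor — tail observations may be unusable",
            RuntimeWarning,
            stacklevel=2,
        )
    surv = np.maximum(surv, SURVIVAL_FLOOR)
    return data.delta * data.z / surv


@dataclass
class WeightSet:
    """Kaplan–Meier weights aligned to z-sorted rows."""

    w: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return np.diag(self.w)


def kaplan_meier_weights(data: CensoredDataset) -> WeightSet:
    """Jumps of the product-limit lifetime distribution as regression weights.

    For z-sorted rows,

    ``w_i = delta_i / (n - i + 1) * prod_{r<i} ((n - r) / (n - r + 1))^delta_r``

    which equals the jump of ``Fhat`` at ``z_(i)``.  Censored rows receive
    weight 0; with no censoring every weight is ``1/n``.  The weights sum to
    at most 1, with equality when the largest observation is uncensored.
    """
    if not data.is_sorted:
        raise ValueError(
            "Kaplan–Meier weights are order-dependent: sort the dataset by z "
            "first (CensoredDataset.sort_by_z)"
        )
    n = data.n
    i = np.arange(1, n + 1)
    ratio = (n - i) / (n - i + 1.0)
    factors = np.where(data.delta == 1, ratio, 1.0)
    # product of ((n-r)/(n-r+1))^delta_r over r < i
    prod_before = np.concatenate(([1.0], np.cumprod(factors)[:-1]))
    w = data.delta / (n - i + 1.0) * prod_before
    return WeightSet(w=w)


def select_reference_predictor(data: CensoredDataset) -> int:
    """Column of ``X`` most correlated (absolute Pearson) with z.

    Correlations are computed over uncensored rows only, since censored
    ``z`` values understate the lifetime.  Zero-variance columns are
    skipped; if all columns are degenerate an error is raised.
    """
    mask = data.delta == 1
    z = data.z[mask]
    best, best_abs = None, -1.0
    for j in range(data.p):
        x = data.X[mask, j]
        if np.ptp(x) == 0 or np.ptp(z) == 0:
            continue
        r = abs(np.corrcoef(x, z)[0, 1])
        if np.isfinite(r) and r > best_abs:
            best, best_abs = j, r
    if best is None:
        raise ValueError("no parametric column with nonzero variance on uncensored rows")
    return best


def knn_impute(data: CensoredDataset, k: int, ref: int | None = None) -> np.ndarray:
    """Replace each censored response by the mean of its k nearest
    uncensored responses.

    Distances are Euclidean on the single reference covariate column (the
    one most correlated with z unless ``ref`` is given).  Neighbour ties at
    equal distance are broken by row index, and the candidate pool is every
    uncensored row.  Uncensored rows pass through unchanged.
    """
    n_unc = int(data.delta.sum())
    if not 2 <= k <= n_unc:
        raise ValueError(f"k={k} must lie in [2, number of uncensored rows={n_unc}]")
    if ref is None:
        ref = select_reference_predictor(data)
    x = data.X[:, ref]
    z_out = data.z.copy()
    unc_idx = np.flatnonzero(data.delta == 1)
    for i in np.flatnonzero(data.delta == 0):
        d = np.abs(x[unc_idx] - x[i])
        order = np.argsort(d, kind="stable")
        z_out[i] = data.z[unc_idx[order[:k]]].mean()
    return z_out


def select_k(
    data: CensoredDataset,
    fit_callback,
    k_range=range(2, 11),
    ref: int | None = None,
):
    """Choose the neighbour count minimising in-sample residual MSE.

    ``fit_callback(z_imputed) -> fitted values`` must run the full model fit
    on the imputed response.  The MSE is computed against the imputed
    response itself (the true lifetimes of censored rows are unobservable).
    Ties are resolved toward the smaller k.

    Returns ``(k, imputed_response)``.
    """
    n_unc = int(data.delta.sum())
    feasible = [k for k in k_range if 2 <= k <= n_unc]
    if not feasible:
        raise ValueError("no feasible k in the requested range")
    if ref is None:
        ref = select_reference_predictor(data)
    best = None
    for k in feasible:
        z_imp = knn_impute(data, k, ref=ref)
        mu = fit_callback(z_imp)
        mse = float(np.mean((z_imp - mu) ** 2))
        if best is None or mse < best[0] - 1e-15:
            best = (mse, k, z_imp)
    return best[1], best[2]
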