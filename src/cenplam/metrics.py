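"""Monte-Carlo performance measures for PLAM estimators.

Parametric component: the scalar mean dispersion error (SMDE) is the
Monte-Carlo mean of the squared Euclidean error of the coefficient vector,
equal to the trace of the empirical MSE matrix (variance plus squared
bias).  Relative efficiency (RE) is a ratio of two SMDEs; RE < 1 means the
numerator's estimator is more efficient.

Nonparametric component: per-function RMSE compares the mean-centred true
component with its (mean-zero) estimate at the observed design points, and
ARMSE averages the per-function RMSEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "smde", "mse_matrix", "relative_efficiency",
           "rmse_function", "armse", "re_table"]


def mse_matrix(beta_hats: np.ndarray, beta_true: np.ndarray) -> np.ndarray:
    """Empirical MSE matrix ``E[(b - bhat)(b - bhat)'] = Var + bias bias'``."""
    beta_hats = np.atleast_2d(np.asarray(beta_hats, dtype=float))
    d = beta_hats - np.asarray(beta_true, dtype=float)[None, :]
    return d.T @ d / len(d)


def smde(beta_hats: np.ndarray, beta_true: np.ndarray) -> float:
    """Scalar mean dispersion error: mean of ``||bhat - b||^2`` over
    replicates, i.e. ``tr(MSE(bhat, b))``."""
    beta_hats = np.atleast_2d(np.asarray(beta_hats, dtype=float))
    d = beta_hats - np.asarray(beta_true, dtype=float)[None, :]
    return float(np.mean(np.sum(d * d, axis=1)))


def relative_efficiency(smde_num: float, smde_den: float) -> float:
    """``RE = SMDE_1 / SMDE_2``; values below 1 favour the numerator."""
    if smde_den <= 0:
        raise ValueError("denominator SMDE must be positive")
    return smde_num / smde_den


def rmse_function(f_true: np.ndarray, f_hat: np.ndarray) -> float:
    """Root mean squared error between a true component and its estimate.

    Both vectors are mean-centred before comparison: additive components
    are identifiable only up to a constant absorbed by the intercept.
    """
    f_true = np.asarray(f_true, dtype=float).ravel()
    f_hat = np.asarray(f_hat, dtype=float).ravel()
    if len(f_true) != len(f_hat):
        raise ValueError("true and estimated component lengths differ")
    d = (f_true - f_true.mean()) - (f_hat - f_hat.mean())
    return float(np.sqrt(np.mean(d * d)))


def armse(rmses) -> float:
    """Average of the per-function RMSEs across the q components."""
    rmses = np.asarray(rmses, dtype=float)
    if rmses.size == 0:
        raise ValueError("need at least one component RMSE")
    return float(rmses.mean())


def re_table(smdes: dict[str, float]) -> pd.DataFrame:
    """Pairwise relative efficiencies.

    Entry (row=A, col=B) is ``SMDE(B) / SMDE(A)``: the column method sits
    in the numerator, so entries below 1 mark columns beating their row.
    """
    methods = list(smdes)
    data = [
        [relative_efficiency(smdes[col], smdes[row]) for col in methods]
        for row in methods
    ]
    return pd.DataFrame(data, index=methods, columns=methods)


@dataclass
class MetricReport:
    """Aggregate metrics for one scenario."""

    smde: dict[str, float] = field(default_factory=dict)
    re: pd.DataFrame | None = None
    rmse: dict[str, np.ndarray] = field(default_factory=dict)  # method -> q values
    armse: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for v in self.smde.values():
            assert v >= 0
        if self.re is not None:
            assert np.allclose(np.diag(self.re.to_numpy()), 1.0)
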