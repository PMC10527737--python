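"""CSV readers/writers and run configuration.

Interchange format: delimited text with named columns ``z, delta,
x1..xp, t1..tq``.  ``delta`` must be strictly 0/1 and no covariate cell may
be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .censoring import CensoredDataset
from .estimator import PLAMFit

__all__ = ["ColumnMapping", "read_dataset", "write_dataset", "write_fit",
           "read_fit", "load_config"]


@dataclass
class ColumnMapping:
    z: str = "z"
    delta: str = "delta"
    parametric: list[str] = field(default_factory=list)
    nonparametric: list[str] = field(default_factory=list)

    def validate(self, columns) -> None:
        roles = [self.z, self.delta, *self.parametric, *self.nonparametric]
        missing = [c for c in roles if c not in columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(set(roles)) != len(roles):
            raise ValueError("column roles overlap")


def _infer_mapping(columns) -> ColumnMapping:
    xs = sorted((c for c in columns if c.startswith("x") and c[1:].isdigit()),
                key=lambda c: int(c[1:]))
    ts = sorted((c for c in columns if c.startswith("t") and c[1:].isdigit()),
                key=lambda c: int(c[1:]))
    return ColumnMapping(parametric=xs, nonparametric=ts)


def read_dataset(path, mapping: ColumnMapping | None = None) -> CensoredDataset:
    """Read a censored dataset from CSV, validating types and completeness."""
    df = pd.read_csv(path, float_precision="round_trip")
    if mapping is None:
        mapping = _infer_mapping(df.columns)
    mapping.validate(df.columns)
    cols = [mapping.z, mapping.delta, *mapping.parametric, *mapping.nonparametric]
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based + header line
        raise ValueError(f"missing or non-numeric cells at file rows {rows[:10]}")
    delta = sub[mapping.delta].to_numpy()
    offenders = np.flatnonzero(~np.isin(delta, (0, 1)))
    if offenders.size:
        raise ValueError(
            f"delta must be strictly 0/1; first offending file row "
            f"{offenders[0] + 2}"
        )
    n = len(sub)
    X = sub[mapping.parametric].to_numpy() if mapping.parametric else np.zeros((n, 1))
    T = sub[mapping.nonparametric].to_numpy() if mapping.nonparametric else np.zeros((n, 0))
    return CensoredDataset(z=sub[mapping.z].to_numpy(), delta=delta.astype(int),
                           X=X, T=T)


def write_dataset(data: CensoredDataset, path) -> None:
    cols = {"z": data.z, "delta": data.delta}
    for j in range(data.p):
        cols[f"x{j + 1}"] = data.X[:, j]
    for j in range(data.q):
        cols[f"t{j + 1}"] = data.T[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_fit(fit: PLAMFit, path) -> None:
    """Persist a fit: scalar diagnostics block, coefficients, per-row
    component values.  Full float precision so the round trip is exact."""
    path = Path(path)
    n, q = fit.components.shape
    per_row = pd.DataFrame(
        {f"f{j + 1}": fit.components[:, j] for j in range(q)}
        | {"fitted": fit.fitted_values, "working_response": fit.working_response}
    )
    scalars = {
        "method": fit.method,
        "beta0": fit.beta0,
        **{f"beta{i + 1}": b for i, b in enumerate(fit.beta)},
        **{f"h{j + 1}": h for j, h in enumerate(fit.bandwidths)},
        "sigma2": fit.sigma2,
        "df": fit.df,
        "iterations": fit.iterations,
        "converged": int(fit.converged),
    }
    if fit.k is not None:
        scalars["k"] = fit.k
    with open(path, "w") as fh:
        for key, val in scalars.items():
            v = f"{val:.17g}" if isinstance(val, float) else val
            fh.write(f"# {key}={v}\n")
        per_row.to_csv(fh, index=False, float_format="%.17g")


def read_fit(path) -> tuple[dict, pd.DataFrame]:
    """Read back a fit written by :func:`write_fit`."""
    scalars: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, _, val = line[2:].strip().partition("=")
            try:
                scalars[key] = int(val) if key in ("iterations", "converged", "k") else float(val)
            except ValueError:
                scalars[key] = val
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])),
                        float_precision="round_trip")
    return scalars, table


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
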