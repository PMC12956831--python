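"""Trial-level regressions against goal distance and group-level inference.

Every outcome (band power, residualized PAC, asymmetry index, aperiodic
exponent, evoked amplitude) is regressed per participant on distance to the
goal -- a continuous integer regressor -- with trial number as a nuisance
regressor against slow drift.  Per-participant distance coefficients are then
submitted to a two-sided one-sample t test (or a paired t test when comparing
condition slices), with Cohen's d as mean/SD (one-sample) or
mean(diff)/SD(diff) (paired).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RegressionResult",
    "GroupStats",
    "epoch_regression",
    "group_test",
    "distance_profile",
]


@dataclass
class RegressionResult:
    """OLS fit of one outcome for one participant (or one summary table)."""

    outcome: str
    params: pd.Series  # intercept, distance, then nuisance terms
    se: pd.Series
    n: int
    distance_col: str
    slice_name: str | None = None

    @property
    def beta_distance(self) -> float:
        return float(self.params["distance"])


@dataclass
class GroupStats:
    """Two-sided t test across participants on regression coefficients."""

    test: str  # "one_sample" | "paired"
    t: float
    df: int
    p: float
    cohens_d: float
    n: int
    mean: float


def epoch_regression(
    table: pd.DataFrame,
    outcome: str,
    distance_col: str = "goal_distance",
    nuisance: tuple[str, ...] = ("trial_number",),
    slice_name: str | None = None,
) -> RegressionResult:
    """OLS of a per-epoch outcome on distance plus nuisance regressors.

    Distance enters as integer steps (shortest distance for cue epochs,
    remaining shortest distance for move epochs).  Raises when fewer than two
    distance levels are present or when the design is collinear.
    """
    cols = [outcome, distance_col, *nuisance]
    data = table[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    n = y.size
    names = ["intercept", "distance", *nuisance]
    X = np.column_stack(
        [np.ones(n), data[distance_col].to_numpy(dtype=float)]
        + [data[c].to_numpy(dtype=float) for c in nuisance]
    )
    if np.unique(X[:, 1]).size < 2:
        raise ValueError(f"fewer than 2 distance levels in column {distance_col!r}")
    if n < X.shape[1]:
        raise ValueError(f"too few observations ({n}) for {X.shape[1]} regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design; columns {names} have rank {rank} < {X.shape[1]}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof > 0:
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(X.shape[1], np.nan)
    return RegressionResult(
        outcome=outcome,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        n=n,
        distance_col=distance_col,
        slice_name=slice_name,
    )


def group_test(
    betas: np.ndarray,
    mode: str = "one_sample",
    other: np.ndarray | None = None,
) -> GroupStats:
    """Two-sided t test on per-participant coefficients.

    ``one_sample`` tests the mean against zero; ``paired`` tests matched
    coefficient vectors against each other (Cohen's d on the differences).
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size < 3:
        raise ValueError("need >= 3 participants")
    if mode == "one_sample":
        values = betas
    elif mode == "paired":
        if other is None or len(other) != betas.size:
            raise ValueError("paired mode requires a matched second vector")
        values = betas - np.asarray(other, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across participants; t test degenerate")
    n = values.size
    t = values.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return GroupStats(
        test=mode,
        t=float(t),
        df=n - 1,
        p=float(p),
        cohens_d=float(values.mean() / sd),
        n=n,
        mean=float(values.mean()),
    )


def distance_profile(
    table: pd.DataFrame,
    outcome: str,
    distance_col: str = "goal_distance",
    bins: tuple[int, ...] = (3, 4, 5),
    descending: bool = False,
) -> pd.DataFrame:
    """Mean outcome per distance bin with dispersion; empty bins stay visible.

    Navigation profiles are conventionally ordered by descending distance
    (the goal being approached); set ``descending=True`` for that layout.
    """
    if len(bins) == 0:
        raise ValueError("bins must be non-empty")
    rows = []
    order = sorted(bins, reverse=descending)
    for b in order:
        vals = table.loc[table[distance_col] == b, outcome].dropna()
        rows.append(
            {
                "distance": b,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "sem": vals.sem() if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
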