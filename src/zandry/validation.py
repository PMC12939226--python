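"""Goodness-of-fit metrics and correlation analysis.

R^2/RMSE reports for simulated-versus-reference series, and the Pearson
correlation matrix (with two-sided significance flags) across quality
indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitReport", "r2_rmse", "pearson_matrix"]


@dataclass(frozen=True)
class FitReport:
    """Agreement between an observed and a predicted series."""

    label: str
    r2: float
    rmse: float
    max_relative_deviation_pct: float
    n: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "r2": self.r2,
            "rmse": self.rmse,
            "max_relative_deviation_pct": self.max_relative_deviation_pct,
            "n": self.n,
        }


def r2_rmse(
    observed: Sequence[float],
    predicted: Sequence[float],
    label: str = "",
    eps: float = 1e-12,
) -> FitReport:
    """Coefficient of determination, RMSE and max relative deviation.

    R^2 = 1 - SS_res/SS_tot; RMSE in the units of the compared quantity;
    the maximum relative deviation (%) is taken over points with
    |observed| > ``eps``.  A constant observed series leaves R^2 undefined
    (NaN, with a warning).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be matching 1-D arrays")
    if len(obs) < 2:
        raise ValueError("need at least 2 points")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant observed series; R^2 is undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    mask = np.abs(obs) > eps
    max_rel = (
        float(np.max(np.abs(resid[mask]) / np.abs(obs[mask])) * 100.0)
        if mask.any()
        else float("nan")
    )
    return FitReport(label=label, r2=r2, rmse=rmse,
                     max_relative_deviation_pct=max_rel, n=len(obs))


def pearson_matrix(
    table: pd.DataFrame, alpha: tuple[float, float] = (0.05, 0.01)
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided significance flags.

    Returns ``(r, p, flags)`` DataFrames over the numeric columns of
    ``table``; ``flags`` holds '' / '*' / '**' at the two alpha levels.
    Zero-variance columns yield NaN correlations.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows for correlation analysis")
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = num[cols[i]].to_numpy(), num[cols[j]].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    flags = p_df.map(
        lambda v: "**" if v < alpha[1] else ("*" if v < alpha[0] else "")
        if np.isfinite(v)
        else ""
    )
    return r_df, p_df, flags
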