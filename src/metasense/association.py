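"""Variance attribution for genome-wide antisense levels.

Univariate OLS of the per-(genome, sample) fraction of significant-asRNA
genes on each candidate driver (genome and sample as categorical factors;
AT content, Pribnow density, expression per Mbp and DNA coverage as numeric
regressors), summarized by R². Plus the Z-test for a change in a regression
coefficient after adding a confounder, and the exact paired Wilcoxon
signed-rank comparison of R² across communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    response: str
    regressor: str
    r_squared: float
    beta: float | None  # numeric regressors only
    se_beta: float | None
    n_obs: int


def _is_numeric(x: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(x)


def univariate_r2(
    response: Sequence[float],
    regressor: Sequence,
    response_name: str = "response",
    regressor_name: str = "regressor",
) -> RegressionResult:
    """OLS of response on one regressor; R² = 1 - SSE/SST.

    Categorical regressors are expanded to indicator contrasts, making R²
    the one-way between-group sum-of-squares ratio. A constant response
    yields R² = 0 with a warning; a single-level categorical regressor is an
    error.
    """
    y = pd.Series(response, dtype=float).reset_index(drop=True)
    x = pd.Series(regressor).reset_index(drop=True)
    if len(y) != len(x):
        raise ValueError("response and regressor lengths differ")
    keep = y.notna() & x.notna()
    y, x = y[keep], x[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y.to_numpy()) == 0:
        warnings.warn("constant response; R² defined as 0")
        return RegressionResult(response_name, regressor_name, 0.0, None, None, len(y))

    numeric = _is_numeric(x)
    if numeric:
        X = sm.add_constant(x.to_numpy(dtype=float))
    else:
        levels = x.astype(str)
        if levels.nunique() < 2:
            raise ValueError("categorical regressor has a single level")
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
        X = sm.add_constant(dummies.to_numpy())
    fit = sm.OLS(y.to_numpy(), X).fit()
    beta = float(fit.params[1]) if numeric else None
    se = float(fit.bse[1]) if numeric else None
    return RegressionResult(
        response_name, regressor_name, float(fit.rsquared), beta, se, len(y)
    )


def regressor_scan(
    summary: pd.DataFrame,
    response: str = "pct_significant",
    regressors: Sequence[str] = (
        "genome_id",
        "sample_id",
        "at_content",
        "rna_per_mbp",
        "pribnow_per_mbp",
        "dna_coverage",
    ),
) -> pd.DataFrame:
    """Univariate R² of the response on each available regressor, sorted
    descending — the 'which variable explains most' table."""
    rows = []
    for reg in regressors:
        if reg not in summary.columns or summary[reg].isna().all():
            continue
        res = univariate_r2(
            summary[response], summary[reg], response_name=response, regressor_name=reg
        )
        rows.append(res.__dict__)
    return (
        pd.DataFrame(rows).sort_values("r_squared", ascending=False).reset_index(drop=True)
    )


def coefficient_change_z(
    beta_uni: float,
    se_uni: float,
    beta_adj: float,
    se_adj: float,
) -> tuple[float, float]:
    """One-tailed Z-test for an increase of a regression coefficient after
    adding a confounder: z = (beta_adj - beta_uni) / sqrt(se_adj² + se_uni²),
    p = 1 - Phi(z). Estimates are treated as independent (conservative)."""
    if se_uni <= 0 or se_adj <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_adj - beta_uni) / np.hypot(se_adj, se_uni)
    return float(z), float(stats.norm.sf(z))


def paired_r2_ranksum(
    r2_base: Sequence[float], r2_extended: Sequence[float]
) -> float:
    """Exact one-tailed Wilcoxon signed-rank p for R² increasing from the base
    to the extended model across paired communities."""
    base = np.asarray(r2_base, dtype=float)
    ext = np.asarray(r2_extended, dtype=float)
    if base.shape != ext.shape:
        raise ValueError("paired vectors must have equal length")
    if base.size < 2:
        raise ValueError("need at least 2 paired communities")
    diff = ext - base
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    res = stats.wilcoxon(ext, base, alternative="greater", method="exact")
    return float(res.pvalue)
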