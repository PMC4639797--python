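"""Per-cohort linear models for age, methylation and phenotype associations.

All models are ordinary least squares, fit in vectorized form across genes,
CpGs, or CpG-gene pairs. Each fit yields the coefficient of interest, its
t-statistic, the z-score obtained by mapping the t tail probability through
the standard-normal quantile (sign-preserving), a two-sided p-value, the
sample size and the effect direction — the per-cohort summary-statistic rows
that the meta-analysis stage combines.

Models
------
- age model: standardized expression ~ age (+ adjusters), per gene
- model 1:  methylation beta-value ~ age (+ adjusters), per CpG
- model 2:  expression ~ methylation + age (+ adjusters), per CpG-gene pair,
  reporting the methylation coefficient
- phenotype model: phenotype ~ delta age + age (+ BMI), per phenotype
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import build_design

__all__ = [
    "fit_age_model",
    "fit_model1",
    "fit_model2",
    "fit_phenotype_model",
    "t_to_z",
    "STAT_COLUMNS",
]

#: columns of every per-cohort statistics table
STAT_COLUMNS = ["unit_id", "cohort_id", "beta", "se", "t", "z", "p", "n", "direction"]

P_FLOOR = 1e-300


def t_to_z(t: np.ndarray, df: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert t-statistics to z-scores and two-sided p-values.

    The z-score is the standard-normal quantile of the t tail probability,
    applied tail-wise so the sign is preserved; computed in log space so
    extreme statistics do not underflow. p-values are floored at 1e-300.
    """
    t = np.asarray(t, dtype=float)
    logsf = stats.t.logsf(np.abs(t), df)
    # cap at the p-value floor so extreme statistics stay finite
    logsf = np.maximum(logsf, np.log(P_FLOOR / 2.0))
    z = np.sign(t) * -special.ndtri_exp(logsf)
    p = np.clip(2.0 * np.exp(logsf), P_FLOOR, 1.0)
    return z, p


def _stats_table(
    unit_ids, cohort_id: str, beta, se, n: int, df: int
) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    # a perfect fit (zero residual s.e., nonzero effect) floors the p-value;
    # a degenerate unit (zero effect and zero s.e.) stays NaN
    exact = (se == 0) & (np.abs(beta) > 0)
    t = np.where(exact, np.sign(beta) * 1e15, t)
    z, p = t_to_z(np.nan_to_num(t, nan=0.0), df)
    z = np.where(np.isnan(t), np.nan, z)
    p = np.where(np.isnan(t), np.nan, p)
    return pd.DataFrame(
        {
            "unit_id": np.asarray(unit_ids, dtype=object),
            "cohort_id": cohort_id,
            "beta": beta,
            "se": se,
            "t": t,
            "z": z,
            "p": p,
            "n": n,
            "direction": np.where(np.isnan(t), "?", np.where(t >= 0, "+", "-")),
        }
    )


def _ols_many(
    X: np.ndarray, Y: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of each column of Y on X; return (beta, se, df) for one coefficient.

    Columns of Y with zero residual variance get se = 0 (flagged NaN upstream).
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} model parameters")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"rank-deficient design: {e}") from None
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[coef_index, coef_index])
    # constant outcomes carry no information: flag rather than fit noise
    degenerate = Y.std(axis=0) <= 1e-12 * (1.0 + np.abs(Y.mean(axis=0)))
    beta = np.where(degenerate, 0.0, coef[coef_index])
    se = np.where(degenerate, 0.0, se)
    return beta, se, df


def _design_with_age(
    covariates: pd.DataFrame, adjust: Sequence[str]
) -> tuple[np.ndarray, int, pd.Index]:
    """Design [intercept, age, adjusters]; returns matrix, age column index,
    and the sample index after dropping rows with missing covariates."""
    cols = ["age"] + [c for c in adjust if c != "age"]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates missing columns: {missing}")
    keep = covariates.loc[:, cols].dropna().index
    design = build_design(covariates.loc[keep], cols)
    return design.to_numpy(dtype=float), 1, keep


def fit_age_model(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    adjust: Sequence[str] = (),
    cohort_id: str = "cohort",
) -> pd.DataFrame:
    """Per-gene OLS of (standardized) expression on chronological age.

    Returns one row per gene with the age coefficient and its t/z/p
    statistics (columns :data:`STAT_COLUMNS`).
    """
    X, age_idx, keep = _design_with_age(covariates, adjust)
    Y = expr.loc[keep].to_numpy(dtype=float)
    beta, se, df = _ols_many(X, Y, age_idx)
    return _stats_table(expr.columns, cohort_id, beta, se, len(keep), df)


def fit_model1(
    meth: pd.DataFrame,
    covariates: pd.DataFrame,
    adjust: Sequence[str] = (),
    cohort_id: str = "cohort",
) -> pd.DataFrame:
    """Per-CpG OLS of methylation beta-values on chronological age.

    CpGs with constant methylation yield NaN statistics and direction '?'.
    """
    X, age_idx, keep = _design_with_age(covariates, adjust)
    Y = meth.loc[keep].to_numpy(dtype=float)
    beta, se, df = _ols_many(X, Y, age_idx)
    return _stats_table(meth.columns, cohort_id, beta, se, len(keep), df)


def fit_model2(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame,
    adjust: Sequence[str] = (),
    cohort_id: str = "cohort",
    collinear_r: float = 0.999,
) -> pd.DataFrame:
    """Per CpG-gene pair OLS of expression on methylation and age.

    Reports the methylation coefficient, age-adjusted. Implemented by
    partialling the base design [intercept, age, adjusters] out of both the
    expression and the methylation columns, then regressing residual on
    residual; this reproduces the full-model coefficient and t-statistic
    exactly, with one shared projection instead of one design per pair.

    ``pairs`` needs columns ``cpg_id`` and ``gene_id``. Pairs whose
    methylation is collinear with the base design (|r| of residuals above
    ``collinear_r`` with zero residual variance) are flagged NaN.
    """
    for col in ("cpg_id", "gene_id"):
        if col not in pairs.columns:
            raise KeyError(f"pairs table missing column {col!r}")
    X, _, keep = _design_with_age(covariates, adjust)
    n, k = X.shape

    Q, _ = np.linalg.qr(X)

    def _resid(df_: pd.DataFrame) -> np.ndarray:
        Y = df_.loc[keep].to_numpy(dtype=float)
        return Y - Q @ (Q.T @ Y)

    e_expr = _resid(expr)
    e_meth = _resid(meth)
    gi = expr.columns.get_indexer(pairs["gene_id"])
    ci = meth.columns.get_indexer(pairs["cpg_id"])
    if np.any(gi < 0) or np.any(ci < 0):
        raise KeyError("pair table references unknown gene or CpG ids")

    ey = e_expr[:, gi]
    em = e_meth[:, ci]
    ss_m = (em**2).sum(axis=0)
    ss_y = (ey**2).sum(axis=0)
    cov = (em * ey).sum(axis=0)

    df = n - k - 1  # base params plus the methylation coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cov / ss_m
        rss = ss_y - cov**2 / ss_m
        se = np.sqrt(np.maximum(rss, 0.0) / df / ss_m)
    bad = ss_m <= 1e-12 * n  # methylation collinear with the base design
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    unit_ids = pairs["cpg_id"].astype(str) + "|" + pairs["gene_id"].astype(str)
    out = _stats_table(unit_ids.to_numpy(), cohort_id, beta, se, n, df)
    out.insert(1, "gene_id", pairs["gene_id"].to_numpy())
    out.insert(1, "cpg_id", pairs["cpg_id"].to_numpy())
    return out


def mad_outlier_mask(values: np.ndarray, k: float = 4.0) -> np.ndarray:
    """True for entries within ``k`` median-absolute-deviations of the median.

    With a constant input the MAD is zero and everything is kept.
    """
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    if mad == 0:
        return ~np.isnan(values)
    return np.abs(values - med) <= k * mad


def fit_phenotype_model(
    phenotypes: pd.DataFrame,
    delta_age: pd.Series,
    age: pd.Series,
    bmi: pd.Series | None = None,
    bmi_adjust: bool = False,
    cohort_id: str = "cohort",
    outlier_mad: float = 4.0,
) -> pd.DataFrame:
    """Per-phenotype OLS of phenotype on delta age, adjusted for age.

    Phenotype outliers (beyond ``outlier_mad`` MADs from the median) are
    excluded before the fit; the number excluded is recorded in an
    ``n_outliers`` column. With ``bmi_adjust`` the model also includes BMI.
    """
    if bmi_adjust and bmi is None:
        raise ValueError("bmi_adjust=True requires a bmi series")
    idx = phenotypes.index.intersection(delta_age.index).intersection(age.index)
    rows = []
    for name in phenotypes.columns:
        y_all = phenotypes.loc[idx, name].to_numpy(dtype=float)
        keep = mad_outlier_mask(y_all, outlier_mad)
        y = y_all[keep]
        cols = [np.ones(keep.sum()), delta_age.loc[idx].to_numpy()[keep],
                age.loc[idx].to_numpy()[keep]]
        if bmi_adjust:
            cols.append(bmi.loc[idx].to_numpy()[keep])
        X = np.column_stack(cols)
        beta, se, df = _ols_many(X, y[:, None], 1)
        tab = _stats_table([name], cohort_id, beta, se, int(keep.sum()), df)
        tab["n_outliers"] = int((~keep).sum())
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)
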