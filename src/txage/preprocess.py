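"""Expression normalization, detection filtering, and residualization.

The pipeline mirrors a standard bead-array workflow: quantile-normalize each
sample to the median distribution and log2-transform; center probe and sample
means to zero; keep genes detected above background in more than 10% of all
discovery samples and measured in at least two cohorts; and finally replace
expression by standardized residuals after regressing out technical and
biological covariates (everything except age), so the association stage sees
mean-zero, unit-variance, covariate-adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize_log2",
    "center_matrix",
    "filter_expressed",
    "residualize",
    "build_design",
]

_SCALE_ORDER = ("raw", "qnorm_log2", "centered", "residual_standardized")


@dataclass
class ExpressionMatrix:
    """A samples-by-genes matrix with a scale tag tracking its processing state.

    The tag may only advance through ``raw -> qnorm_log2 -> centered ->
    residual_standardized``; operations check the tag of their input.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALE_ORDER:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    def _advance(self, new_tag: str, values: pd.DataFrame) -> "ExpressionMatrix":
        if _SCALE_ORDER.index(new_tag) <= _SCALE_ORDER.index(self.scale_tag):
            raise ValueError(
                f"scale_tag may only move forward: {self.scale_tag!r} -> {new_tag!r}"
            )
        return ExpressionMatrix(values=values, scale_tag=new_tag)

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def gene_ids(self):
        return self.values.columns


def quantile_normalize_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the median distribution, then log2.

    Every sample's order statistics are replaced by the across-sample median
    of the corresponding order statistic, so all rows share one distribution;
    within-sample ranks are preserved. Ties share the mean of their target
    values. Requires strictly positive input.
    """
    x = m.values.to_numpy(dtype=float)
    if np.any(x <= 0):
        i, j = np.argwhere(x <= 0)[0]
        raise ValueError(
            "quantile normalization requires strictly positive values; "
            f"found {x[i, j]!r} at sample {m.values.index[i]!r}, "
            f"gene {m.values.columns[j]!r}"
        )
    order = np.argsort(x, axis=1, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=1)
    target = np.median(sorted_x, axis=0)

    out = np.empty_like(x)
    for r in range(x.shape[0]):
        row = np.empty(x.shape[1])
        row[order[r]] = target
        # ties: average the target values over tied entries
        vals, inv, counts = np.unique(x[r], return_inverse=True, return_counts=True)
        if len(vals) < x.shape[1]:
            sums = np.zeros(len(vals))
            np.add.at(sums, inv, row)
            row = (sums / counts)[inv]
        out[r] = row
    out = np.log2(out)
    return m._advance(
        "qnorm_log2", pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    )


def center_matrix(
    m: ExpressionMatrix, tol: float = 1e-10, max_iter: int = 100
) -> ExpressionMatrix:
    """Center probe (column) and sample (row) means to zero.

    Alternates row- and column-mean removal until both are below ``tol`` in
    absolute value; for a plain mean-centering this converges in one or two
    sweeps. Idempotent on already-centered input.
    """
    x = m.values.to_numpy(dtype=float).copy()
    for _ in range(max_iter):
        x -= x.mean(axis=1, keepdims=True)
        x -= x.mean(axis=0, keepdims=True)
        if (
            np.abs(x.mean(axis=1)).max() < tol
            and np.abs(x.mean(axis=0)).max() < tol
        ):
            break
    return m._advance(
        "centered", pd.DataFrame(x, index=m.values.index, columns=m.values.columns)
    )


def filter_expressed(
    detection_p: Mapping[str, pd.DataFrame],
    p_thresh: float = 0.05,
    frac: float = 0.10,
    min_cohorts: int = 2,
) -> tuple[set, pd.DataFrame]:
    """Select genes detected above background across the discovery sample.

    A gene is kept iff (1) its detection p-value is below ``p_thresh`` in
    strictly more than ``frac`` of all discovery samples pooled across
    cohorts, and (2) it is measured in at least ``min_cohorts`` cohorts.

    Parameters
    ----------
    detection_p:
        Mapping cohort id -> samples-by-genes detection p-value matrix; a
        gene is "measured" in a cohort iff it appears among that cohort's
        columns.

    Returns
    -------
    (kept, report):
        The kept gene-id set and a per-gene report table with columns
        ``gene_id, n_cohorts, frac_detected, kept, reason``.
    """
    passing: dict[str, int] = {}
    measured: dict[str, int] = {}
    total_samples = 0
    for dp in detection_p.values():
        total_samples += dp.shape[0]
        counts = (dp.to_numpy() < p_thresh).sum(axis=0)
        for gene, cnt in zip(dp.columns, counts):
            passing[gene] = passing.get(gene, 0) + int(cnt)
            measured[gene] = measured.get(gene, 0) + 1

    rows = []
    kept: set = set()
    for gene in passing:
        fr = passing[gene] / total_samples
        ok_frac = fr > frac
        ok_cohorts = measured[gene] >= min_cohorts
        if ok_frac and ok_cohorts:
            kept.add(gene)
            reason = ""
        elif not ok_frac:
            reason = f"detected in {fr:.3f} <= {frac} of samples"
        else:
            reason = f"measured in {measured[gene]} < {min_cohorts} cohorts"
        rows.append(
            {
                "gene_id": gene,
                "n_cohorts": measured[gene],
                "frac_detected": fr,
                "kept": gene in kept,
                "reason": reason,
            }
        )
    return kept, pd.DataFrame(rows)


def build_design(
    covariates: pd.DataFrame,
    columns: Sequence[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Build a numeric design matrix from a covariate table.

    Non-numeric (factor) columns are expanded to 0/1 indicators with the
    first level as reference. Rows with missing values are dropped by the
    caller (see :func:`residualize`).
    """
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"intercept": np.ones(len(covariates))}, index=covariates.index))
    for col in columns:
        if col not in covariates.columns:
            raise KeyError(f"covariate column {col!r} not found")
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_frame())
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def residualize(
    m: ExpressionMatrix,
    covariates: pd.DataFrame,
    covariate_list: Sequence[str],
) -> ExpressionMatrix:
    """Replace expression by standardized residuals on the given covariates.

    Per gene: OLS residuals of expression on an intercept plus the listed
    covariates, divided by their sample s.d. (n-1 denominator). The output is
    gene-wise mean zero and unit variance, and numerically orthogonal to
    every covariate column. ``age`` must not be among the covariates — it is
    the exposure of the downstream association models.
    """
    if "age" in covariate_list:
        raise ValueError("covariate_list must not include 'age'")
    vals = m.values
    design = build_design(covariates.loc[vals.index], covariate_list)
    X = design.to_numpy(dtype=float)

    # guard against singular designs and report offending columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _dependent_columns(X, design.columns)
        raise ValueError(f"singular covariate design; dependent columns: {bad}")

    Y = vals.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sd = resid.std(axis=0, ddof=1)
    zero = sd < 1e-12
    if np.any(zero):
        genes = list(vals.columns[zero])
        raise ValueError(f"zero residual variance for genes: {genes[:5]}")
    out = (resid - resid.mean(axis=0)) / sd
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        scale_tag="residual_standardized",
    )


def _dependent_columns(X: np.ndarray, names) -> list[str]:
    """Identify columns that do not increase the design rank (for messages)."""
    bad = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, j : j + 1]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(str(name))
    return bad
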