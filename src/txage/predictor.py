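"""Transcriptomic age prediction from meta-analysis summary statistics.

The predictor never sees individual-level training data jointly: it takes
per-gene marginal effects from the age-association meta-analysis and a
gene-by-gene reference correlation matrix R averaged over training cohorts,
and solves an approximate ridge regression (the summary-statistic analogue of
best linear unbiased prediction):

    b       = z / sqrt(z^2 + n - 2)            marginal effect, s.d./s.d. scale
    b_R     = ((n-1) R + lambda I)^(-1) (n-1) b    joint ridge effects
    Z_j     = sum_i b_R[i] * x[j, i]           raw predictor for individual j
    SZ_j    = (Z_j - mu_z) / sigma_z * sigma_age + mu_age
    delta_j = SZ_j - age_j

The ridge penalty lambda is calibrated by maximizing the correlation between
predicted and chronological age in a designated calibration cohort, which is
excluded from the meta-analysis and from R. Leave-one-out validation re-runs
the meta-analysis without each target cohort before scoring it, so validation
is always out-of-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .meta import stouffer_meta

__all__ = [
    "PredictorModel",
    "AgePrediction",
    "z_to_beta",
    "reference_correlation",
    "ridge_joint_effects",
    "train_predictor",
    "calibrate_lambda",
    "predict_cohort",
    "loo_predict",
    "scale_predictions",
    "delta_age",
    "pooled_age_sd",
    "export_general_predictor",
    "load_predictor",
    "score_with_weights",
]

DEFAULT_LAMBDA_GRID = np.logspace(0, 6, 25)


@dataclass
class PredictorModel:
    """Joint ridge effects plus the pieces they were derived from."""

    gene_ids: pd.Index
    b_marginal: np.ndarray
    b_r: np.ndarray
    lam: float
    r_matrix: np.ndarray
    n_eff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not np.all(np.isfinite(self.b_r)):
            raise ValueError("non-finite joint effects")


@dataclass
class AgePrediction:
    """Per-sample raw predictor, scaled transcriptomic age, and delta age."""

    table: pd.DataFrame  # columns: z_raw, sz, delta, age
    mu_age: float
    sigma_age: float
    mu_z: float
    sigma_z: float

    @property
    def r_with_age(self) -> float:
        return float(np.corrcoef(self.table["sz"], self.table["age"])[0, 1])


def z_to_beta(z, n) -> np.ndarray:
    """Marginal effect on the standardized scale from a z (or t) statistic.

    ``b = z / sqrt(z^2 + n - 2)``: the identity linking the test statistic
    of a simple regression between standardized variables to its slope
    (equivalently the correlation coefficient).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("z_to_beta requires n > 2")
    return z / np.sqrt(z**2 + n - 2.0)


def reference_correlation(
    exprs: Sequence[pd.DataFrame],
    ns: Sequence[int] | None = None,
) -> tuple[np.ndarray, pd.Index]:
    """Sample-size-weighted average of per-cohort gene correlation matrices.

    ``R = sum_i n_i R_i / sum_i n_i`` with the diagonal reset to exactly 1.
    All cohorts must share the same gene set (columns are aligned to the
    first cohort's order).
    """
    if not exprs:
        raise ValueError("need at least one cohort for the reference correlation")
    genes = exprs[0].columns
    if ns is None:
        ns = [len(e) for e in exprs]
    acc = np.zeros((len(genes), len(genes)))
    total = 0.0
    for e, n in zip(exprs, ns):
        if set(e.columns) != set(genes):
            raise ValueError("gene sets differ across cohorts")
        x = e.loc[:, genes].to_numpy(dtype=float)
        acc += n * np.corrcoef(x, rowvar=False)
        total += n
    r = acc / total
    np.fill_diagonal(r, 1.0)
    return r, genes


def ridge_joint_effects(
    b_marginal: np.ndarray,
    r_matrix: np.ndarray,
    n: float,
    lam: float,
) -> np.ndarray:
    """Solve ((n-1) R + lambda I) b_R = (n-1) b via a symmetric PD solve."""
    if n <= 1:
        raise ValueError("n must exceed 1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    a = (n - 1.0) * r_matrix + lam * np.eye(len(b_marginal))
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
    except linalg.LinAlgError:
        raise ValueError(
            "system not positive definite (rank-deficient R at lambda=0?); "
            "use lambda > 0"
        ) from None
    return linalg.cho_solve((c, low), (n - 1.0) * b_marginal, check_finite=False)


def _effective_n(ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of contributing cohort sizes."""
    ns = np.asarray(ns, dtype=float)
    return float((ns**2).sum() / ns.sum())


def train_predictor(
    stats_tables: Sequence[pd.DataFrame],
    exprs_for_r: Sequence[pd.DataFrame],
    lam: float,
    gene_ids: pd.Index | None = None,
) -> PredictorModel:
    """Build a predictor from per-cohort age-model statistics and reference
    expression matrices (both excluding any validation cohort).

    The meta-analysis combines the supplied cohorts by Stouffer weighting;
    marginal effects come from the meta z and total n; R is the weighted
    average correlation matrix; n in ``(n-1)R`` is the weighted mean cohort
    size of the R reference cohorts.
    """
    meta = stouffer_meta(stats_tables, stage="discovery")
    meta = meta.set_index("unit_id")
    r_matrix, genes = reference_correlation(exprs_for_r)
    if gene_ids is not None:
        genes = pd.Index(gene_ids)
        gsel = [list(exprs_for_r[0].columns).index(g) for g in genes]
        r_matrix = r_matrix[np.ix_(gsel, gsel)]
    meta = meta.reindex(genes)
    if meta["z_meta"].isna().any():
        missing = list(genes[meta["z_meta"].isna()])
        raise ValueError(f"genes missing from meta-analysis: {missing[:5]}")
    b = z_to_beta(meta["z_meta"].to_numpy(), meta["n_total"].to_numpy())
    n_eff = _effective_n([len(e) for e in exprs_for_r])
    b_r = ridge_joint_effects(b, r_matrix, n_eff, lam)
    return PredictorModel(
        gene_ids=genes,
        b_marginal=b,
        b_r=b_r,
        lam=float(lam),
        r_matrix=r_matrix,
        n_eff=n_eff,
        provenance={"n_cohorts": len(stats_tables)},
    )


def scale_predictions(
    z_raw: pd.Series, mu_age: float, sigma_age: float
) -> tuple[pd.Series, float, float]:
    """Affinely rescale the raw predictor to the age scale.

    Returns ``(sz, mu_z, sigma_z)`` with ``mean(sz) = mu_age`` and
    ``sd(sz) = sigma_age`` exactly (n-1 denominator).
    """
    mu_z = float(z_raw.mean())
    sigma_z = float(z_raw.std(ddof=1))
    if not sigma_z > 0:
        raise ValueError("predictor has zero variance; cannot scale")
    sz = (z_raw - mu_z) / sigma_z * sigma_age + mu_age
    return sz, mu_z, sigma_z


def delta_age(sz: pd.Series, age: pd.Series) -> pd.Series:
    """Scaled transcriptomic age minus chronological age, per individual."""
    if not sz.index.equals(age.index):
        raise ValueError("sz and age must be aligned on the same samples")
    return sz - age


def predict_cohort(
    model: PredictorModel,
    expr: pd.DataFrame,
    age: pd.Series,
    min_gene_overlap: float = 0.9,
) -> AgePrediction:
    """Score a validation cohort with a trained model.

    ``z_raw`` is the weighted sum of the cohort's standardized expression
    over the model genes; genes absent from the cohort are dropped from the
    sum without reweighting, provided at least ``min_gene_overlap`` of the
    model genes are present. Scaling uses the cohort's own age mean/s.d.
    and the predictor's own mean/s.d.
    """
    common = model.gene_ids.intersection(expr.columns)
    overlap = len(common) / len(model.gene_ids)
    if overlap < min_gene_overlap:
        raise ValueError(
            f"gene overlap {overlap:.2%} below floor {min_gene_overlap:.0%} "
            f"({len(common)}/{len(model.gene_ids)} model genes present)"
        )
    w = pd.Series(model.b_r, index=model.gene_ids).loc[common]
    z_raw = expr.loc[:, common] @ w
    mu_age, sigma_age = float(age.mean()), float(age.std(ddof=1))
    sz, mu_z, sigma_z = scale_predictions(z_raw, mu_age, sigma_age)
    table = pd.DataFrame(
        {"z_raw": z_raw, "sz": sz, "delta": delta_age(sz, age), "age": age}
    )
    return AgePrediction(table, mu_age, sigma_age, mu_z, sigma_z)


def calibrate_lambda(
    stats_tables: Sequence[pd.DataFrame],
    exprs_for_r: Sequence[pd.DataFrame],
    calib_expr: pd.DataFrame,
    calib_age: pd.Series,
    grid: Sequence[float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose lambda maximizing r(predicted age, age) in the calibration
    cohort; ties resolve to the smallest lambda.

    The calibration cohort must not appear in ``stats_tables`` or
    ``exprs_for_r``. Returns the chosen lambda and the grid trace
    (lambda, r).
    """
    if grid is None:
        grid = DEFAULT_LAMBDA_GRID
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if len(grid) == 0:
        raise ValueError("lambda grid is empty")
    rows = []
    for lam in grid:
        model = train_predictor(stats_tables, exprs_for_r, lam)
        pred = predict_cohort(model, calib_expr, calib_age)
        rows.append({"lambda": lam, "r": pred.r_with_age})
    trace = pd.DataFrame(rows)
    best = trace["r"].round(12).idxmax()  # first (= smallest lambda) among ties
    return float(trace.loc[best, "lambda"]), trace


def loo_predict(
    stats_by_cohort: dict[str, pd.DataFrame],
    exprs_by_cohort: dict[str, pd.DataFrame],
    ages_by_cohort: dict[str, pd.Series],
    target: str,
    lam: float,
) -> AgePrediction:
    """Leave-one-out prediction: train on every cohort except ``target``
    (both the meta-analysis and R exclude it), then score ``target``."""
    train_ids = [c for c in stats_by_cohort if c != target]
    if not train_ids:
        raise ValueError("need at least one training cohort")
    model = train_predictor(
        [stats_by_cohort[c] for c in train_ids],
        [exprs_by_cohort[c] for c in train_ids],
        lam,
    )
    return predict_cohort(model, exprs_by_cohort[target], ages_by_cohort[target])


def pooled_age_sd(
    cohort_means: Sequence[float],
    cohort_sds: Sequence[float],
    cohort_ns: Sequence[int],
) -> tuple[float, float]:
    """Pooled mean and s.d. of age across cohorts from summary moments.

    ``sigma^2 = [sum (n_i - 1) s_i^2 + sum n_i (mu_i - mu)^2] / (sum n_i - 1)``
    — the within- plus between-cohort decomposition; equals the moments of
    the concatenated samples when the s_i use the n-1 denominator.
    """
    mus = np.asarray(cohort_means, dtype=float)
    sds = np.asarray(cohort_sds, dtype=float)
    ns = np.asarray(cohort_ns, dtype=float)
    if len(ns) < 2:
        raise ValueError("pooling requires at least two cohorts")
    if np.any(ns < 2):
        raise ValueError("every cohort must have n >= 2")
    mu = float((ns * mus).sum() / ns.sum())
    var = float(
        (((ns - 1) * sds**2).sum() + (ns * (mus - mu) ** 2).sum()) / (ns.sum() - 1)
    )
    return mu, float(np.sqrt(var))


def export_general_predictor(
    model: PredictorModel,
    path: str | Path,
    mu_age: float,
    sigma_age: float,
    mu_z: float,
    sigma_z: float,
) -> None:
    """Write a portable predictor file: constants header plus gene weights.

    Format: '#'-prefixed ``key=value`` lines (mu_age, sigma_age, mu_z,
    sigma_z, lambda, n_eff) followed by a two-column TSV
    ``gene_id<TAB>weight``.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key, val in [
            ("mu_age", mu_age),
            ("sigma_age", sigma_age),
            ("mu_z", mu_z),
            ("sigma_z", sigma_z),
            ("lambda", model.lam),
            ("n_eff", model.n_eff),
        ]:
            fh.write(f"#{key}={float(val)!r}\n")
        fh.write("gene_id\tweight\n")
        for g, w in zip(model.gene_ids, model.b_r):
            fh.write(f"{g}\t{float(w)!r}\n")


def load_predictor(path: str | Path) -> tuple[pd.Series, dict[str, float]]:
    """Read a predictor file back: (weights series, constants dict)."""
    constants: dict[str, float] = {}
    rows: list[tuple[str, float]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].split("=", 1)
                constants[key] = float(val)
            elif line and not line.startswith("gene_id\t"):
                g, w = line.split("\t")
                rows.append((g, float(w)))
    weights = pd.Series(dict(rows), name="weight")
    return weights, constants


def score_with_weights(
    weights: pd.Series,
    constants: dict[str, float],
    expr: pd.DataFrame,
) -> pd.Series:
    """Score an external cohort with an exported predictor file's contents.

    Returns the scaled transcriptomic age using the exported constants
    (for cohorts without chronological age available).
    """
    common = weights.index.intersection(expr.columns)
    z_raw = expr.loc[:, common] @ weights.loc[common]
    return (z_raw - constants["mu_z"]) / constants["sigma_z"] * constants[
        "sigma_age"
    ] + constants["mu_age"]
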