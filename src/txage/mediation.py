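"""Methylation-mediation analysis: Sobel tests, matched controls, enrichment.

For every CpG within a fixed window (default +/-250 kb) of an age-associated
gene, two meta-analyzed statistics are combined in a Sobel test:

    Z_sobel = Z1 * Z2 / sqrt(Z1^2 + Z2^2)

where Z1 is the meta z-score for methylation ~ age (model 1) and Z2 the meta
z-score for expression ~ methylation | age (model 2). A CpG-gene pair is
flagged as mediating if its Sobel p-value clears a per-gene Bonferroni
threshold (alpha divided by the number of CpGs tested in that gene).

Control genes matched on gene length and log mean expression support
Fisher-exact enrichment tests of significant CpGs in age-associated versus
random genes, and of genomic features (CpG island/shore/shelf, chromatin
states) in mediating versus non-mediating CpGs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "window_assign",
    "sobel_test",
    "flag_mediators",
    "select_matched_random_genes",
    "classify_cpg_region",
    "enrichment_test",
    "enrichment_over_alpha_grid",
]


def window_assign(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Pair each CpG with every gene whose window contains it.

    A CpG at position ``pos`` on the same chromosome pairs with gene ``g``
    iff ``start(g) - window_bp <= pos < end(g) + window_bp`` (closed lower
    bound, half-open upper bound, 0-based coordinates). One CpG may pair
    with several genes when windows overlap.

    ``cpgs`` needs columns ``cpg_id, chrom, pos`` (rows with a true
    ``excluded`` column are dropped first); ``genes`` needs
    ``gene_id, chrom, start, end``. Returns a ``cpg_id, gene_id`` table.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be nonnegative, got {window_bp}")
    if "excluded" in cpgs.columns:
        cpgs = cpgs.loc[~cpgs["excluded"].astype(bool)]
    out = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        csub = cpgs.loc[cpgs["chrom"] == chrom]
        if csub.empty:
            continue
        pos = csub["pos"].to_numpy(dtype=np.int64)
        lo = gsub["start"].to_numpy(dtype=np.int64) - window_bp
        hi = gsub["end"].to_numpy(dtype=np.int64) + window_bp
        # sort genes by window start and sweep with searchsorted bounds
        order = np.argsort(lo, kind="stable")
        lo_s, hi_s = lo[order], hi[order]
        gid_s = gsub["gene_id"].to_numpy()[order]
        for p, cid in zip(pos, csub["cpg_id"].to_numpy()):
            j_max = np.searchsorted(lo_s, p, side="right")
            hits = np.nonzero(hi_s[:j_max] > p)[0]
            for j in hits:
                out.append((cid, gid_s[j]))
    return pd.DataFrame(out, columns=["cpg_id", "gene_id"])


def sobel_test(z1, z2) -> tuple[np.ndarray, np.ndarray]:
    """Sobel mediation statistic and two-sided normal p-value.

    ``z_sobel = z1 * z2 / sqrt(z1^2 + z2^2)``, defined as 0 when both
    inputs are 0. Accepts scalars or arrays. The identity
    ``|z_sobel| <= min(|z1|, |z2|)`` holds for all inputs.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
        raise ValueError("sobel_test requires finite inputs")
    denom = np.sqrt(z1**2 + z2**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, z1 * z2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return z, p


def flag_mediators(sobel: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Bonferroni flagging of mediating CpG-gene pairs.

    ``sobel`` needs columns ``gene_id`` and ``p_sobel``. A pair is flagged
    iff ``p_sobel < alpha / (number of CpGs tested in its gene)``. Returns
    the table with an added boolean ``mediator_flag`` column.
    """
    out = sobel.copy()
    n_per_gene = out.groupby("gene_id")["gene_id"].transform("size")
    out["mediator_flag"] = out["p_sobel"] < (alpha / n_per_gene)
    return out


def select_matched_random_genes(
    candidates: pd.DataFrame,
    targets: pd.DataFrame,
    k: int | None = None,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Select control genes matched to targets on length and mean expression.

    One-to-one greedy nearest-neighbour matching on standardized
    (log length_bp, log-scale mean expression), followed by a swap-refinement
    pass that resolves pairwise assignment improvements. Both tables need
    ``gene_id, length_bp, mean_expression``.

    ``mean_expression`` is used on its recorded scale if it can be negative
    (already-log values); otherwise its log is taken.

    Returns the matched subset of ``candidates`` (k rows, aligned to target
    order).
    """
    if k is None:
        k = len(targets)
    if k == 0:
        return candidates.iloc[0:0]
    pool = candidates
    if not allow_overlap:
        pool = candidates.loc[~candidates["gene_id"].isin(set(targets["gene_id"]))]
    if len(pool) < k:
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than requested matches ({k})"
        )

    def _features(df: pd.DataFrame) -> np.ndarray:
        length = np.log(df["length_bp"].to_numpy(dtype=float))
        me = df["mean_expression"].to_numpy(dtype=float)
        if np.all(me > 0):
            me = np.log(me)
        return np.column_stack([length, me])

    ft = _features(targets.iloc[:k])
    fc = _features(pool)
    both = np.vstack([ft, fc])
    mu, sd = both.mean(axis=0), both.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    ft = (ft - mu) / sd
    fc = (fc - mu) / sd

    d = np.sqrt(((ft[:, None, :] - fc[None, :, :]) ** 2).sum(axis=2))
    # greedy pass: globally smallest distances first
    assign = np.full(len(ft), -1)
    used = np.zeros(len(fc), dtype=bool)
    order = np.argsort(d, axis=None, kind="stable")
    n_assigned = 0
    for flat in order:
        i, j = divmod(flat, d.shape[1])
        if assign[i] == -1 and not used[j]:
            assign[i] = j
            used[j] = True
            n_assigned += 1
            if n_assigned == len(ft):
                break
    # refinement: swap pairs while that lowers total distance
    improved = True
    while improved:
        improved = False
        for i in range(len(ft)):
            for i2 in range(i + 1, len(ft)):
                j, j2 = assign[i], assign[i2]
                if d[i, j2] + d[i2, j] < d[i, j] + d[i2, j2] - 1e-15:
                    assign[i], assign[i2] = j2, j
                    improved = True
    return pool.iloc[assign].reset_index(drop=True)


def classify_cpg_region(
    pos: int | np.ndarray,
    islands: Sequence[tuple[int, int]],
    flank_bp: int = 1_500,
) -> np.ndarray:
    """Classify positions relative to CpG islands.

    ``island`` if inside an island interval (0-based half-open); ``shore``
    within ``flank_bp`` of an island edge (boundary closed toward the
    island); ``shelf`` within the next ``flank_bp`` (1,501-3,000 bp from the
    island by default); otherwise ``open_sea``. Islands must be sorted and
    non-overlapping.
    """
    iv = np.asarray(list(islands), dtype=np.int64).reshape(-1, 2)
    if len(iv) > 1:
        if np.any(np.diff(iv[:, 0]) < 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("islands must be sorted and non-overlapping")
    pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    out = np.full(pos_arr.shape, "open_sea", dtype=object)
    if len(iv):
        starts, ends = iv[:, 0], iv[:, 1]
        for i, p in enumerate(pos_arr):
            # distance to the nearest island (0 if inside, half-open)
            inside = (starts <= p) & (p < ends)
            if inside.any():
                out[i] = "island"
                continue
            # gap distance: for p left of an island start s it is s - p, for
            # p at or beyond the (half-open) end e it is p - e; the shore
            # boundary is closed toward the island at exactly flank_bp
            dist = np.minimum(
                np.where(starts > p, starts - p, np.iinfo(np.int64).max),
                np.where(p >= ends, p - ends, np.iinfo(np.int64).max),
            ).min()
            if dist <= flank_bp:
                out[i] = "shore"
            elif dist <= 2 * flank_bp:
                out[i] = "shelf"
    if np.isscalar(pos) or np.asarray(pos).ndim == 0:
        return out[0]
    return out


def enrichment_test(
    group_a_flags: np.ndarray,
    group_b_flags: np.ndarray,
) -> dict:
    """Fisher exact test of flag enrichment in group A versus group B.

    Returns ``{"table": 2x2, "odds_ratio", "ci95", "p"}``. The 2x2 table is
    [[a_flagged, a_not], [b_flagged, b_not]]; the odds ratio is the sample
    OR with a Woolf (log-OR normal) 95% CI. A zero margin triggers the
    Haldane-Anscombe 0.5 correction for the OR and CI (the Fisher p uses
    the raw counts).
    """
    a = np.asarray(group_a_flags, dtype=bool)
    b = np.asarray(group_b_flags, dtype=bool)
    table = np.array(
        [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if np.any(table == 0):
        t = t + 0.5
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se_log = np.sqrt((1.0 / t).sum())
    lo = float(np.exp(np.log(or_) - 1.959963984540054 * se_log))
    hi = float(np.exp(np.log(or_) + 1.959963984540054 * se_log))
    return {"table": table, "odds_ratio": float(or_), "ci95": (lo, hi), "p": float(p)}


def enrichment_over_alpha_grid(
    p_a: np.ndarray,
    p_b: np.ndarray,
    alphas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Run the enrichment test across a grid of significance levels.

    Flags are ``p < alpha`` within each group; the default grid spans
    1e-20 to 0.05 (log-spaced), the robustness sweep used around the main
    enrichment threshold.
    """
    if alphas is None:
        alphas = np.logspace(-20, np.log10(0.05), 10)
    rows = []
    for alpha in alphas:
        res = enrichment_test(np.asarray(p_a) < alpha, np.asarray(p_b) < alpha)
        rows.append(
            {
                "alpha": alpha,
                "odds_ratio": res["odds_ratio"],
                "ci_low": res["ci95"][0],
                "ci_high": res["ci95"][1],
                "p": res["p"],
            }
        )
    return pd.DataFrame(rows)
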