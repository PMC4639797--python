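"""Sample-size-weighted (Stouffer) meta-analysis with replication gating.

Per-cohort z-scores (or t-statistics, for the methylation models) are
combined as a weighted sum with weights proportional to the square root of
each cohort's sample size and standardized so the squared weights sum to
one — the METAL sample-size scheme. Discovery hits pass a Bonferroni
threshold computed from the number of units actually tested; replication
additionally requires the replication-stage z to point in the discovery
direction; the combined stage re-meta-analyses all cohorts of both stages.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "stouffer_meta",
    "bonferroni_threshold",
    "gate_discovery",
    "gate_replication",
    "combine_stages",
]

META_COLUMNS = ["unit_id", "z_meta", "p_meta", "n_total", "direction_string", "stage"]


def _meta_from_wide(
    z: pd.DataFrame, n: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Stouffer-combine units-by-cohorts z and n tables."""
    Z = z.to_numpy(dtype=float)
    N = n.to_numpy(dtype=float)
    present = ~np.isnan(Z)
    if not present.any(axis=1).all():
        missing = z.index[~present.any(axis=1)].tolist()
        raise ValueError(f"units with no cohort statistics: {missing[:5]}")
    w = np.where(present, np.sqrt(np.where(present, N, 0.0)), 0.0)
    w = w / np.sqrt((w**2).sum(axis=1, keepdims=True))
    z_meta = np.nansum(w * Z, axis=1)
    p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z_meta)), 1e-300, 1.0)
    n_total = np.where(present, N, 0.0).sum(axis=1).astype(int)
    signs = np.where(present, np.where(Z >= 0, "+", "-"), "?")
    direction = ["".join(row) for row in signs]
    return pd.DataFrame(
        {
            "unit_id": z.index,
            "z_meta": z_meta,
            "p_meta": p_meta,
            "n_total": n_total,
            "direction_string": direction,
            "stage": stage,
        }
    ).reset_index(drop=True)


def stouffer_meta(
    stats_tables: Iterable[pd.DataFrame],
    stage: str = "discovery",
    cohort_order: Sequence[str] | None = None,
    stat: str = "z",
) -> pd.DataFrame:
    """Combine per-cohort statistics tables into one meta-analysis table.

    Parameters
    ----------
    stats_tables:
        Per-cohort tables as produced by the association module (columns
        ``unit_id, cohort_id, z, t, n, ...``). Units absent from a cohort, or
        with NaN statistics there, appear as '?' in the direction string and
        are excluded from the weights for that unit.
    cohort_order:
        Fixed cohort order for the direction string; defaults to order of
        appearance.
    stat:
        Which per-cohort statistic to combine: ``"z"`` (default) or ``"t"``
        (the weighted sum of t-statistics used for the methylation models).

    Returns one row per unit: ``unit_id, z_meta, p_meta, n_total,
    direction_string, stage``. Units missing in every cohort are dropped.
    """
    tables = [t for t in stats_tables if len(t)]
    if not tables:
        raise ValueError("no cohort statistics supplied")
    longf = pd.concat(tables, ignore_index=True)
    if cohort_order is None:
        cohort_order = list(dict.fromkeys(longf["cohort_id"]))
    z = longf.pivot_table(index="unit_id", columns="cohort_id", values=stat,
                          aggfunc="first", sort=False)
    z = z.reindex(columns=cohort_order)
    n = longf.pivot_table(index="unit_id", columns="cohort_id", values="n",
                          aggfunc="first", sort=False).reindex(columns=cohort_order)
    all_missing = z.isna().all(axis=1)
    z = z.loc[~all_missing]
    # preserve the input unit order
    first_seen = longf.drop_duplicates("unit_id")["unit_id"]
    order = [u for u in first_seen if u in z.index]
    z = z.reindex(index=order)
    n = n.reindex(index=order)
    return _meta_from_wide(z, n, stage)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m!r}")
    return alpha / m


def gate_discovery(meta: pd.DataFrame, m: int, alpha: float = 0.05) -> set:
    """Units significant at the Bonferroni threshold alpha/m (strict <)."""
    if len(meta) == 0:
        return set()
    thr = bonferroni_threshold(alpha, m)
    return set(meta.loc[meta["p_meta"] < thr, "unit_id"])


def gate_replication(
    disc: pd.DataFrame,
    repl: pd.DataFrame,
    m_repl: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag units replicating: replication p below alpha/m_repl AND the
    replication z in the same direction as the discovery z.

    Units missing from either stage are not replicated. Returns a table
    ``unit_id, z_disc, z_repl, p_repl, replicated``.
    """
    thr = bonferroni_threshold(alpha, m_repl)
    d = disc.set_index("unit_id")
    r = repl.set_index("unit_id")
    units = d.index
    z_disc = d["z_meta"]
    z_repl = r["z_meta"].reindex(units)
    p_repl = r["p_meta"].reindex(units)
    replicated = (
        (p_repl < thr)
        & (np.sign(z_repl) == np.sign(z_disc))
        & z_repl.notna()
    )
    return pd.DataFrame(
        {
            "unit_id": units,
            "z_disc": z_disc.to_numpy(),
            "z_repl": z_repl.to_numpy(),
            "p_repl": p_repl.to_numpy(),
            "replicated": replicated.to_numpy(),
        }
    ).reset_index(drop=True)


def combine_stages(
    disc_stats: Iterable[pd.DataFrame],
    repl_stats: Iterable[pd.DataFrame],
    cohort_order: Sequence[str] | None = None,
    stat: str = "z",
) -> pd.DataFrame:
    """Stouffer meta-analysis over all discovery plus replication cohorts."""
    return stouffer_meta(
        list(disc_stats) + list(repl_stats),
        stage="combined",
        cohort_order=cohort_order,
        stat=stat,
    )
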