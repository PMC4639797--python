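"""End-to-end drivers tying the stages together.

The stage order mirrors the analysis the package implements: normalize and
filter expression, fit per-cohort age models, meta-analyse with
discovery/replication gating, test methylation mediation and feature
enrichment, build and validate the transcriptomic age predictor, and
associate delta age with phenotypes. ``run_pipeline`` executes all of it on
synthetic cohorts from a config and writes TSV outputs plus a JSON summary;
the intermediate drivers are importable pieces used by both the tests and
the command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, mediation, meta, predictor
from .preprocess import ExpressionMatrix, filter_expressed, residualize
from .synthetic import (
    CohortDataset,
    SimulationConfig,
    simulate_cohorts,
    simulate_methylation,
    simulate_phenotypes,
)

logger = logging.getLogger("txage")

__all__ = [
    "PipelineConfig",
    "standardize_cohorts",
    "age_association_stats",
    "run_prediction_study",
    "phenotype_meta",
    "run_mediation_study",
    "run_pipeline",
]

#: covariates regressed out of expression before association and prediction:
#: technical (plate, RNA quality) plus biological (sex, fasting, smoking,
#: cell counts); chronological age is never among them
RESIDUAL_COVARIATES = [
    "sex", "fasting", "smoking", "gran", "lymph", "mono", "ery", "plt",
    "plate", "rna_quality",
]

#: adjusters of the methylation~age model (model 1)
MODEL1_ADJUST = ["sex", "fasting", "smoking", "gran", "lymph", "mono", "ery", "plt"]

#: adjusters of the expression~methylation+age model (model 2)
MODEL2_ADJUST = MODEL1_ADJUST + ["plate", "rna_quality"]


@dataclass
class PipelineConfig:
    """Everything the full pipeline needs, loadable from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_discovery: int = 4          # leading cohorts form the discovery stage
    alpha: float = 0.05
    lambda_grid: Sequence[float] = tuple(predictor.DEFAULT_LAMBDA_GRID)
    calibration_cohort: str | None = None   # default: first cohort
    detection_p_thresh: float = 0.05
    detection_frac: float = 0.10
    min_cohorts: int = 2
    out_dir: str = "txage_out"
    seed: int | None = None       # overrides simulation.seed when set

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.seed is not None:
            self.simulation.seed = int(self.seed)
        if not 1 <= self.n_discovery < self.simulation.n_cohorts:
            raise ValueError(
                "n_discovery must leave at least one replication cohort"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def standardize_cohorts(
    cohorts: Sequence[CohortDataset],
    covariates: Sequence[str] = tuple(RESIDUAL_COVARIATES),
) -> dict[str, pd.DataFrame]:
    """Residual-standardized expression per cohort (gene-wise mean 0, s.d. 1)."""
    out = {}
    for c in cohorts:
        m = ExpressionMatrix(c.expression, scale_tag="qnorm_log2")
        out[c.cohort_id] = residualize(m, c.covariates, list(covariates)).values
    return out


def age_association_stats(
    cohorts: Sequence[CohortDataset],
    resid: dict[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Per-cohort age-model statistics on residual-standardized expression."""
    return {
        c.cohort_id: association.fit_age_model(
            resid[c.cohort_id], c.covariates, adjust=(), cohort_id=c.cohort_id
        )
        for c in cohorts
    }


def run_prediction_study(
    cohorts: Sequence[CohortDataset],
    resid: dict[str, pd.DataFrame] | None = None,
    stats: dict[str, pd.DataFrame] | None = None,
    lam: float | None = None,
    lambda_grid: Sequence[float] | None = None,
    calibration_cohort: str | None = None,
) -> dict:
    """Calibrate lambda on one cohort, then leave-one-out predict every cohort.

    The calibration cohort is excluded from the meta-analysis and from R
    while lambda is chosen; each cohort's prediction then comes from a model
    trained without that cohort. Returns a dict with the chosen ``lam``, the
    calibration ``trace``, and ``predictions`` mapping cohort id to
    :class:`~txage.predictor.AgePrediction`.
    """
    if resid is None:
        resid = standardize_cohorts(cohorts)
    if stats is None:
        stats = age_association_stats(cohorts, resid)
    ages = {c.cohort_id: c.covariates["age"] for c in cohorts}
    ids = [c.cohort_id for c in cohorts]
    if calibration_cohort is None:
        calibration_cohort = ids[0]
    if calibration_cohort not in ids:
        raise ValueError(f"calibration cohort {calibration_cohort!r} not found")

    trace = None
    if lam is None:
        train_ids = [c for c in ids if c != calibration_cohort]
        lam, trace = predictor.calibrate_lambda(
            [stats[c] for c in train_ids],
            [resid[c] for c in train_ids],
            resid[calibration_cohort],
            ages[calibration_cohort],
            grid=lambda_grid,
        )
    predictions = {
        cid: predictor.loo_predict(stats, resid, ages, cid, lam) for cid in ids
    }
    return {"lam": lam, "trace": trace, "predictions": predictions,
            "calibration_cohort": calibration_cohort}


def phenotype_meta(
    cohorts: Sequence[CohortDataset],
    predictions: dict[str, "predictor.AgePrediction"],
    bmi_adjust: bool = False,
) -> pd.DataFrame:
    """Meta-analysed delta-age ~ phenotype associations across cohorts."""
    tables = []
    for c in cohorts:
        if c.phenotypes is None:
            raise ValueError(f"{c.cohort_id}: phenotypes not generated")
        pred = predictions[c.cohort_id].table
        bmi = c.phenotypes["bmi"] if "bmi" in c.phenotypes.columns else None
        phenos = c.phenotypes.drop(columns=["bmi"]) if bmi_adjust and bmi is not None else c.phenotypes
        tables.append(
            association.fit_phenotype_model(
                phenos,
                pred["delta"],
                c.covariates["age"],
                bmi=bmi,
                bmi_adjust=bmi_adjust,
                cohort_id=c.cohort_id,
            )
        )
    return meta.stouffer_meta(tables, stage="combined")


def run_mediation_study(
    config: SimulationConfig,
    cohorts: Sequence[CohortDataset],
    genes: pd.DataFrame,
    cpgs: pd.DataFrame,
    target_genes: Sequence[str] | None = None,
    resid: dict[str, pd.DataFrame] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Sobel mediation analysis plus feature enrichment of mediating CpGs.

    Pairs CpGs with the target genes (default: the truly age-associated
    set) within the configured window, meta-analyses model 1 and model 2
    t-statistics across cohorts, Sobel-tests every pair with per-gene
    Bonferroni flagging, and tests mediator enrichment in each annotation
    class.
    """
    if target_genes is None:
        target_genes = genes.loc[genes["age_associated_truth"], "gene_id"]
    gsub = genes.loc[genes["gene_id"].isin(set(target_genes))]
    pairs = mediation.window_assign(cpgs, gsub, config.cpg_window_bp)
    if pairs.empty:
        empty = pd.DataFrame(
            columns=["cpg_id", "gene_id", "z1", "z2", "z_sobel", "p_sobel",
                     "mediator_flag"]
        )
        return {"pairs": pairs, "sobel": empty, "enrichment": {},
                "meta_model1": pd.DataFrame(), "meta_model2": pd.DataFrame()}
    if resid is None:
        resid = standardize_cohorts(cohorts)

    m1_tables, m2_tables = [], []
    for c in cohorts:
        if c.methylation is None:
            raise ValueError(f"{c.cohort_id}: methylation not generated")
        m1_tables.append(
            association.fit_model1(
                c.methylation, c.covariates, MODEL1_ADJUST, cohort_id=c.cohort_id
            )
        )
        m2_tables.append(
            association.fit_model2(
                resid[c.cohort_id], c.methylation, pairs, c.covariates,
                adjust=MODEL1_ADJUST, cohort_id=c.cohort_id,
            )
        )
    # weighted sum of t-statistics across cohorts for both models
    meta1 = meta.stouffer_meta(m1_tables, stage="combined", stat="t").set_index("unit_id")
    meta2 = meta.stouffer_meta(m2_tables, stage="combined", stat="t").set_index("unit_id")

    pair_ids = pairs["cpg_id"].astype(str) + "|" + pairs["gene_id"].astype(str)
    z1 = meta1["z_meta"].reindex(pairs["cpg_id"]).to_numpy()
    z2 = meta2["z_meta"].reindex(pair_ids).to_numpy()
    z_sobel, p_sobel = mediation.sobel_test(np.nan_to_num(z1), np.nan_to_num(z2))
    sobel = pd.DataFrame(
        {
            "cpg_id": pairs["cpg_id"].to_numpy(),
            "gene_id": pairs["gene_id"].to_numpy(),
            "z1": z1,
            "z2": z2,
            "z_sobel": z_sobel,
            "p_sobel": p_sobel,
        }
    )
    sobel = mediation.flag_mediators(sobel, alpha=alpha)

    # feature enrichment: mediating vs non-mediating CpGs near target genes
    ann = cpgs.set_index("cpg_id")
    per_cpg = sobel.groupby("cpg_id")["mediator_flag"].any()
    tested = ann.loc[per_cpg.index]
    enrich = {}
    for feature, col in [
        ("island", "island_class"),
        ("promoter", "chromhmm_class"),
        ("enhancer", "chromhmm_class"),
        ("insulator", "chromhmm_class"),
    ]:
        in_class = (tested[col] == feature).to_numpy()
        flags = per_cpg.to_numpy()
        enrich[feature] = mediation.enrichment_test(in_class[flags], in_class[~flags])
    return {"pairs": pairs, "sobel": sobel, "enrichment": enrich,
            "meta_model1": meta1.reset_index(), "meta_model2": meta2.reset_index()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic cohorts and write outputs + summary JSON.

    Stage order: simulate, detection filter, per-cohort age models,
    discovery meta-analysis and gating, replication gating, combined
    meta-analysis, mediation + enrichment, lambda calibration and
    leave-one-out prediction, delta-age phenotype associations. Outputs are
    TSV tables under ``config.out_dir`` plus ``summary.json``; deterministic
    under the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    logger.info("simulating %d cohorts", sim.n_cohorts)
    cohorts, genes = simulate_cohorts(sim)
    cpgs = simulate_methylation(sim, cohorts, genes)
    simulate_phenotypes(sim, cohorts)

    kept, filter_report = filter_expressed(
        {c.cohort_id: c.detection_p for c in cohorts},
        p_thresh=config.detection_p_thresh,
        frac=config.detection_frac,
        min_cohorts=config.min_cohorts,
    )
    filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    kept_cols = [g for g in genes["gene_id"] if g in kept]

    resid = standardize_cohorts(cohorts)
    resid = {cid: df.loc[:, kept_cols] for cid, df in resid.items()}
    stats = age_association_stats(cohorts, resid)

    ids = [c.cohort_id for c in cohorts]
    disc_ids, repl_ids = ids[: config.n_discovery], ids[config.n_discovery :]
    disc = meta.stouffer_meta([stats[c] for c in disc_ids], stage="discovery",
                              cohort_order=disc_ids)
    repl = meta.stouffer_meta([stats[c] for c in repl_ids], stage="replication",
                              cohort_order=repl_ids)
    m_disc = len(disc)
    sig = meta.gate_discovery(disc, m_disc, config.alpha)
    logger.info("discovery threshold %.3g (alpha/m, m=%d): %d significant",
                config.alpha / m_disc, m_disc, len(sig))
    disc_sig = disc.loc[disc["unit_id"].isin(sig)]
    repl_sig = repl.loc[repl["unit_id"].isin(sig)]
    m_repl = len(disc_sig)
    replication = (
        meta.gate_replication(disc_sig, repl_sig, m_repl, config.alpha)
        if m_repl
        else pd.DataFrame(columns=["unit_id", "z_disc", "z_repl", "p_repl", "replicated"])
    )
    replicated = set(replication.loc[replication["replicated"], "unit_id"])
    combined = meta.combine_stages(
        [stats[c] for c in disc_ids], [stats[c] for c in repl_ids],
        cohort_order=ids,
    )
    disc.to_csv(out / "meta_discovery.tsv", sep="\t", index=False)
    repl.to_csv(out / "meta_replication.tsv", sep="\t", index=False)
    combined.to_csv(out / "meta_combined.tsv", sep="\t", index=False)
    replication.to_csv(out / "replication_gate.tsv", sep="\t", index=False)

    med = run_mediation_study(
        sim, cohorts, genes, cpgs,
        target_genes=sorted(replicated),
        resid=resid, alpha=config.alpha,
    )
    med["sobel"].to_csv(out / "sobel.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"feature": k, "odds_ratio": v["odds_ratio"],
             "ci_low": v["ci95"][0], "ci_high": v["ci95"][1], "p": v["p"]}
            for k, v in med["enrichment"].items()
        ]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    pred = run_prediction_study(
        cohorts, resid=resid, stats=stats,
        lambda_grid=config.lambda_grid,
        calibration_cohort=config.calibration_cohort,
    )
    for cid, ap in pred["predictions"].items():
        ap.table.to_csv(out / f"prediction_{cid}.tsv", sep="\t")

    # general predictor from all cohorts except the calibration cohort
    calib = pred["calibration_cohort"]
    train_ids = [c for c in ids if c != calib]
    model = predictor.train_predictor(
        [stats[c] for c in train_ids], [resid[c] for c in train_ids], pred["lam"]
    )
    mu_age, sigma_age = predictor.pooled_age_sd(
        [cohorts[ids.index(c)].covariates["age"].mean() for c in train_ids],
        [cohorts[ids.index(c)].covariates["age"].std(ddof=1) for c in train_ids],
        [cohorts[ids.index(c)].n_samples for c in train_ids],
    )
    z_train = pd.concat(
        [resid[c] @ pd.Series(model.b_r, index=model.gene_ids) for c in train_ids]
    )
    predictor.export_general_predictor(
        model, out / "general_predictor.tsv", mu_age, sigma_age,
        float(z_train.mean()), float(z_train.std(ddof=1)),
    )

    pheno = phenotype_meta(cohorts, pred["predictions"])
    pheno.to_csv(out / "phenotype_meta.tsv", sep="\t", index=False)
    pheno_bmi = phenotype_meta(cohorts, pred["predictions"], bmi_adjust=True)
    pheno_bmi.to_csv(out / "phenotype_meta_bmi_adjusted.tsv", sep="\t", index=False)

    truth_age = set(genes.loc[genes["age_associated_truth"], "gene_id"])
    summary = {
        "seed": sim.seed,
        "n_cohorts": sim.n_cohorts,
        "n_genes_tested": m_disc,
        "discovery_threshold": config.alpha / m_disc,
        "n_discovery_significant": len(sig),
        "n_carried_to_replication": m_repl,
        "replication_threshold": config.alpha / m_repl if m_repl else None,
        "n_replicated": len(replicated),
        "replicated_true_positive": len(replicated & truth_age),
        "lambda": pred["lam"],
        "prediction_r": {
            cid: ap.r_with_age for cid, ap in pred["predictions"].items()
        },
        "mean_abs_delta_years": float(
            np.mean(
                [ap.table["delta"].abs().mean() for ap in pred["predictions"].values()]
            )
        ),
        "enrichment_or": {k: v["odds_ratio"] for k, v in med["enrichment"].items()},
        "phenotype_meta": {
            row.unit_id: {"z": row.z_meta, "p": row.p_meta,
                          "direction": row.direction_string}
            for row in pheno.itertuples()
        },
    }
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
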