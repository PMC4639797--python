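"""Multi-cohort synthetic data generator.

Emulates the statistical structure of a multi-cohort blood transcriptomics
study of ageing: per-cohort expression matrices in which a configurable
fraction of genes carries a linear age signal (both signs), covariate and
batch structure, CpG methylation that partially mediates the age effect for
a subset of genes, region annotations (CpG island/shore/shelf, chromatin
states), and phenotypes coupled to a per-individual latent ageing-rate
offset so that delta-age associations are recoverable downstream.

The key generative device is a latent "biological age" per sample:
``bio_age = chronological age + offset`` with ``offset ~ N(0, ageing_rate_sd)``.
Expression responds to biological age; the covariate table records only
chronological age. Phenotypes load on the same offset, which is what makes
an accurate transcriptomic age predictor informative about them beyond
chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "simulate_cohorts",
    "simulate_methylation",
    "simulate_phenotypes",
]

#: phenotypes generated by default, with the sign of their coupling to the
#: latent ageing offset (all positive: faster agers have higher values)
DEFAULT_PHENOTYPES = {
    "sbp": 1.0,
    "dbp": 1.0,
    "chol": 1.0,
    "hdl": 1.0,
    "glucose": 1.0,
    "bmi": 1.0,
}

# island / chromatin class frequencies for mediating vs non-mediating CpGs;
# mediators are planted preferentially in enhancers/insulators outside islands
_ISLAND_CLASSES = ("island", "shore", "shelf", "open_sea")
_CHROM_CLASSES = ("promoter", "enhancer", "insulator", "other")
_ISLAND_P_NULL = (0.35, 0.25, 0.10, 0.30)
_ISLAND_P_MEDIATOR = (0.08, 0.22, 0.15, 0.55)
_CHROM_P_NULL = (0.30, 0.15, 0.05, 0.50)
_CHROM_P_MEDIATOR = (0.10, 0.45, 0.15, 0.30)


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n_cohorts:
        Number of independent cohorts.
    n_per_cohort:
        Samples per cohort; a single int is broadcast to all cohorts.
    n_genes:
        Genes measured in every cohort.
    frac_age_genes:
        Fraction of genes with a true linear age effect (random sign).
    age_effect_sd:
        Magnitude of the age effect for age genes, in expression s.d.
        per s.d. of (biological) age.
    frac_mediated:
        Fraction of age genes whose age effect is partially routed through
        the methylation of one of their CpGs.
    mediation_strength:
        Fraction in [0, 1] of the age effect carried by the mediator.
    mediator_age_corr:
        Correlation between the mediator latent and standardized biological
        age; controls the strength of the methylation~age association.
    n_cpg_per_gene:
        CpG sites placed in each gene's window.
    cpg_window_bp:
        Half-width in bp of the window around a gene within which its CpGs
        are placed (and within which CpG-gene pairs are formed downstream).
    noise_sd:
        Residual expression s.d.
    ageing_rate_sd:
        S.d. in years of the latent per-sample ageing offset.
    phenotype_coupling:
        Phenotype s.d. per year of latent ageing offset.
    age_range:
        (min, max) of the uniform chronological age distribution, years.
    frac_unexpressed:
        Fraction of genes flagged unexpressed per cohort (detection p-values
        uniform on [0, 1] instead of concentrated below 0.05).
    overlapping_windows:
        If True, genes are packed densely enough that CpG windows overlap,
        exercising multi-gene CpG assignment.
    seed:
        Seed for all randomness.
    """

    n_cohorts: int = 6
    n_per_cohort: Sequence[int] | int = 500
    n_genes: int = 1000
    frac_age_genes: float = 0.2
    age_effect_sd: float = 0.3
    frac_mediated: float = 0.7
    mediation_strength: float = 0.5
    mediator_age_corr: float = 0.6
    n_cpg_per_gene: int = 5
    cpg_window_bp: int = 250_000
    noise_sd: float = 1.0
    ageing_rate_sd: float = 5.0
    phenotype_coupling: float = 0.5
    age_range: tuple[float, float] = (20.0, 80.0)
    frac_unexpressed: float = 0.0
    include_covariate_effects: bool = True
    phenotype_signs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES)
    )
    overlapping_windows: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "frac_age_genes",
            "frac_mediated",
            "mediation_strength",
            "mediator_age_corr",
            "frac_unexpressed",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("n_cohorts", "n_genes", "n_cpg_per_gene", "cpg_window_bp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if isinstance(self.n_per_cohort, (int, np.integer)):
            self.n_per_cohort = [int(self.n_per_cohort)] * self.n_cohorts
        else:
            self.n_per_cohort = [int(n) for n in self.n_per_cohort]
        if len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError(
                "n_per_cohort length "
                f"{len(self.n_per_cohort)} != n_cohorts {self.n_cohorts}"
            )
        if any(n <= 0 for n in self.n_per_cohort):
            raise ValueError(f"n_per_cohort entries must be positive: {self.n_per_cohort}")
        for name in ("age_effect_sd", "noise_sd", "ageing_rate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must satisfy min < max, got {self.age_range}")


@dataclass
class CohortDataset:
    """One cohort's data plus the generative truth used to score recovery."""

    cohort_id: str
    expression: pd.DataFrame        # samples x genes, log2-intensity scale
    detection_p: pd.DataFrame       # samples x genes in [0, 1]
    covariates: pd.DataFrame        # samples x covariate columns
    methylation: pd.DataFrame | None = None   # samples x CpGs, beta-values
    phenotypes: pd.DataFrame | None = None    # samples x phenotype columns
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]


def _bio_age_sd(config: SimulationConfig) -> float:
    lo, hi = config.age_range
    return float(np.sqrt((hi - lo) ** 2 / 12.0 + config.ageing_rate_sd**2))


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[CohortDataset], pd.DataFrame]:
    """Generate expression, covariates and gene annotation for all cohorts.

    Returns the cohort list and a gene annotation table with columns
    ``gene_id, chrom, start, end, length_bp, mean_expression,
    age_associated_truth, mediated_truth, beta_true`` (``beta_true`` is the
    realized marginal slope of standardized expression on standardized
    biological age).

    Deterministic under ``config.seed``: the same config yields byte-identical
    outputs.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_cohorts = root.spawn(2)
    rng = np.random.default_rng(ss_genes)

    g = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(g)])

    # gene architecture: which genes respond to age, which are mediated
    n_age = int(round(config.frac_age_genes * g))
    age_idx = rng.choice(g, size=n_age, replace=False)
    age_mask = np.zeros(g, dtype=bool)
    age_mask[age_idx] = True
    signs = rng.choice([-1.0, 1.0], size=g)
    beta = np.where(age_mask, signs * config.age_effect_sd, 0.0)

    n_med = int(round(config.frac_mediated * n_age))
    med_idx = rng.choice(age_idx, size=n_med, replace=False) if n_age else np.array([], int)
    med_mask = np.zeros(g, dtype=bool)
    med_mask[med_idx] = True

    # coordinates on one synthetic chromosome; by default genes are spaced so
    # that the +/- window regions never overlap
    length_bp = np.exp(rng.normal(np.log(20_000), 0.8, size=g)).astype(np.int64) + 200
    gap = 1_000 if config.overlapping_windows else 2 * config.cpg_window_bp + 1_000
    starts = np.concatenate([[config.cpg_window_bp], np.cumsum(length_bp[:-1] + gap) + config.cpg_window_bp])
    ends = starts + length_bp
    mu_expr = rng.normal(8.0, 1.5, size=g)

    # effective marginal slope for mediated genes (part of the effect flows
    # through the mediator latent, which is only partially age-correlated)
    ms, a = config.mediation_strength, config.mediator_age_corr
    sd_g = np.sqrt((1 - ms) ** 2 + ms**2 + 2 * ms * (1 - ms) * a)
    slope_mediated = ((1 - ms) + ms * a) / sd_g if sd_g > 0 else 0.0
    beta_marginal = np.where(med_mask, beta * slope_mediated, beta)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chrS",
            "start": starts,
            "end": ends,
            "length_bp": length_bp,
            "mean_expression": mu_expr,
            "age_associated_truth": age_mask,
            "mediated_truth": med_mask,
            "beta_true": beta_marginal,
        }
    )

    sd_bio = _bio_age_sd(config)
    lo, hi = config.age_range
    mid = (lo + hi) / 2.0

    cohorts: list[CohortDataset] = []
    for c, (n, ss) in enumerate(zip(config.n_per_cohort, ss_cohorts.spawn(config.n_cohorts))):
        crng = np.random.default_rng(ss)
        cid = f"cohort{c:02d}"
        sample_ids = [f"{cid}_s{i:04d}" for i in range(n)]

        age = np.round(crng.uniform(lo, hi, size=n), 2)
        offset = crng.normal(0.0, config.ageing_rate_sd, size=n)
        z_bio = (age + offset - mid) / sd_bio

        # mediator latent per mediated gene: corr(m, z_bio) = mediator_age_corr
        m_lat = a * z_bio[:, None] + np.sqrt(1 - a**2) * crng.standard_normal((n, n_med))

        # age pathway per gene: direct, or split between direct and mediator
        pathway = np.tile(z_bio[:, None], (1, g))
        if n_med and sd_g > 0:
            pathway[:, med_mask] = ((1 - ms) * z_bio[:, None] + ms * m_lat) / sd_g

        sex = crng.integers(0, 2, size=n).astype(float)
        fasting = crng.integers(0, 2, size=n).astype(float)
        smoking = (crng.random(n) < 0.25).astype(float)
        cells = np.abs(crng.normal(loc=[4.0, 2.0, 0.5, 4.5, 250.0], scale=[1.0, 0.5, 0.15, 0.5, 50.0], size=(n, 5)))
        n_plates = max(2, n // 96)
        plate_idx = crng.integers(0, n_plates, size=n)
        rna_quality = np.clip(crng.normal(8.5, 0.8, size=n), 4.0, 10.0)

        expr = mu_expr[None, :] + beta[None, :] * pathway
        if config.include_covariate_effects:
            sex_load = crng.normal(0.0, 0.15, size=g)
            rq_load = crng.normal(0.0, 0.10, size=g)
            plate_eff = crng.normal(0.0, 0.15, size=(n_plates, g))
            expr = expr + sex[:, None] * sex_load[None, :]
            expr = expr + ((rna_quality - 8.5) / 0.8)[:, None] * rq_load[None, :]
            expr = expr + plate_eff[plate_idx, :]
        expr = expr + crng.normal(0.0, config.noise_sd, size=(n, g))

        det = crng.uniform(0.0, 0.04, size=(n, g))
        if config.frac_unexpressed > 0:
            n_unexpr = int(round(config.frac_unexpressed * g))
            unexpr = crng.choice(g, size=n_unexpr, replace=False)
            det[:, unexpr] = crng.uniform(0.0, 1.0, size=(n, n_unexpr))

        covariates = pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "fasting": fasting,
                "smoking": smoking,
                "gran": cells[:, 0],
                "lymph": cells[:, 1],
                "mono": cells[:, 2],
                "ery": cells[:, 3],
                "plt": cells[:, 4],
                "plate": [f"P{j:02d}" for j in plate_idx],
                "rna_quality": rna_quality,
            },
            index=sample_ids,
        )
        truth = {
            "offset": pd.Series(offset, index=sample_ids, name="offset"),
            "mediator_latent": pd.DataFrame(m_lat, index=sample_ids, columns=gene_ids[med_mask]),
        }
        cohorts.append(
            CohortDataset(
                cohort_id=cid,
                expression=pd.DataFrame(expr, index=sample_ids, columns=gene_ids),
                detection_p=pd.DataFrame(det, index=sample_ids, columns=gene_ids),
                covariates=covariates,
                truth=truth,
            )
        )
    return cohorts, genes


def simulate_methylation(
    config: SimulationConfig,
    cohorts: list[CohortDataset],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Place CpGs in gene windows and fill per-cohort methylation matrices.

    For each mediated gene, its first CpG is the mediator: its logit-scale
    methylation tracks the mediator latent that already feeds that gene's
    expression, so methylation carries the mediated share of the age effect.
    All other CpGs get age- and expression-independent beta-values.

    Returns a CpG annotation table (``cpg_id, chrom, pos, gene_id,
    island_class, chromhmm_class, excluded, is_mediator_truth``) and sets
    ``cohort.methylation`` in place. Beta-values are always inside [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    k = config.n_cpg_per_gene
    w = config.cpg_window_bp

    rows = []
    for _, gr in genes.iterrows():
        lo = max(0, int(gr.start) - w)
        hi = int(gr.end) + w
        pos = np.sort(rng.integers(lo, hi, size=k))
        mediated = bool(gr.mediated_truth)
        for j in range(k):
            is_med = mediated and j == 0
            ip = _ISLAND_P_MEDIATOR if is_med else _ISLAND_P_NULL
            cp = _CHROM_P_MEDIATOR if is_med else _CHROM_P_NULL
            rows.append(
                {
                    "cpg_id": f"cg_{gr.gene_id}_{j}",
                    "chrom": gr.chrom,
                    "pos": int(pos[j]),
                    "gene_id": gr.gene_id,
                    "island_class": _ISLAND_CLASSES[rng.choice(4, p=ip)],
                    "chromhmm_class": _CHROM_CLASSES[rng.choice(4, p=cp)],
                    "excluded": False,
                    "is_mediator_truth": is_med,
                }
            )
    cpgs = pd.DataFrame(rows)

    base_logit = rng.normal(0.0, 1.0, size=len(cpgs))
    med_rows = cpgs.index[cpgs.is_mediator_truth].to_numpy()
    med_gene_of_row = cpgs.loc[med_rows, "gene_id"].to_numpy()

    for cohort, ss in zip(
        cohorts, np.random.SeedSequence([config.seed, 2]).spawn(len(cohorts))
    ):
        crng = np.random.default_rng(ss)
        n = cohort.n_samples
        logit = base_logit[None, :] + crng.normal(0.0, 0.35, size=(n, len(cpgs)))
        m_lat = cohort.truth["mediator_latent"]
        if len(med_rows):
            # mediator CpG logit follows the gene's mediator latent plus a
            # small measurement noise; 0.5 logit units per latent s.d.
            sig = m_lat.loc[:, med_gene_of_row].to_numpy()
            logit[:, med_rows] = (
                base_logit[None, med_rows]
                + 0.5 * sig
                + crng.normal(0.0, 0.1, size=(n, len(med_rows)))
            )
        beta = 1.0 / (1.0 + np.exp(-logit))
        cohort.methylation = pd.DataFrame(
            np.clip(beta, 0.0, 1.0),
            index=cohort.expression.index,
            columns=cpgs.cpg_id.to_numpy(),
        )
    return cpgs


def simulate_phenotypes(
    config: SimulationConfig,
    cohorts: list[CohortDataset],
) -> None:
    """Fill per-cohort phenotype tables.

    Each phenotype is ``slope_age * age + sign * coupling * offset + e`` with
    unit-variance noise, where ``offset`` is the latent ageing offset in
    years. With ``phenotype_coupling = 0`` phenotypes are independent of the
    offset given age.
    """
    config.validate()
    for cohort, ss in zip(
        cohorts, np.random.SeedSequence([config.seed, 3]).spawn(len(cohorts))
    ):
        crng = np.random.default_rng(ss)
        n = cohort.n_samples
        age = cohort.covariates["age"].to_numpy()
        offset = cohort.truth["offset"].to_numpy()
        data = {}
        for name, sign in config.phenotype_signs.items():
            data[name] = (
                0.03 * age
                + sign * config.phenotype_coupling * offset
                + crng.normal(0.0, 1.0, size=n)
            )
        cohort.phenotypes = pd.DataFrame(data, index=cohort.expression.index)
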