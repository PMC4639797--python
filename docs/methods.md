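# Methods

`txage` implements a multi-cohort analysis of age-associated blood gene
expression: per-cohort linear association models, sample-size-weighted
meta-analysis with discovery/replication gating, a Sobel-test screen for
methylation-mediated age effects with feature-enrichment analysis, and a
transcriptomic age predictor built from meta-analysis summary statistics by
approximate ridge regression. Because the consortium data such a study rests
on cannot be redistributed, the package ships a synthetic multi-cohort
generator with the statistical structure the analysis assumes; every stage
is exercised and validated against that generator.

## Generative model

Each of `n_cohorts` cohorts draws chronological age uniformly on
`age_range` (recorded to two decimals, as study phenotype files typically
do) and a latent per-sample ageing offset `u ~ N(0, ageing_rate_sd)` in
years. **Biological age** `a* = age + u` drives expression; the covariate
table records only chronological age. This latent offset is the device that
makes delta-age (predicted minus chronological age) informative: phenotypes
load on the same offset, so an accurate expression-based age predictor
carries signal about them beyond chronological age. Real studies motivate
this construct but do not observe it; it is a modeling choice, and the
truth tables expose it so tests can score recovery exactly.

Expression for gene *g* is

    x_g = mu_g + beta_g * path_g(a*) + covariate effects + N(0, noise_sd)

on a log2-intensity-like scale (`mu_g ~ N(8, 1.5)`). A fraction
`frac_age_genes` of genes receives `|beta_g| = age_effect_sd` (expression
s.d. per s.d. of biological age) with random sign; the rest have zero age
effect. Covariate structure (sex and RNA-quality loadings, plate batch
shifts of s.d. 0.15, one plate per ~96 samples) is small relative to the
noise but non-ignorable, so residualization is doing real work.

For a fraction `frac_mediated` of age genes the age pathway is split
through a mediator latent `m = a*z + sqrt(1-a^2)*e` with
`a = mediator_age_corr` (default 0.6): the pathway becomes
`((1-s)*z_a + s*m)/sd`, `s = mediation_strength`. The gene's designated
mediator CpG tracks `m` on the logit scale (0.5 logit units per latent
s.d., plus small measurement noise) and is inverse-logit transformed, so
beta-values always lie in [0, 1] while the age-linear signal is
approximately preserved — the generation happens on the logit scale even
though the analysis models beta-values directly, a deliberate asymmetry
that keeps the range constraint without distorting moderate effects.
Non-mediating CpGs are age- and expression-independent given age.
Mediating CpGs are planted preferentially in enhancer/insulator,
non-island annotation classes (8% island, 45% enhancer versus 35% and 15%
for null CpGs), which is what the enrichment stage is expected to recover
qualitatively (odds ratios above 1 for enhancers/insulators, below 1 for
islands/promoters).

Phenotypes are `0.03*age + sign * phenotype_coupling * u + N(0,1)`, with
`phenotype_coupling` in phenotype s.d. per year of offset (default 0.5) and
per-phenotype signs configurable.

Defaults are a desk-scale study: 6 cohorts x 500 samples, 1,000 genes
(20% age-associated at 0.3 s.d./s.d., 70% of those mediated at strength
0.5), 5 CpGs per gene, window 250 kb, ages 20-80, offset s.d. 5 years.
Genes sit on one synthetic chromosome spaced so CpG windows do not overlap
(an `overlapping_windows` mode packs them to exercise multi-gene CpG
assignment). No published effect-size distribution exists for this setting;
the defaults were chosen once for testability — strong enough that a
six-cohort study has near-complete power — and the tests interpret results
under exactly these conditions.

What the generator does **not** emulate: probe-level artifacts
(cross-hybridization, dye bias), realistic spatial correlation of
methylation beyond the within-gene mediator structure, population
stratification, or non-linear age trends. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
linear-Gaussian conditions, not robustness to microarray pathology.

## Preprocessing

Quantile normalization maps every sample's order statistics to the
across-sample median distribution (ties share the mean of their target
values), then log2. Probe and sample means are centered by alternating
row/column sweeps to |mean| < 1e-10 (one sweep is exact for plain
centering; the loop guards pathological inputs, capped at 100 iterations).
The detection filter keeps genes with detection p < 0.05 in strictly more
than 10% of all discovery samples and measured in at least two cohorts.
Residualization regresses each gene on the technical and biological
covariates (never age), expanding factors to first-level-reference
indicators, and divides residuals by their n-1 s.d.; samples with missing
covariates are dropped from the affected fits. Whether residual
standardization should happen per cohort or after pooling is not fixed by
convention; it is done per cohort here, which also makes cohorts
exchangeable for the leave-one-out design.

## Association models and meta-analysis

All models are OLS. The age model regresses standardized expression on
chronological age; model 1 regresses methylation beta-values on age;
model 2 regresses expression on methylation and age jointly (methylation
coefficient reported), computed by partialling the shared base design out
of both sides — algebraically identical to the full fit but one QR
decomposition per cohort instead of one per pair. t-statistics map to
z-scores through the standard-normal quantile of the t tail probability,
tail-wise to preserve sign, in log space so |t| up to hundreds does not
overflow; p-values are floored at 1e-300, and a perfect fit (zero residual
s.e. with nonzero effect) reports the floor rather than NaN. Constant
outcomes are flagged (`?` direction) rather than fit.

Meta-analysis combines per-cohort statistics as `sum(w_i z_i)` with
`w_i = sqrt(n_i)/sqrt(sum n_j)` (squared weights sum to 1). The expression
stages combine z-scores; the methylation models combine t-statistics, the
convention of the weighted-sum-of-t workflow they mirror. Cohorts missing
a unit appear as `?` in the direction string and drop out of the weights.
Discovery significance uses alpha/m with m the number of genes actually
tested in the run; replication requires p below alpha/(number carried
forward) **and** an unchanged meta z sign; the combined stage re-runs the
meta-analysis over all cohorts. Both m values are always computed from the
data, never hard-coded.

The phenotype model regresses each phenotype on delta age adjusted for
chronological age (optionally BMI), after excluding values more than 4
raw-MADs from the median — a deliberately simple, reproducible outlier
rule, logged via an `n_outliers` column.

## Mediation and enrichment

CpG-gene pairs form within `[start - w, end + w)` (w = 250 kb, closed
lower bound, half-open upper, 0-based). The Sobel statistic is
`Z1*Z2/sqrt(Z1^2+Z2^2)` (defined 0 at the origin), two-sided normal
p-value, flagged per gene at alpha divided by the CpGs tested in that gene.
The identity |Z_sobel| <= min(|Z1|, |Z2|) makes the test conservative under
the null; the acceptance suite documents a null flag rate far below
nominal.

Control genes are matched one-to-one to targets on standardized (log gene
length, log-scale mean expression) by greedy globally-nearest assignment
plus a pairwise swap-refinement pass — a dependency-free stand-in for
optimal matching whose contract is the balance postcondition (two-sample
KS p > 0.01 on both covariates under default configurations) rather than
the algorithm. Island/shore/shelf classification measures gap distance to
the nearest island with the shore boundary closed at exactly 1,500 bp
toward the island (and shelf at 3,000 bp). Enrichment uses Fisher's exact
test with a sample odds ratio and Woolf CI, Haldane-Anscombe 0.5 correction
on zero margins, and an alpha-grid sweep (1e-20 to 0.05) for robustness.

## The transcriptomic age predictor

Marginal effects on the standardized scale come from the meta-analysis via
`b = z/sqrt(z^2 + n - 2)` — the identity between a simple-regression test
statistic and its correlation-scale slope, verified by a round-trip oracle
test. Joint effects solve

    ((n_eff - 1) R + lambda I) b_R = (n_eff - 1) b

by Cholesky (never explicit inversion), where R is the sample-size-weighted
average of per-cohort gene correlation matrices with the diagonal reset to
1 and `n_eff` is the sample-size-weighted mean of the contributing cohort
sizes (a pooling convention the summary-statistic literature leaves open;
any single-cohort case reduces to the exact identity, which the oracle test
pins at 1e-8 against explicit individual-level ridge). Off-diagonal R is
not shrunk beyond the ridge itself; lambda > 0 guarantees solvability.

lambda is chosen on a designated calibration cohort — excluded from both
the meta-analysis and R — as the grid argmax of Pearson r(predicted age,
age), ties to the smallest value; the default grid is 25 log-spaced points
on [1, 1e6]. Under the default configuration the argmax typically sits at
the heavy-shrinkage end, which is expected when p (1,000 genes) is large
relative to the per-cohort n in R and shrinkage mostly rescales the
predictor (correlation is scale-free).

Leave-one-out validation retrains the meta-analysis and R without each
target cohort, scores the target as `Z_j = sum_i b_R[i] x_ij`, and rescales
`SZ = (Z - mu_z)/sigma_z * sigma_age + mu_age` using the target cohort's
own age moments and its own predictor moments, so mean(SZ) and sd(SZ) equal
the cohort's age mean/s.d. to machine precision; delta age is SZ minus
chronological age. Genes absent from a validation cohort are dropped from
the weighted sum without renormalization (the weights are a fixed formula),
with a hard failure below 90% gene overlap; a mean-imputation flag is
deliberately not the default. The exported general predictor (trained on
all cohorts except the calibration one) carries mu/sigma constants computed
from the pooled training cohorts — ages via the pooled-variance method
(within- plus between-cohort components, exactly the moments of the
concatenated samples), predictor moments from the pooled training
predictions — so external cohorts without age data can still be scored.

## Problem sizes and numerical choices

The test and acceptance workloads use the default 6x500x1,000 configuration
for prediction (20 seeds), a 4x250x300 configuration for the enrichment
replicates, 5x300x10,000 for meta-analysis null calibration, and 10,000
pairs for the Sobel null — sizes chosen so the full suite completes in a
few minutes on one core while keeping Monte-Carlo error well inside the
asserted bounds. Determinism comes from a single seed fanned out through
`numpy.random.SeedSequence` spawning; regenerating with the same config is
bit-identical. Tolerances: exact identities at 1e-10 to 1e-12, the ridge
oracle at 1e-8, calibration bands (type-I error, variance) at the width
implied by the simulation sizes.

## Known limitations

- The generator's linear-Gaussian expression model cannot probe robustness
  to heavy tails, batch-confounded age distributions, or platform mixtures
  (the Affymetrix-style arm of a real study is out of scope).
- Model 1/model 2 adjusters include methylation-chip structure only insofar
  as the generator simulates it (it does not simulate chip/row effects).
- The matching algorithm is near-optimal, not optimal; its balance contract
  is asserted, not its optimality.
- A single mediator CpG per gene is generated; the analysis handles many
  per gene, but power statements in the tests reflect the one-mediator
  design.
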