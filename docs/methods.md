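# Methods

This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Data model and effective coverage

Pooled sequencing observes, at each SNP and sample, an alt-read fraction
whose precision is limited by two binomial layers: sampling `n_chrs` pooled
chromosomes from the population, then sampling `n_reads` reads from the
pool. The effective number of independent chromosomes,
`N_eff = (n_reads·n_chrs − 1)/(n_reads + n_chrs)`, is symmetric in the two
layers, is bounded above by both, and is used as (i) the per-sample quality
filter (default mean N_eff ≥ 28, strict inequality drops the sample), and
(ii) the binomial prior weight in every GLM. The MAF filter (default 1%)
acts on the across-sample mean of the folded frequency; folding is a
package choice where the convention was ambiguous.

## Pool FST

The two-sample estimator is the method-of-moments ANOVA form with N_eff as
the per-sample chromosome count: per SNP, `FST = (MSP − MSG)/(MSP +
(n_c − 1)·MSG)`; the genome-wide value is ratio-of-sums, and negative
per-SNP estimates are retained so the aggregate stays unbiased. Two
consequences worth knowing:

* literally duplicated samples give exactly `−1/(n_c − 1)`, not 0 — the
  estimator subtracts expected sampling variance that never occurred;
* for two samples of one population taken t generations apart, the
  expectation is `t/(4N)` (the between-sample component is half the squared
  frequency difference), not the `t/(2N)` of unhalved temporal-F
  statistics. Tests assert the `t/(4N)` form, which is exact for this
  estimator.

## Boom–bust simulator and ABC

The simulator is deliberately linkage-free: unlinked biallelic loci,
initial frequencies from a truncated neutral 1/x spectrum (lower bound
1/(2N_Max)), binomial resampling of 2N copies per generation, census N_Max
everywhere except the bottleneck generations (defaults 17–18 and 34–35 of
50, i.e. two overwinters in three seasons). None of the five ABC summaries
uses linkage, so this preserves the inference target at a small fraction of
the cost of a chromosome-scale forward simulation; it is the one deliberate
deviation from a full sequence simulator and is invisible to the summaries.

Pool-seq emulation draws 2·pool_n chromosomes binomially (default pool_n =
50 diploids) and then reads at Poisson(60) depth. Summaries: all pairwise
pool-FST split into within-year and between-year medians, plus R² of PC1,
LD1, LD2 against year (DAPC with year prior). Year labels follow the
inter-bottleneck epochs; five evenly spaced samples per year by default.

ABC follows the rejection + local-linear-regression recipe: summaries are
z-scored over the simulation table, the closest `tolerance` fraction
(default 5%) by Euclidean distance is accepted with Epanechnikov weights,
and log-parameters are regression-adjusted to the observed summary vector.
The adjustment includes the standard heteroscedasticity correction —
residuals rescaled by a locally fitted residual SD — because the raw
local-linear adjustment measurably under-covers here: the map from (log
N_Min) to FST-type summaries saturates for weak bottlenecks, so residual
spread varies strongly across the accepted cloud. The prior is log-uniform
(N_Max ∈ [10³, 10⁵], N_Min ∈ [10, 10⁴]) with N_Min ≤ N_Max enforced by
rejection and re-imposed on adjusted draws. Derived N_e is the harmonic
mean of the census schedule. The package's coverage experiment uses 2,000
prior draws, 600 loci and 5 samples/year per simulated dataset — sizes
chosen so the five summaries are informative enough for the regression to
be locally linear; smaller simulated datasets leave N_Min posteriors biased
toward the weak-bottleneck plateau.

## Environmental covariates and the GLM battery

Covariates are daily-weather summaries over day-windows `[a, b]` before
each sample's collection date (inclusive). The ten summaries: temperature
mean and variance (of the daily midpoint), max of daily maxima, min of
daily minima, proportion of days with tmax > 32 °C and with tmin < 5 °C;
precipitation mean/variance; relative-humidity mean/variance. The eleven
default windows are {0–7, 0–15, 7–15, 0–30, 15–30, 0–45, 0–60, 30–60,
0–75, 45–90, 0–90} days: the endpoints and the named interior windows are
fixed design points, the rest fill the grid and are configurable. Variance
is the sample variance. 10 × 11 = 110 covariates; with the null and time
models this is 112 models per SNP per region.

The response is the observed frequency with prior weight N_eff (quasi-count
formulation) — deterministic and free of rounding bias at low N_eff; AIC
and LRT use the binomial log-likelihood kernel (constants cancel within a
SNP). The year factor uses treatment coding with the earliest level as
reference (coding cannot affect AIC/LRT); covariates are standardized per
sample set (sign of β₂ is preserved). Fitting is IRLS with at most 50
iterations and relative deviance tolerance 1e-8, batched across SNPs via a
stacked small-matrix solve with a 1e-9 ridge for degenerate designs;
monomorphic SNPs are skipped and non-converged fits are excluded from
best-model tallies. Ties in AIC go to fewer parameters, then lexicographic
model id.

Permutations reorder per-sample labels once and apply that ordering to all
SNPs, preserving linkage: environment-kind shuffles covariate rows while
keeping the real time term, year-kind shuffles the time factor. The
relative rate per model and genome partition is `rr_n = log₂(N_real /
N_perm,n)` with population-SD over permutations; a zero count on either
side gets a 0.5 pseudo-count on both terms and a flag.

Calibration caveat: the covariate LRT is uniform under the null generator
(no planted effects) on a common-SNP panel. For SNPs that *do* carry a real
environmental effect, permuting the covariate does not remove the
within-year frequency variance that effect created, so permuted P-values at
causal SNPs are anticonservative in isolation — which is exactly why
enrichment is judged on best-model counts against the permuted batteries,
not on per-SNP permutation P-values.

## Window scans

P-values are rank-normalized to the exact uniform grid {1/L, …, 1} with
ties broken by genomic position. Windows are 0.1 Mb at 50 kb step, starting
at coordinate 0, 0-based half-open internally. The signal-enrichment test
counts genome-wide top-5% members per window against an exact binomial tail
at success probability 0.05. WZA is `Z = Σwᵢzᵢ/√(Σwᵢ²)` with
`zᵢ = Φ⁻¹(1 − pᵢ)` and default weights p̄q̄ from the mean allele frequency
(equal weights supported; outputs record which was used); p ∈ {0, 1} is
clamped to [1/(10L), 1 − 1/(10L)] and flagged. Empirical per-window
critical values take the upper 1% of permutation scores (the per-window
maximum, with a warning, below 20 permutations). Windows of interest are
peak-centered ±0.2 Mb intervals from contiguous significant runs, merged
when overlapping.

## Karyotyping and haplotype tracking

Marker selection keeps SNPs with dosage-r² to the 0/1 karyotype (over
labeled homozygotes) above 0.99, canonically ordered by position so
floating-point reductions are input-order invariant, then ranks by mean
mutual r² (> 0.8) and keeps the top 47 by default. The PCA-loading
pre-filter used in marker pipelines is folded into the karyotype-r²
criterion — on labeled homozygotes the two select the same loci. The
linear SVM is trained on homozygotes only; the HET band is the midpoint of
the two classes' mean training scores ± a quarter of the inter-class gap,
so a fully heterozygous marker vector lands between the homozygote score
clouds. Hyperparameters (C = 1) and the three-class margin rule are package
choices where the upstream procedure was silent.

Anchor sets apply BH-FDR within the window's tested SNPs (q < 0.05),
expand by partners at r² > 0.6 within ±0.2 Mb, and polarize each locus so
the tracked allele is the one positively correlated with the inverted
karyotype; the haplotype trajectory is the unweighted mean of polarized
frequencies, regressed on a covariate by OLS (undefined and flagged for
constant covariates or < 3 samples).

## Population-genetic statistics

π is reported as the per-window sum of mean pairwise differences (windowed
--window-pi convention; divide by accessible sites for per-site values).
Tajima's D uses the standard a₁/a₂/b/c/e constants and is undefined at
S = 0 (and degenerate at n = 3, where the variance constants vanish).
Karyotype FST is the Weir–Cockerham (1984) two-population estimator on
diploid dosages (a, b, c components; ratio-of-sums per window; HET
excluded). Pairwise LD is mean r² over SNP pairs per 50 kb window at 10 kb
step, with a composite-LD (dosage-correlation) fallback for unphased input
flagged in the output. Matched controls are sampled uniformly without
replacement from off-chromosome SNPs within ±0.20 cM/Mb and ±0.030 global
AF; the tolerance contract is re-asserted on every emitted control.

## Cross-model statistics

Top-5% sets are formed within each analysis' own tested SNP universe (the
per-analysis ranking convention) before intersecting; an
intersection-universe mode exists. Enrichment uses a one-sided Fisher exact
test (two-sided available), the sample odds ratio with Haldane 0.5
correction on zero cells, and Woolf log-OR confidence intervals.
Directionality is the percentage of jointly significant SNPs (both β ≠ 0)
with agreeing coefficient signs; 50% is the null, 100% and 0% both indicate
block-like coordinated change. The GWAS × GLM window scan Bonferroni-
corrects within the whole window × phenotype family and flags windows whose
significant-phenotype count exceeds the 95th-largest count across permuted
GLM scans. The inversion–phenotype test is the linear model trait ~
karyotype (equal-variance t-test, vectorized across traits) with
1,000 label-shuffling permutations of the significant-trait count by
default.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analyses assume:
multi-year biweekly sampling, boom–bust latent drift, a single
inversion-like haplotype whose logit frequency responds linearly to one
named weather covariate (block SNPs mix the haplotype frequency with their
own background at weight r_block = 0.9, giving tunable block LD), two-stage
pool-seq noise at stated coverages, seasonal weather with AR(1) noise, and
GWAS summaries with a planted overlap fraction. Defaults: N_Max = 20,000
and N_Min = 300 (the scale of the demographic estimates this kind of study
produces), pool of 100 chromosomes at mean coverage 60, effect size 1
logit/SD of the covariate, and an initial *common-SNP* spectrum (uniform
folded frequencies, as in a MAF-filtered analysis panel; the simulator's
1/x spectrum is available as `init_spectrum="neutral"`).

It does not simulate reads or mapping error, diploid selection, migration,
recombination within the block (the block is a single latent frequency plus
per-SNP background), or spatial structure. Passing tests therefore show the
statistics behave correctly under the assumed noise model — they do not
show robustness to mapping artifacts, unmodeled substructure, or violations
of the binomial observation model.

## Problem sizes used in tests

The test and acceptance runs use desk-scale versions of the study design:
hundreds to a few thousand SNPs, 18–24 pooled samples, 5–10 permutations
for enrichment checks (100 remains the analysis default), and a
2,000-simulation ABC table. These sizes were chosen as the smallest at
which each statistical property is clearly expressed; all are configurable
upward.

## Known limitations

* Regression-adjusted ABC draws can leave the marginal prior range
  (only the joint N_Min ≤ N_Max constraint is re-imposed).
* The GLM battery assumes exchangeable samples within the design factors;
  temporal autocorrelation beyond the year factor is handled only through
  the permutation null, not the likelihood.
* Window statistics treat SNPs as exchangeable within windows; SNP-density
  and LD variation along the genome are absorbed by the per-window
  permutation thresholds, as in the source analyses.
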