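# Methods

## The score

The teloscore aggregates 11 GWAS-discovered LTL variants. Weights are the
published per-effect-allele LTL effects expressed in base pairs; across all
11 panel rows the bp weight equals the SD-scale effect β times a single
conversion constant of 1200 bp per SD, which `panel.bp_from_beta` applies
and `panel.validate_panel` enforces (tolerance 0.05 bp, the printed
rounding). Panel constants are embedded verbatim (GRCh37, 1-based); the
package never re-estimates weights.

The raw score Σ g·w is defined only for fully called subjects. The scaled
score divides the sum over called SNPs by the number called, i.e. it is the
average bp contribution per called genotype; it equals raw/11 for complete
subjects, and it is the default headline quantity because it keeps subjects
with partial genotyping (the call-rate filter admits ≥ 8 of 11 called) in
the analysis. Note the two variants are on different scales (the scaled
score is ~1/11 of the raw score), so quintile cutpoints are never shared
between them.

## Quality control

- Call-rate filter: subjects need at least `min_called` (default 8) of the
  11 panel SNPs; the threshold is an integer count, not a percentage, to
  avoid float boundary ambiguity (8/11 = 72.7%).
- Hardy–Weinberg: exact conditional (Levene–Haldane) test per SNP in
  controls, α = 0.05; the chi-square variant is available
  (`hwe_method="chisq"`). The exact test is the field standard at the
  panel's minor-allele frequencies, where rare-homozygote cells are small.
- MAF ties at 0.5 resolve the panel's *other* allele as "minor" so reported
  MAFs always name a definite allele; the same rule fixes the allelic-model
  orientation for a 0.5-frequency SNP (TERT).
- Duplicate concordance pools all pairwise comparisons where both calls are
  present.
- VCF input is matched by chromosome + position + allele pair, with
  automatic recoding when REF/ALT orientation is flipped relative to the
  effect/other alleles; a site whose allele pair disagrees with the panel is
  skipped, never strand-complemented silently.

## Association models

All models are unconditional logistic regressions fitted by Newton maximum
likelihood (statsmodels) with age in years (continuous) and sex and country
as indicators, reference level = largest control category. Subjects missing
an adjustment covariate are dropped complete-case with a logged count.
Odds ratios carry Wald 95% CIs, exp(β ± 1.96·se), and two-sided Wald
p-values; a likelihood-ratio p-value helper exists for sensitivity checks.
Fits that fail to converge or show quasi-separation (|β| > 15) are flagged
and propagate the flag to their results.

Quintile analysis: cutpoints are the 20/40/60/80th percentiles of control
scaled scores using linear interpolation between order statistics (the
common default; recorded in run metadata). Bins are half-open, boundary
values fall in the lower bin. The categorical model uses indicator terms
for bins 2–5 (bin 1 reference); the trend model enters the bin index 1–5 as
one numeric term, so its OR is per one-quintile increment (entering the raw
scaled score instead is available as `score_trend_association`).

Per-SNP models count the minor allele as fixed in controls (allelic 0/1/2;
codominant het and rare-hom contrasts vs common hom; dominant carrier;
recessive rare hom), with an effect-allele orientation flag for
score-consistent coding. A codominant contrast with an empty
rare-homozygote cell is omitted with an explicit marker rather than fitted.
Bonferroni correction uses α/(n SNPs × n models) = 0.05/22 = 0.0023 for the
default allelic + codominant pair.

Stratified runs restrict cases to one stratum level (JAK2 V617F status or
MPN subtype) while keeping all controls; quintile cutpoints are recomputed
from the stratum's controls by default (`cutpoints_mode="per-stratum"`) —
since controls carry no stratum label this coincides with the overall
cutpoints unless covariate exclusions differ — with frozen overall
cutpoints as the alternative. Strata with < 10 cases are computed but
flagged low-power.

## Synthetic cohorts

The generator's defaults emulate the study conditions the analysis is meant
for: 480 cases / 909 controls; country weights proportional to the control
margins 75 (Hungary) / 182 (Italy) / 132 (Poland) / 520 (Spain); ~50%
males; ages from a normal(53, 11) truncated to [18, 95], a stand-in chosen
to match reported medians/IQRs in the mid-50s (only medians/IQRs are
published, so the full shape is a modeling choice exposed in the config);
MPN subtype weights 149/173/36/122 (CML/ET/PMF/PV); 3% independent (MCAR)
per-call missingness targeting a 97% call rate; JAK2-positive fraction 0.5
among cases.

Genotypes are independent across SNPs, Binomial(2, EAF) per SNP — exact
HWE. No linkage disequilibrium is modeled: the panel spans 9 chromosomes
and the score treats SNPs additively, so LD adds nothing to validating this
pipeline.

Disease is generated prospectively: a pool of 20 × (n_cases + n_controls)
subjects receives true genotypes and covariates; each subject's case
probability is inverse-logit(baseline + effects); cases and controls are
then sampled to the exact requested margins. Logistic odds ratios are
invariant to outcome-dependent sampling, so injected ORs are recoverable;
the baseline intercept (−2.0) only controls pool efficiency. For
quintile-effect models the injected effect acts on quintiles of the pool's
prospective control distribution; since that set is unknowable a priori,
one refinement pass is used (provisional draw with pool-wide cutpoints →
recompute cutpoints on the provisional non-cases → final independent draw),
which converges to within Monte-Carlo noise at the default prevalence.
Missingness is applied after sampling, so the disease model always acts on
true genotypes. Covariates are drawn from the same distributions for both
groups, emulating frequency matching; the analysis adjusts for residual
imbalance. All randomness flows from a single seed through spawned
per-stage streams; identical configs give byte-identical cohorts.

What the generator does **not** emulate: linkage disequilibrium and
population stratification, covariate-dependent (non-MCAR) genotyping
failure, age/sex-dependent disease risk, clonal hematopoiesis in controls,
and somatic driver-mutation acquisition. Passing recovery tests therefore
demonstrates that the estimator chain is correct under the stated sampling
model, not that real-data confounding is handled beyond the adjustment set.

## Parameter recovery and a known attenuation

Recovery experiments (`pipeline.recover_quintile_or`,
`recover_allelic_or`) inject published effect sizes — per-quintile ORs
1.25/1.65/1.54/1.82 and an allelic OR of 1.43 at EAF 0.13 — and rerun the
full QC + scoring + adjusted-model chain over 200 seeded replicates,
summarising with the geometric mean (exp of mean log-OR; the arithmetic
mean of ORs is Jensen-biased upward). The allelic model recovers its target
essentially exactly. The extreme-quintile contrast recovers ~1.71–1.76
against an injected 1.82: with 3% of calls missing, ~28% of subjects have a
scaled score that is a perturbed version of the true score the effect acted
on, and the resulting quintile misclassification attenuates the Q5-vs-Q1 OR
by roughly 4–6%. With missingness disabled the recovery is unbiased
(`tests/test_recovery.py`), isolating the effect as score measurement
error, not estimator bias. The same mechanism operates in any real study
analysed with a scaled score under partial genotyping, so scaled-score
quintile ORs should be read as mildly conservative.

## Numerical choices and degenerate inputs

- Convergence: Newton, tol 1e-10, max 100 iterations; BFGS fallback on a
  singular Hessian, always flagged.
- HWE exact p-values use log-gamma arithmetic with a 1e-10 tie tolerance;
  validated against an exact-rational enumeration oracle for allele totals
  ≤ 50.
- Quintile cutpoints require ≥ 5 distinct control scores; constant score
  distributions are an error, not silently binned.
- Monomorphic SNPs raise; empty quintile bins and empty rare-homozygote
  cells yield omitted-with-marker rows.
- Problem sizes: recovery experiments use 200 replicates at the default
  480/909 margins with a 20× pool; the type-I-error check uses 100 null
  cohorts. These sizes give Monte-Carlo SEs a small fraction of the effects
  under test.
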