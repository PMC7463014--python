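# teloscore

Tools for the **teloscore**, a weighted genetic score over 11 SNPs that
serves as a proxy for leukocyte telomere length (LTL), and for testing its
association with disease risk in case-control studies of myeloproliferative
neoplasms (MPNs).

Telomere length measured directly (qPCR, FISH) in retrospective studies is
vulnerable to reverse causation and measurement bias. Because LTL is partly
heritable, a score built from GWAS-discovered LTL variants gives a
genetically determined, exposure-independent instrument instead. For each
panel SNP *j* with per-effect-allele LTL effect *w<sub>j</sub>* (in base
pairs) and effect-allele count *g<sub>ij</sub>* ∈ {0, 1, 2} for subject *i*:

- raw score: *S<sub>i</sub>* = Σ<sub>j</sub> *g<sub>ij</sub> w<sub>j</sub>*
  (defined when all 11 SNPs are called);
- scaled score: *S̃<sub>i</sub>* = Σ<sub>j∈called</sub> *g<sub>ij</sub>
  w<sub>j</sub>* / *n<sub>called,i</sub>*, usable with partial genotyping.

Subjects are binned into quintiles of the **control** score distribution and
disease association is estimated by unconditional logistic regression
(quintiles 2–5 vs 1, plus a per-quintile trend), adjusted for age, sex and
country. Individual SNPs are tested under allelic, codominant, dominant and
recessive models with Bonferroni correction over 11 SNPs × 2 models.

The package provides:

- `teloscore.panel` — the 11-SNP panel (rsid, effect allele, EAF, β in SD
  units and the bp-per-allele weight, β × 1200 bp/SD) embedded as data;
- `teloscore.cohort` / `teloscore.qc` — TSV and VCF readers, call-rate
  filtering, exact (Levene–Haldane) Hardy–Weinberg testing in controls, MAF
  and duplicate-sample concordance;
- `teloscore.score` — raw/scaled scores, control quintile cutpoints,
  leave-one-out score variants;
- `teloscore.association` — covariate-adjusted logistic models with Wald
  CIs, stratified (e.g. JAK2 V617F) runs;
- `teloscore.simulate` — a synthetic-cohort generator (HWE genotypes at the
  panel EAFs, realistic covariate margins, controlled missingness,
  injectable quintile or per-SNP effects) so the whole chain is testable by
  parameter recovery without individual-level study data;
- a thin CLI: `teloscore simulate | analyze | report`.

## Worked example

Simulate a cohort of 480 cases / 909 controls in which disease risk rises
with the scaled-score quintile (injected odds ratios 1.25 / 1.65 / 1.54 /
1.82 for quintiles 2–5 vs 1) and re-analyze it
(`python examples/03_full_analysis.py`):

```
retained 479 cases / 909 controls
control quintile cutpoints (bp/genotype): 63.72, 71.78, 80.95, 91.68

quintile model (adjusted for age, sex, country):
  quintile 1    OR 1.00 (reference)
  quintile 2    OR 0.98 (0.67-1.44), p=0.924
  quintile 3    OR 1.54 (1.07-2.20), p=0.0195
  quintile 4    OR 1.44 (1.00-2.07), p=0.0481
  quintile 5    OR 1.58 (1.10-2.27), p=0.0125
  per-quintile  OR 1.14 (1.05-1.23), p=0.00185

per-SNP Bonferroni threshold: p < 0.0023
```

The fitted quintile odds ratios scatter around the injected values (one
replicate; `examples/04_effect_recovery.py` averages many), the per-quintile
trend is clearly positive, and no individual SNP crosses the Bonferroni
threshold — the injected effect lives on the whole score, and each SNP's
share of it is far below detectable size at this sample size.

The other examples: `01_panel_and_score.py` (panel contents and score
arithmetic), `02_simulate_and_qc.py` (call-rate filter and Hardy–Weinberg
report).

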