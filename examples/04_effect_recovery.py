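"""Parameter recovery: does the pipeline return the effect we injected?

Runs a small Monte-Carlo recovery experiment (25 replicates here; the
acceptance script uses 200): each replicate simulates a fresh cohort
with a per-allele odds ratio of 1.43 at a SNP with effect-allele
frequency 0.13, re-analyses it with the adjusted allelic model, and the
geometric mean of the recovered odds ratios is compared with the truth.
"""

from teloscore.pipeline import recover_allelic_or, recover_quintile_or

out = recover_allelic_or(n_reps=25, seed=2)
print(f"allelic recovery ({out['n_reps']} replicates): injected OR "
      f"{out['target_or']}, recovered {out['recovered_or']:.3f} "
      f"(MC z = {out['z_vs_target']:.2f})")

out = recover_quintile_or(n_reps=25, seed=1)
print(f"quintile recovery ({out['n_reps']} replicates): injected Q5-vs-Q1 OR "
      f"{out['target_or']}, recovered {out['recovered_or']:.3f} "
      f"(MC z = {out['z_vs_target']:.2f})")
print("\nThe quintile contrast recovers slightly below truth: with 3% of "
      "calls missing, the scaled score is an error-prone version of the "
      "score the effect acted on, and quintile misclassification attenuates "
      "the extreme-quintile odds ratio by a few percent.")
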