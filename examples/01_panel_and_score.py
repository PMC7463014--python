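"""Inspect the 11-SNP telomere-length panel and score a subject.

Builds the panel of published LTL-associated SNPs, then computes raw and
scaled teloscores for a hand-written genotype vector with one missing
call.  The scaled score is the per-called-genotype average bp effect, so
partially genotyped subjects remain comparable.
"""

import numpy as np

from teloscore import MISSING, builtin_panel, scaled_teloscore, teloscore

panel = builtin_panel()
print(f"panel: {len(panel)} SNPs, total per-heterozygote weight "
      f"{sum(panel.bp_weights):.1f} bp")
for e in panel:
    print(f"  {e.rsid:<11} {e.gene:<7} EA={e.effect_allele} EAF={e.eaf:<5} "
          f"beta={e.beta:.3f} SD -> {e.bp_per_allele:.1f} bp/allele")

# a fully genotyped subject heterozygous everywhere
g_full = np.ones(11, dtype=np.int8)
print(f"\nall-heterozygous subject: raw = {teloscore(g_full, panel):.1f} bp, "
      f"scaled = {scaled_teloscore(g_full, panel).scaled_score:.2f} bp/genotype")

# the same subject with one failed genotype call: raw undefined, scaled ok
g_partial = g_full.copy()
g_partial[0] = MISSING
res = scaled_teloscore(g_partial, panel)
print(f"with 1 missing call: n_called = {res.n_called}, "
      f"scaled = {res.scaled_score:.2f} bp/genotype (raw undefined)")
print("\nHigher scaled scores mean more long-telomere alleles, i.e. longer "
      "genetically determined telomeres.")
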