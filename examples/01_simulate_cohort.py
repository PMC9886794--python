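"""Simulate a pooled-sequencing case/control cohort and inspect how well
pooled read counts recover the true diploid allele counts."""

import numpy as np

from mitolav.simulate import (CohortDesign, VariantSpec,
                              build_variant_records, simulate_genotypes)

design = CohortDesign(seed=1)  # 494 cases + 572 controls, 43 pools, ~378x
print(f"pools: {design.n_case_pools} case + {design.n_control_pools} "
      f"control = {design.n_case_pools + design.n_control_pools}")
print(f"per-sample coverage: {design.per_sample_coverage:.2f}x")

rng = np.random.default_rng(1)
specs = [VariantSpec("GENE1", maf, maf) for maf in (0.002, 0.01, 0.05, 0.2)]
genotypes = simulate_genotypes(design, specs, rng)
true_counts = genotypes.sum(axis=0)
records, _, kept = build_variant_records(design, specs, rng,
                                         genotypes=genotypes)
print("\ntrue MAF   true count   estimated count (cases+controls)")
for spec, true, rec in zip(specs, true_counts, records):
    est = rec.counts.min_case + rec.counts.min_ctrl
    print(f"{spec.true_maf_cases:8.3f}   {true:10d}   {est:15d}")
print("\nEstimates come from depth-weighted pooled read fractions, "
      "debiased for the 0.002 per-read miscall rate and rounded; at ~15x "
      "per sample they track the truth to within a few alleles.")
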