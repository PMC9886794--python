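"""Single-variant Fisher association on a simulated null cohort: p-value
calibration, rarity classes and enrichment directionality."""

import numpy as np

from mitolav.simulate import CohortDesign, default_variant_panel, \
    build_variant_records
from mitolav.stats import associate, correct_multiplicity, \
    summarize_distributions
from mitolav.variants import adjust_minor_allele

rng = np.random.default_rng(7)
design = CohortDesign(seed=7)
specs = default_variant_panel(3000, rng, design=design)
records, _, _ = build_variant_records(design, specs, rng)
records = [adjust_minor_allele(r) for r in records]

results = associate(records)
threshold = correct_multiplicity(results, alpha=0.05)
print(f"{len(results)} variants kept; Bonferroni threshold "
      f"{threshold:.2e}")

summary = summarize_distributions(results, exclude_singletons=True)
strata = summary["enriched_by_rarity_all"]
for name in ("rare", "common"):
    s = strata[name]
    print(f"{name:6s}: n={s['n']:5d}  enriched {s['pct_enriched']:.1f}%")
n_sig = sum(r.p_value <= 0.05 for r in results)
print(f"nominally significant (p <= 0.05): {n_sig} "
      f"(~5% expected under this null)")
print("\nUnder the null, common variants split ~50/50 between enriched "
      "and depleted; rare variants lean slightly 'enriched' because the "
      "case group holds fewer chromosomes, so equal minor counts give a "
      "higher case frequency. No variant should survive the Bonferroni "
      "threshold.")
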