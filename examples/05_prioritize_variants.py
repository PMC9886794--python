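"""Plant fully qualifying longevity-associated variants among nulls and
recover them with the six-criterion prioritization cascade."""

import numpy as np

from mitolav import prioritize
from mitolav.aa import classify_table
from mitolav.simulate import (CohortDesign, build_variant_records,
                              default_variant_panel, planted_lav_spec)
from mitolav.stats import associate
from mitolav.variants import adjust_minor_allele

rng = np.random.default_rng(3)
design = CohortDesign(seed=3)
specs = default_variant_panel(2000, rng, design=design) \
    + [planted_lav_spec(f"LAVGENE{i}", rng) for i in range(5)]
records, _, _ = build_variant_records(design, specs, rng)
records = classify_table([adjust_minor_allele(r) for r in records])

ranked = prioritize.rank(prioritize.apply_criteria(associate(records)))
print(f"{len(ranked)} variants pass the association gate (p <= 0.05)")
print("\ntop 8 by the lexicographic criteria order:")
print("rank  gene        p        tier  impact  external  evidence")
for p in ranked[:8]:
    print(f"{p.rank:4d}  {p.gene:10s} {p.p_value:8.2e} "
          f"{p.c3_location_tier:5s} {p.c4_impact:7s} {p.c5_external:8s} "
          f"{p.c6_evidence:5d}")
print("\nsummary:", prioritize.lav_summary(ranked))
print("\nThe five planted variants (enriched rare nsVs with damaging "
      "predictions, external absence and evidence lines) occupy the top "
      "ranks; chance-significant nulls rank below them on the "
      "impact/evidence keys.")
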