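"""Permutation gene-set enrichment against a configurable background,
cross-checked against the hypergeometric tail."""

import numpy as np
from scipy.stats import hypergeom

from mitolav.enrich import enrich

background = [f"G{i}" for i in range(2000)]     # e.g. mito proteome scale
metabolic = background[:50]                      # a disease category
query = background[:20] + background[100:160]    # 80 genes, 20 in category

res = enrich(query, {"metabolic": metabolic}, background,
             n_permutations=10_000, rng=np.random.default_rng(0),
             background_name="proteome")[0]
p_hyper = float(hypergeom.sf(res.observed - 1, len(background),
                             len(metabolic), len(query)))
print(f"observed overlap: {res.observed} (expected "
      f"{res.expected:.2f} under the null)")
print(f"empirical permutation p: {res.p_empirical:.4g} "
      f"(B = {res.n_permutations})")
print(f"hypergeometric tail:     {p_hyper:.4g}")
print("\nThe permutation null draws query-sized gene sets uniformly from "
      "the background, so its p converges to the hypergeometric tail; "
      "here the planted 10-fold over-representation is decisively "
      "detected.")
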