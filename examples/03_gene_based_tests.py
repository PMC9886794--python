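"""The three gene-level aggregate tests on a gene with a planted
case-enriched rare-variant burden, against a null gene."""

import numpy as np

from mitolav.genetests import (combined_test, null_model, optimal_test,
                               rare_kernel_test)

rng = np.random.default_rng(11)
n = 1066
y = np.r_[np.ones(494), np.zeros(572)]
null = null_model(y)

# null gene: 6 rare variants, same frequency in both groups
G_null = rng.binomial(2, rng.uniform(0.002, 0.02, size=6), size=(n, 6))

# burden gene: carriers concentrated in cases across all 6 variants
G_hit = np.zeros((n, 6))
for j in range(6):
    G_hit[rng.choice(494, size=14, replace=False), j] = 1
    G_hit[494 + rng.choice(572, size=4, replace=False), j] = 1

for name, G in (("null gene", G_null), ("burden gene", G_hit)):
    p_k, _ = rare_kernel_test(G, null)
    p_c, _ = combined_test(G, null)
    p_o, rho = optimal_test(G, null, rng=np.random.default_rng(0))
    print(f"{name}: kernel p={p_k:.3g}  combined p={p_c:.3g}  "
          f"optimal p={p_o:.3g} (rho={rho})")
print("\nThe kernel test aggregates squared per-variant scores, the "
      "combined test adds a common-variant partition, and the optimal "
      "test scans kernel-to-burden combinations; a consistently "
      "case-enriched gene drives all three far below 0.05, with rho "
      "selected away from the pure-kernel end.")
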