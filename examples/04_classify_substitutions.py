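"""Classify amino-acid substitutions as conservative (C),
non-conservative (NC) or radical (R) from R-group properties."""

from mitolav.aa import PROPERTY_NAMES, classify, parse_hgvs_p

for text in ("p.L100L", "p.K100E", "p.S1378G", "p.D1352E", "p.G50W"):
    ref, pos, alt = parse_hgvs_p(text)
    change = classify(ref, alt, pos)
    flipped = [name for name, d in zip(PROPERTY_NAMES, change.diff_vector)
               if d]
    print(f"{text:10s} -> {change.label:2s}  ({change.n_diffs} "
          f"differences: {', '.join(flipped) or 'none'})")
print("\nC = zero property differences; NC = at least one; R = two or "
      "more including a size change (steric potential). The diff vector "
      "makes every label auditable against the packaged property table.")
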