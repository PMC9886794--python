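"""Per-variant association statistics and distribution summaries.

The association test is a two-sided Fisher exact test on the 2x2 table of
diploid minor/major allele counts in cases vs controls, with Bonferroni and
Benjamini-Hochberg multiplicity correction, minor-allele-frequency rarity
classes (rare: cohort MAF <= 0.010, inclusive), singleton flags (cohort
minor count exactly 1) and enrichment directionality (strictly greater MAF
in cases than controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .variants import AlleleCounts, VariantRecord, maf

#: Rarity boundary on the cohort minor-allele frequency; the boundary value
#: itself counts as rare.
DEFAULT_MAF_THRESHOLD = 0.010

#: Relative tolerance when deciding whether a table's hypergeometric
#: probability "ties" the observed one in the two-sided rule. Absorbs float
#: rounding in exactly-tied (e.g. mirror-symmetric) tables without pulling
#: in genuinely more probable ones.
_TIE_RTOL = 1e-10


class StatsError(ValueError):
    pass


def fisher_exact_two_sided(counts: AlleleCounts | Sequence[Sequence[int]]
                           ) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table. Degenerate
    tables (an empty minor or major column) give p = 1.
    """
    if isinstance(counts, AlleleCounts):
        a, b = counts.min_case, counts.maj_case
        c, d = counts.min_ctrl, counts.maj_ctrl
    else:
        (a, b), (c, d) = counts
    if min(a, b, c, d) < 0:
        raise StatsError("negative cell in contingency table")
    n1, n2 = a + b, c + d
    if n1 <= 0 or n2 <= 0:
        raise StatsError("both row sums must be > 0")
    total = n1 + n2
    k_col = a + c  # minor-allele column margin
    if k_col == 0 or k_col == total:
        return 1.0
    lo = max(0, n1 - (total - k_col))
    hi = min(n1, k_col)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, k_col, n1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(1.0, max(p, np.nextafter(0, 1)))


def odds_ratio(counts: AlleleCounts) -> float:
    """Case/control minor-allele odds ratio.

    Adds 0.5 to every cell when any cell is zero (Haldane-Anscombe); used
    for reporting only, never for the p-value.
    """
    a, b = counts.min_case, counts.maj_case
    c, d = counts.min_ctrl, counts.maj_ctrl
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


@dataclass
class AssociationResult:
    """Per-variant association statistics."""

    key: str
    chrom: str
    pos: int
    gene: str
    consequence_class: str
    p_value: float
    odds_ratio: float
    maf_cases: float
    maf_controls: float
    maf_cohort: float
    enriched: bool
    rarity: str            # "rare" | "common"
    singleton: bool
    p_bonferroni: float = 1.0
    q_bh: float = 1.0
    record: VariantRecord | None = field(default=None, repr=False)


def _is_enriched(c: AlleleCounts) -> bool:
    # strict inequality on exact rational frequencies; ties are depleted
    return c.min_case * c.total_ctrl > c.min_ctrl * c.total_case


def _is_rare(c: AlleleCounts, threshold: float = DEFAULT_MAF_THRESHOLD
             ) -> bool:
    # inclusive boundary, compared exactly (0.010 == 1/100)
    return Fraction(c.minor_cohort, c.total_cohort) \
        <= Fraction(threshold).limit_denominator(10**6)


def associate(records: Iterable[VariantRecord],
              maf_threshold: float = DEFAULT_MAF_THRESHOLD
              ) -> list[AssociationResult]:
    """Fisher-test every (already minor-allele-adjusted) record."""
    out = []
    for r in records:
        c = r.counts
        out.append(AssociationResult(
            key=r.key, chrom=r.chrom, pos=r.pos, gene=r.gene,
            consequence_class=r.consequence_class,
            p_value=fisher_exact_two_sided(c),
            odds_ratio=odds_ratio(c),
            maf_cases=maf(r, "cases"),
            maf_controls=maf(r, "controls"),
            maf_cohort=maf(r, "cohort"),
            enriched=_is_enriched(c),
            rarity="rare" if _is_rare(c, maf_threshold) else "common",
            singleton=c.minor_cohort == 1,
            record=r,
        ))
    return out


def bh_qvalues(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values with m total tests.

    ``m`` may exceed ``len(pvalues)`` (tests performed but not reported);
    with m == len(pvalues) this matches the standard BH adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    r = len(p)
    if m is None:
        m = r
    if m < r:
        raise StatsError("m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, r + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(r)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def correct_multiplicity(results: Sequence[AssociationResult],
                         m: int | None = None,
                         alpha: float = 0.05) -> float:
    """Attach Bonferroni and BH values in place; return the per-test
    Bonferroni threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must be in (0, 1)")
    if m is None:
        m = len(results)
    if m < len(results):
        raise StatsError("m must be >= number of results")
    q = bh_qvalues([r.p_value for r in results], m)
    for r, qi in zip(results, q):
        r.p_bonferroni = min(1.0, r.p_value * m)
        r.q_bh = float(qi)
    return alpha / m


def bonferroni_threshold(alpha: float = 0.05, m: int = 660) -> float:
    """Per-test significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must be in (0, 1)")
    if m < 1:
        raise StatsError("m must be >= 1")
    return alpha / m


def summarize_distributions(results: Sequence[AssociationResult],
                            exclude_singletons: bool = False,
                            alpha: float = 0.05) -> dict:
    """Panel-style distribution summary.

    Returns consequence-class counts and percentages (coding vs non-coding
    pies), plus the centenarian-enriched fraction by rarity stratum, both
    over all variants and restricted to nominally significant ones
    (p <= alpha).
    """
    rows = [r for r in results
            if not (exclude_singletons and r.singleton)]
    summary: dict = {
        "n_variants": len(rows),
        "exclude_singletons": exclude_singletons,
    }
    if not rows:
        summary["warning"] = "empty input"
        return summary

    from .variants import CODING_CLASSES
    coding = [r for r in rows if r.consequence_class in CODING_CLASSES]
    noncoding = [r for r in rows if r.consequence_class not in CODING_CLASSES]
    summary["n_coding"] = len(coding)
    summary["n_noncoding"] = len(noncoding)
    summary["pct_coding"] = 100.0 * len(coding) / len(rows)

    def _pie(group: list[AssociationResult]) -> dict:
        counts: dict[str, int] = {}
        for r in group:
            counts[r.consequence_class] = counts.get(r.consequence_class,
                                                     0) + 1
        n = max(1, len(group))
        return {cls: {"n": k, "pct": 100.0 * k / n}
                for cls, k in sorted(counts.items())}

    summary["coding_classes"] = _pie(coding)
    summary["noncoding_classes"] = _pie(noncoding)

    def _enriched_fraction(group: list[AssociationResult]) -> float | None:
        if not group:
            return None
        return 100.0 * sum(r.enriched for r in group) / len(group)

    for label, pred in (("all", lambda r: True),
                        ("significant", lambda r: r.p_value <= alpha)):
        strata = {}
        for rarity in ("rare", "common"):
            grp = [r for r in rows if r.rarity == rarity and pred(r)]
            strata[rarity] = {
                "n": len(grp),
                "pct_enriched": _enriched_fraction(grp),
            }
        grp = [r for r in rows if pred(r)]
        strata["overall"] = {"n": len(grp),
                             "pct_enriched": _enriched_fraction(grp)}
        summary[f"enriched_by_rarity_{label}"] = strata
    return summary


def manhattan_table(results: Sequence[AssociationResult]):
    """Manhattan-plot-ready table (chrom, pos, gene, p, -log10 p)."""
    import pandas as pd
    return pd.DataFrame({
        "chrom": [r.chrom for r in results],
        "pos": [r.pos for r in results],
        "gene": [r.gene for r in results],
        "p": [r.p_value for r in results],
        "neg_log10_p": [-np.log10(r.p_value) for r in results],
    })
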