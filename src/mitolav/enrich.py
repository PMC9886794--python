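"""Age-related-disease gene-set enrichment with permutation null.

Tests whether a query gene set (e.g. the mitonuclear candidate list) is
over-represented in GWAS-derived disease-category gene sets, against a
configurable background (whole genome ~21,000 genes, mitochondrial
proteome ~2,220, or the candidate list ~660). The null distribution of the
category overlap is built by drawing |query|-sized gene sets uniformly
without replacement from the background; the empirical p-value is

    p = (1 + #{permutations with overlap >= observed}) / (B + 1),

which converges to the hypergeometric upper tail as B grows (the test
suite checks exactly this). Uniform gene sampling — no conditioning on
gene length or SNP density — is the documented default.

Also provides the GWAS-catalog preprocessing rules: category-specific
significance filtering (disease rows at p <= 1e-8; lifespan / aging /
longevity rows at p <= 1e-6) and per-(gene, trait, study) deduplication
keeping the most significant association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Trait strings treated as lifespan-type (lower-stringency) categories.
LIFESPAN_TERMS = frozenset({"lifespan", "aging", "longevity"})

DISEASE_P_MAX = 1e-8
LIFESPAN_P_MAX = 1e-6


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: int
    expected: float          # mean overlap under the permutation null
    p_empirical: float
    n_permutations: int
    background: str


def filter_catalog(rows: pd.DataFrame,
                   disease_p_max: float = DISEASE_P_MAX,
                   lifespan_p_max: float = LIFESPAN_P_MAX) -> pd.DataFrame:
    """Keep catalog rows passing the category-specific p thresholds.

    Expects columns ``gene, trait, category, p_reported, study``. Rows
    whose category is a lifespan term use the (laxer) lifespan threshold;
    all other rows the genome-wide disease threshold. Both inclusive.
    """
    required = {"gene", "trait", "category", "p_reported", "study"}
    missing = required - set(rows.columns)
    if missing:
        raise EnrichmentError(f"catalog lacks columns: {sorted(missing)}")
    is_lifespan = rows["category"].str.lower().isin(LIFESPAN_TERMS)
    keep = np.where(is_lifespan,
                    rows["p_reported"] <= lifespan_p_max,
                    rows["p_reported"] <= disease_p_max)
    return rows.loc[keep].reset_index(drop=True)


def dedupe(rows: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, trait, study) keep only the most significant row.

    Ties on p keep the first occurrence in input order (stable).
    """
    idx = (rows.reset_index(drop=True)
               .groupby(["gene", "trait", "study"], sort=False)["p_reported"]
               .idxmin())
    return rows.reset_index(drop=True).loc[sorted(idx)].reset_index(drop=True)


def load_category_map(path) -> dict[str, str]:
    """Trait -> category mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].str.lower(), df.iloc[:, 1]))


def categorize(rows: pd.DataFrame, trait_to_category: Mapping[str, str]
               ) -> pd.DataFrame:
    """Attach a ``category`` column by (case-insensitive) trait lookup."""
    rows = rows.copy()
    rows["category"] = [trait_to_category.get(t.lower(), "other")
                        for t in rows["trait"]]
    return rows


def enrich(query: Sequence[str],
           category_sets: Mapping[str, Sequence[str]],
           background: Sequence[str],
           n_permutations: int = 10_000,
           rng: np.random.Generator | None = None,
           background_name: str = "custom") -> list[EnrichmentResult]:
    """Permutation enrichment of ``query`` in each category gene set."""
    if rng is None:
        rng = np.random.default_rng(0)
    if n_permutations < 1000:
        raise EnrichmentError("n_permutations must be >= 1000")
    bg = list(dict.fromkeys(background))
    bg_index = {g: i for i, g in enumerate(bg)}
    query_set = list(dict.fromkeys(query))
    offenders = [g for g in query_set if g not in bg_index]
    if offenders:
        raise EnrichmentError(
            f"{len(offenders)} query genes absent from background: "
            f"{offenders[:10]}"
        )
    n_bg, n_q = len(bg), len(query_set)
    cat_names = list(category_sets)
    membership = np.zeros((len(cat_names), n_bg), dtype=bool)
    for ci, cat in enumerate(cat_names):
        for g in category_sets[cat]:
            i = bg_index.get(g)
            if i is not None:
                membership[ci, i] = True
    q_idx = np.array([bg_index[g] for g in query_set])
    observed = membership[:, q_idx].sum(axis=1)

    null_overlap = np.empty((n_permutations, len(cat_names)), dtype=np.int64)
    for b in range(n_permutations):
        draw = rng.choice(n_bg, size=n_q, replace=False)
        null_overlap[b] = membership[:, draw].sum(axis=1)

    out = []
    for ci, cat in enumerate(cat_names):
        ge = int((null_overlap[:, ci] >= observed[ci]).sum())
        out.append(EnrichmentResult(
            category=cat,
            observed=int(observed[ci]),
            expected=float(null_overlap[:, ci].mean()),
            p_empirical=(1.0 + ge) / (n_permutations + 1.0),
            n_permutations=n_permutations,
            background=background_name,
        ))
    return out
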