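"""Six-criterion prioritization cascade for longevity-associated variants.

The cascade evaluates, per variant:

1. nominal single-variant association (p <= 0.05) — a hard gate;
2. centenarian enrichment (MAF_cases > MAF_controls) — a priority key,
   not a gate (depleted variants survive, ranked lower);
3. location tier: nonsynonymous > other coding > non-coding;
4. predicted impact: for nsVs an NC/R amino-acid label plus a damaging
   prediction (Condel deleterious or CADD_phred >= threshold); for ncVs a
   strong Regulome rank or curated regulatory evidence;
5. external-population rarity corroboration: every available external MAF
   <= 0.010; total absence from external populations also passes (absence
   is the strongest rarity signal);
6. count of a-priori biological evidence lines (conservation flags plus
   curated evidence notes) — more is better.

Missing annotation yields an explicit ``unknown`` state, never a pass.
Ranking is lexicographic on the criteria in their listed order, then
ascending p, then genomic coordinate; no weighted score is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .stats import AssociationResult

PASS, FAIL, UNKNOWN = "pass", "fail", "unknown"
_STATE_ORDER = {PASS: 0, UNKNOWN: 1, FAIL: 2}
_TIER_ORDER = {"nsV": 0, "other_coding": 1, "ncV": 2}

#: Coding classes that are not nonsynonymous missense changes.
_OTHER_CODING = frozenset({"synonymous", "stop_gain", "frameshift",
                           "inframe_indel"})


@dataclass(frozen=True)
class PrioritizerConfig:
    p_max: float = 0.05
    cadd_min: float = 15.0          # "possibly damaging" tier
    regulome_max: int = 3
    external_maf_max: float = 0.010
    min_nsv: int = 2                # hotspot-gene threshold

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")
        if not 1 <= self.regulome_max <= 7:
            raise ValueError("regulome_max must be in 1..7")
        if not 0.0 <= self.external_maf_max <= 0.5:
            raise ValueError("external_maf_max must be in [0, 0.5]")
        if self.min_nsv < 1:
            raise ValueError("min_nsv must be >= 1")


@dataclass
class PriorityRecord:
    """A variant's state on each criterion plus its final rank."""

    key: str
    chrom: str
    pos: int
    gene: str
    p_value: float
    c1_assoc: str
    c2_enriched: str
    c3_location_tier: str       # "nsV" | "other_coding" | "ncV"
    c4_impact: str              # pass | fail | unknown
    c5_external: str            # pass | fail | unknown
    c6_evidence: int
    rarity: str
    maf_cases: float
    maf_controls: float
    rank: int = 0
    detail: dict = field(default_factory=dict)

    @property
    def sort_key(self) -> tuple:
        return (
            0 if self.c2_enriched == PASS else 1,
            _TIER_ORDER[self.c3_location_tier],
            _STATE_ORDER[self.c4_impact],
            _STATE_ORDER[self.c5_external],
            -self.c6_evidence,
            self.p_value,
            _chrom_sort_value(self.chrom),
            self.pos,
        )


def _chrom_sort_value(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


def _location_tier(consequence_class: str) -> str:
    if consequence_class == "nonsynonymous":
        return "nsV"
    if consequence_class in _OTHER_CODING:
        return "other_coding"
    return "ncV"


def _impact_state(tier: str, ann: Mapping, cfg: PrioritizerConfig) -> str:
    cadd = ann.get("cadd_phred")
    condel = ann.get("condel_label")
    if tier == "nsV":
        label = ann.get("aa_label")
        if label is None and cadd is None and condel is None:
            return UNKNOWN
        damaging = ((condel == "deleterious")
                    or (cadd is not None and cadd >= cfg.cadd_min))
        if label in ("NC", "R") and damaging:
            return PASS
        if label is None or (cadd is None and condel in (None, "missing")):
            return UNKNOWN
        return FAIL
    if tier == "other_coding":
        # no amino-acid label applies; the prediction-score rule alone
        if cadd is None and condel is None:
            return UNKNOWN
        return PASS if ((condel == "deleterious")
                        or (cadd is not None and cadd >= cfg.cadd_min)) \
            else FAIL
    # non-coding: regulome rank or curated regulatory evidence
    rank_ = ann.get("regulome_rank")
    reg_flag = ann.get("regulatory_evidence")
    if rank_ is None and reg_flag is None:
        return UNKNOWN
    if (rank_ is not None and rank_ <= cfg.regulome_max) or reg_flag:
        return PASS
    return FAIL


def _external_state(ann: Mapping, cfg: PrioritizerConfig) -> str:
    mafs = [v for k, v in ann.items() if k.startswith("maf_")
            and v is not None]
    if not mafs:
        return PASS  # absent from every external population: strongest signal
    return PASS if all(v <= cfg.external_maf_max for v in mafs) else FAIL


def _evidence_count(ann: Mapping) -> int:
    n = int(ann.get("evidence_notes") or 0)
    n += int(bool(ann.get("vert_conserved")))
    n += int(bool(ann.get("invert_conserved")))
    return n


def apply_criteria(results: Sequence[AssociationResult],
                   config: PrioritizerConfig | None = None
                   ) -> list[PriorityRecord]:
    """Evaluate the cascade on association results carrying their records.

    Only criterion-1 passers are emitted (the hard gate); every other
    criterion's state is recorded on the emitted record — nothing is
    silently dropped past the gate.
    """
    cfg = config or PrioritizerConfig()
    out: list[PriorityRecord] = []
    for res in results:
        if res.p_value > cfg.p_max:
            continue
        ann = res.record.annotations if res.record is not None else {}
        tier = _location_tier(res.consequence_class)
        out.append(PriorityRecord(
            key=res.key, chrom=res.chrom, pos=res.pos, gene=res.gene,
            p_value=res.p_value,
            c1_assoc=PASS,
            c2_enriched=PASS if res.enriched else FAIL,
            c3_location_tier=tier,
            c4_impact=_impact_state(tier, ann, cfg),
            c5_external=_external_state(ann, cfg),
            c6_evidence=_evidence_count(ann),
            rarity=res.rarity,
            maf_cases=res.maf_cases, maf_controls=res.maf_controls,
            detail={"consequence_class": res.consequence_class,
                    "aa_label": ann.get("aa_label"),
                    "vert_conserved": bool(ann.get("vert_conserved")),
                    "invert_conserved": bool(ann.get("invert_conserved"))},
        ))
    return out


def rank(records: Iterable[PriorityRecord]) -> list[PriorityRecord]:
    """Stable lexicographic ranking; rank 1 is the top variant."""
    ordered = sorted(records, key=lambda r: r.sort_key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def hotspot_genes(records: Sequence[PriorityRecord],
                  min_nsv: int = 2) -> dict[str, list[str]]:
    """Genes carrying >= min_nsv prioritized nonsynonymous variants."""
    per_gene: dict[str, list[str]] = {}
    for r in records:
        if r.c3_location_tier == "nsV":
            per_gene.setdefault(r.gene, []).append(r.key)
    return {g: keys for g, keys in sorted(per_gene.items())
            if len(keys) >= min_nsv}


def lav_summary(records: Sequence[PriorityRecord]) -> dict:
    """Headline counts over the prioritized set (shares recomputed)."""
    n = len(records)
    nsv = sum(r.c3_location_tier == "nsV" for r in records)
    enr = sum(r.c2_enriched == PASS for r in records)
    rare = sum(r.rarity == "rare" for r in records)
    return {
        "n_prioritized": n,
        "n_genes": len({r.gene for r in records}),
        "n_nsv": nsv,
        "pct_enriched": 100.0 * enr / n if n else None,
        "pct_rare": 100.0 * rare / n if n else None,
        "n_vert_conserved": sum(
            bool(r.detail.get("vert_conserved")) for r in records),
        "n_invert_conserved": sum(
            bool(r.detail.get("invert_conserved")) for r in records),
    }
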