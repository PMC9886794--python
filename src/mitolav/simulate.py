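"""Synthetic case/control cohort generator with pooled-sequencing read model.

Emulates the study design the statistics modules were built for: a
centenarian ("case") vs control cohort sequenced as equimolar DNA pools —
by default 494 cases and 572 controls in pools of up to 25 individuals
(43 pools in total, homogeneous by group), with a median per-pool depth of
~378x, i.e. ~15x per sample.

The generative model is deliberately minimal:

* individual genotypes are Binomial(2, MAF) per group (Hardy-Weinberg);
* per-pool, per-site depth is Poisson around the median pool coverage;
* alt reads are Binomial(depth, f') with f' = f(1-e) + (1-f)e, where f is
  the pool's alt-chromosome fraction and e the per-read miscall rate;
* group diploid allele counts are recovered as
  round(2 * N_group * sum(alt)/sum(depth)) over the group's pools
  (half-away-from-zero rounding, so singletons survive rounding).

No read-level FASTQ/BAM simulation, alignment, or variant calling is
attempted; the simulator operates at the allele-count level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .variants import (AlleleCounts, VariantRecord, CONSEQUENCE_CLASSES,
                       CODING_CLASSES, VariantError, write_variants)


class DesignError(ValueError):
    """Raised when a cohort design or variant spec violates an invariant."""


@dataclass(frozen=True)
class CohortDesign:
    """Pooled-sequencing study design.

    Defaults reproduce the reference cohort: 494 cases + 572 controls in 43
    pools of at most 25 (pool_size is a maximum; 43*25 = 1075 > 1066, so
    the last pool of each group may be under-full), median pool depth
    378.12x and a per-read miscall rate of 0.002.
    """

    n_cases: int = 494
    n_controls: int = 572
    pool_size: int = 25
    n_pools: int = 43
    median_pool_coverage: float = 378.12
    seq_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "pool_size", "n_pools"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be > 0")
        if self.median_pool_coverage <= 0:
            raise DesignError("median_pool_coverage must be > 0")
        if not 0.0 <= self.seq_error_rate <= 0.05:
            raise DesignError("seq_error_rate must be in [0, 0.05]")
        if self.n_pools * self.pool_size < self.n_cases + self.n_controls:
            raise DesignError(
                "n_pools * pool_size must cover n_cases + n_controls"
            )

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_case_pools(self) -> int:
        return math.ceil(self.n_cases / self.pool_size)

    @property
    def n_control_pools(self) -> int:
        return math.ceil(self.n_controls / self.pool_size)

    @property
    def per_sample_coverage(self) -> float:
        """Fold coverage per individual implied by the pool design."""
        return self.median_pool_coverage / self.pool_size

    def pool_assignment(self) -> np.ndarray:
        """Deterministic round-robin pool index per individual.

        Cases fill pools 0..n_case_pools-1, controls the next
        n_control_pools; pools are homogeneous by group. Individuals are
        ordered cases first, controls after (as in simulate_genotypes).
        """
        case_pools = np.arange(self.n_cases) % self.n_case_pools
        ctrl_pools = (self.n_case_pools
                      + np.arange(self.n_controls) % self.n_control_pools)
        return np.concatenate([case_pools, ctrl_pools])

    def pool_groups(self) -> np.ndarray:
        """Boolean array per pool: True where the pool holds cases."""
        return np.arange(self.n_case_pools + self.n_control_pools) \
            < self.n_case_pools


@dataclass(frozen=True)
class VariantSpec:
    """Ground-truth description of one simulated bi-allelic site."""

    gene: str
    true_maf_cases: float
    true_maf_controls: float
    consequence_class: str = "nonsynonymous"
    aa_change: tuple[str, int, str] | None = None
    annotation_payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("true_maf_cases", "true_maf_controls"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise DesignError(f"{name}={v} outside [0, 0.5]")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise DesignError(
                f"unknown consequence class {self.consequence_class!r}"
            )
        if self.aa_change is not None \
                and self.consequence_class not in CODING_CLASSES:
            raise DesignError("aa_change only allowed for coding classes")


def simulate_genotypes(design: CohortDesign, specs: Sequence[VariantSpec],
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a (n_individuals x n_variants) genotype table of 0/1/2 values.

    Rows are ordered cases first then controls. Genotypes are independent
    Binomial(2, MAF) draws per group (Hardy-Weinberg equilibrium, no LD).
    """
    if not specs:
        raise DesignError("specs must be non-empty")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    p_case = np.array([s.true_maf_cases for s in specs])
    p_ctrl = np.array([s.true_maf_controls for s in specs])
    g_case = rng.binomial(2, p_case, size=(design.n_cases, len(specs)))
    g_ctrl = rng.binomial(2, p_ctrl, size=(design.n_controls, len(specs)))
    return np.vstack([g_case, g_ctrl]).astype(np.int8)


@dataclass
class PoolReads:
    """Per-pool read counts: alt reads and total depth per variant."""

    alt: np.ndarray       # (n_pools_used, n_variants) int
    depth: np.ndarray     # (n_pools_used, n_variants) int
    pool_n: np.ndarray    # individuals per pool
    pool_is_case: np.ndarray  # bool per pool

    def __post_init__(self) -> None:
        if np.any(self.alt > self.depth):
            raise DesignError("alt reads exceed depth")


def pool_and_sequence(genotypes: np.ndarray, design: CohortDesign,
                      rng: np.random.Generator | None = None) -> PoolReads:
    """Pool individuals (homogeneous by group) and draw read counts."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    assignment = design.pool_assignment()
    n_pools = design.n_case_pools + design.n_control_pools
    pool_n = np.bincount(assignment, minlength=n_pools)
    if np.any(pool_n == 0):
        raise DesignError("pool with zero assigned individuals")
    n_var = genotypes.shape[1]
    # alt-chromosome count per pool: sum genotypes of members
    alt_chrom = np.zeros((n_pools, n_var))
    np.add.at(alt_chrom, assignment, genotypes.astype(np.int64))
    frac = alt_chrom / (2 * pool_n)[:, None]
    e = design.seq_error_rate
    frac_obs = frac * (1 - e) + (1 - frac) * e
    depth = rng.poisson(design.median_pool_coverage, size=(n_pools, n_var))
    alt = rng.binomial(depth, frac_obs)
    return PoolReads(alt=alt, depth=depth, pool_n=pool_n,
                     pool_is_case=design.pool_groups())


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (keeps singletons)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def estimate_pooled_counts(reads: PoolReads, design: CohortDesign
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate per-group diploid ALT allele counts from pooled reads.

    Returns ``(alt_case, alt_ctrl, ok)`` arrays over variants. The group
    estimate is round(2 * N_group * f_hat) where f_hat is the
    depth-weighted mean pooled alt fraction sum(alt)/sum(depth) over the
    group's pools with positive depth, debiased for the per-read miscall
    rate e by inverting f_obs = f(1-e) + (1-f)e, i.e.
    f_hat = (f_raw - e)/(1 - 2e), clipped at 0. Without this debiasing the
    error floor alone contributes ~2*N*e phantom alleles per group and
    singletons are never recovered. ``ok`` is False where every pool of
    either group had zero depth (variant must be dropped, reason logged
    upstream). Estimates are clipped to [0, 2 * N_group]; rounding is
    half-away-from-zero so a true singleton's ~1.0 expected count
    survives.
    """
    is_case = reads.pool_is_case
    e = design.seq_error_rate
    out = []
    ok = np.ones(reads.alt.shape[1], dtype=bool)
    for mask, n_group in ((is_case, design.n_cases),
                          (~is_case, design.n_controls)):
        alt = reads.alt[mask].astype(float)
        depth = reads.depth[mask].astype(float)
        tot_depth = depth.sum(axis=0)
        tot_alt = alt.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot_depth > 0, tot_alt / tot_depth, np.nan)
        ok &= tot_depth > 0
        if e > 0:
            frac = np.clip((frac - e) / (1.0 - 2.0 * e), 0.0, 1.0)
        est = _round_half_away(2 * n_group * frac)
        est = np.clip(est, 0, 2 * n_group)
        out.append(est)
    alt_case = np.where(ok, out[0], 0).astype(np.int64)
    alt_ctrl = np.where(ok, out[1], 0).astype(np.int64)
    return alt_case, alt_ctrl, ok


# ---------------------------------------------------------------------------
# Annotation payloads and variant panels
# ---------------------------------------------------------------------------

_NONCODING_SPLIT = (("intronic", 0.45), ("utr3", 0.20), ("utr5", 0.10),
                    ("upstream", 0.15), ("downstream", 0.07), ("splice", 0.03))
#: coding-class proportions among coding variants (~67% nonsynonymous,
#: 26% synonymous, 4% stop gain, 3% frameshift, <1% in-frame indel).
_CODING_SPLIT = (("nonsynonymous", 0.67), ("synonymous", 0.26),
                 ("stop_gain", 0.04), ("frameshift", 0.025),
                 ("inframe_indel", 0.005))
#: share of variants in coding sequence; non-coding variants outnumber
#: coding ones in exon-focused capture that also spans UTRs and promoters.
_CODING_SHARE = 0.35

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _null_annotations(cls: str, true_maf: float,
                      rng: np.random.Generator) -> dict[str, Any]:
    """Realistic annotation payload for a non-planted variant.

    Scores are drawn so that strongly damaging predictions are the
    exception, external population MAFs track the simulated frequency, and
    every field has realistic missingness.
    """
    ann: dict[str, Any] = {}
    if cls in CODING_CLASSES:
        if rng.random() < 0.85:  # CADD available for most coding variants
            ann["cadd_phred"] = float(np.round(rng.gamma(2.0, 4.0), 2))
        if cls == "nonsynonymous" and rng.random() < 0.75:
            ann["condel_label"] = ("deleterious" if rng.random() < 0.15
                                   else "neutral")
    else:
        if rng.random() < 0.6:
            ann["regulome_rank"] = int(rng.integers(1, 8))
    # external population MAFs near the simulated frequency, sometimes absent
    for src in ("maf_1kg", "maf_gnomad", "maf_exac"):
        if rng.random() < 0.7 and true_maf > 0:
            ann[src] = float(np.round(
                true_maf * rng.lognormal(0.0, 0.35), 6))
    ann["vert_conserved"] = int(rng.random() < 0.15)
    ann["invert_conserved"] = int(rng.random() < 0.08)
    ann["evidence_notes"] = int(rng.poisson(0.2))
    return ann


def default_variant_panel(n_variants: int, rng: np.random.Generator,
                          n_genes: int = 200,
                          singleton_fraction: float = 0.5,
                          enriched_fraction: float = 0.0,
                          design: CohortDesign | None = None,
                          ) -> list[VariantSpec]:
    """Build a null (or partially case-enriched) variant panel.

    Roughly half the sites are seeded at singleton-scale frequency (true
    MAF 1/(2N)) — deep pooled sequencing of a capture panel sees a large
    singleton pool — and the rest draw a log-uniform MAF in [1e-3, 0.5].
    ``enriched_fraction`` of the non-singleton rare sites get a 10x higher
    case than control frequency; all other sites are null (equal
    frequencies in both groups).
    """
    if design is None:
        design = CohortDesign()
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    singleton_maf = 1.0 / (2 * design.n_total)
    specs = []
    for i in range(n_variants):
        if rng.random() < singleton_fraction:
            m = singleton_maf
        else:
            m = float(np.exp(rng.uniform(np.log(1e-3), np.log(0.5))))
        cls = _draw_class(rng)
        mc = mt = m
        if (enriched_fraction > 0 and m > singleton_maf and m <= 0.01
                and rng.random() < enriched_fraction):
            mc = min(0.5, 10 * m)
        aa = None
        if cls == "nonsynonymous":
            ref_aa, alt_aa = rng.choice(list(_AA), size=2, replace=False)
            aa = (str(ref_aa), int(rng.integers(1, 500)), str(alt_aa))
        specs.append(VariantSpec(
            gene=genes[int(rng.integers(n_genes))],
            true_maf_cases=mc, true_maf_controls=mt,
            consequence_class=cls, aa_change=aa,
            annotation_payload=_null_annotations(cls, m, rng),
        ))
    return specs


def _draw_class(rng: np.random.Generator) -> str:
    if rng.random() < _CODING_SHARE:
        split = _CODING_SPLIT
    else:
        split = _NONCODING_SPLIT
    u = rng.random()
    acc = 0.0
    for cls, w in split:
        acc += w / sum(w2 for _, w2 in split)
        if u < acc:
            return cls
    return split[-1][0]


def planted_lav_spec(gene: str, rng: np.random.Generator,
                     true_maf_cases: float = 0.02,
                     true_maf_controls: float = 0.002) -> VariantSpec:
    """A variant spec that fully qualifies under the prioritization cascade:

    case-enriched rare nonsynonymous site with a radical-leaning amino-acid
    change, damaging predictions (CADD >= 20, Condel deleterious), absence
    from external populations, and several a-priori evidence lines.
    """
    ref_aa, alt_aa = ("K", "E") if rng.random() < 0.5 else ("D", "W")
    return VariantSpec(
        gene=gene,
        true_maf_cases=true_maf_cases, true_maf_controls=true_maf_controls,
        consequence_class="nonsynonymous",
        aa_change=(ref_aa, int(rng.integers(1, 500)), alt_aa),
        annotation_payload={
            "cadd_phred": float(np.round(rng.uniform(20, 35), 2)),
            "condel_label": "deleterious",
            "vert_conserved": 1, "invert_conserved": 1,
            "evidence_notes": 2,
        },
    )


# ---------------------------------------------------------------------------
# End-to-end cohort build
# ---------------------------------------------------------------------------

def build_variant_records(design: CohortDesign, specs: Sequence[VariantSpec],
                          rng: np.random.Generator | None = None,
                          genotypes: np.ndarray | None = None,
                          ) -> tuple[list[VariantRecord], np.ndarray,
                                     np.ndarray]:
    """Simulate genotypes, pool-sequence them, and estimate count records.

    Returns ``(records, genotypes, kept)`` where ``kept`` marks the specs
    that survived (positive depth in both groups and a non-zero estimated
    cohort ALT count — variants estimated monomorphic are dropped).
    Records are *not* yet minor-allele adjusted.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if genotypes is None:
        genotypes = simulate_genotypes(design, specs, rng)
    reads = pool_and_sequence(genotypes, design, rng)
    alt_case, alt_ctrl, ok = estimate_pooled_counts(reads, design)
    kept = ok & ((alt_case + alt_ctrl) > 0)
    records: list[VariantRecord] = []
    for i, spec in enumerate(specs):
        if not kept[i]:
            continue
        ann = dict(spec.annotation_payload)
        if spec.aa_change is not None:
            ref_aa, posn, alt_aa = spec.aa_change
            ann["aa_change"] = f"p.{ref_aa}{posn}{alt_aa}"
        records.append(VariantRecord(
            chrom="1", pos=i + 1, ref="A", alt="G",
            gene=spec.gene, consequence_class=spec.consequence_class,
            counts=AlleleCounts(
                min_case=int(alt_case[i]),
                maj_case=2 * design.n_cases - int(alt_case[i]),
                min_ctrl=int(alt_ctrl[i]),
                maj_ctrl=2 * design.n_controls - int(alt_ctrl[i]),
            ),
            annotations=ann,
        ))
    return records, genotypes, kept


def write_cohort(outdir: str | Path, design: CohortDesign,
                 specs: Sequence[VariantSpec],
                 rng: np.random.Generator | None = None) -> dict[str, Path]:
    """Simulate a cohort and write VCF + annotation TSV + truth sidecar.

    The JSON sidecar records the design and per-variant true frequencies so
    parameter-recovery tests can compare estimates against the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, _, kept = build_variant_records(design, specs, rng)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    # records carry pos = spec index + 1; rewrite keys by kept order
    write_variants(records, paths["vcf"], paths["annotations"])
    truth = {
        "design": asdict(design),
        "variants": [
            {"gene": s.gene, "true_maf_cases": s.true_maf_cases,
             "true_maf_controls": s.true_maf_controls,
             "consequence_class": s.consequence_class,
             "kept": bool(kept[i])}
            for i, s in enumerate(specs)
        ],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
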