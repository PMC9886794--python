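"""End-to-end orchestration: simulate/load -> adjust -> single-variant ->
gene-based (both singleton policies) -> classify -> prioritize -> enrich ->
summarize.

The run configuration is a YAML (or JSON) file; every threshold has a
documented default matching the study design the package models. All
randomness flows from the single ``seed`` field, so a fixed configuration
reproduces its report bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import aa, genetests, prioritize, simulate, stats
from .enrich import EnrichmentResult, enrich as run_enrichment
from .variants import adjust_minor_allele, read_variants, write_variants

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration with study-design defaults."""

    n_cases: int = 494
    n_controls: int = 572
    pool_size: int = 25
    n_pools: int = 43
    median_pool_coverage: float = 378.12
    seq_error_rate: float = 0.002

    n_variants: int = 5000
    n_genes: int = 200
    singleton_fraction: float = 0.5
    enriched_fraction: float = 0.0

    maf_threshold: float = 0.010
    alpha: float = 0.05
    bonferroni_m: int = 660

    gene_test_resample: int = 10_000
    rho_grid: tuple[float, ...] = genetests.DEFAULT_RHO_GRID
    singleton_policies: tuple[str, ...] = ("included", "excluded")

    cadd_min: float = 15.0
    regulome_max: int = 3
    external_maf_max: float = 0.010
    min_nsv: int = 2

    enrichment_permutations: int = 10_000

    seed: int = 0
    outdir: str = "mitolav_run"

    # optional file inputs; when absent the cohort is simulated
    vcf: str | None = None
    annotations: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in (0, 0.5)")
        # delegate the remaining validation to the component configs
        self.design()
        self.prioritizer_config()

    def design(self) -> simulate.CohortDesign:
        return simulate.CohortDesign(
            n_cases=self.n_cases, n_controls=self.n_controls,
            pool_size=self.pool_size, n_pools=self.n_pools,
            median_pool_coverage=self.median_pool_coverage,
            seq_error_rate=self.seq_error_rate, seed=self.seed,
        )

    def prioritizer_config(self) -> prioritize.PrioritizerConfig:
        return prioritize.PrioritizerConfig(
            p_max=self.alpha, cadd_min=self.cadd_min,
            regulome_max=self.regulome_max,
            external_maf_max=self.external_maf_max, min_nsv=self.min_nsv,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("rho_grid", "singleton_policies"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages and write the report bundle; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s "
                                           "%(message)s"))
    root = logging.getLogger("mitolav")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        return _run(config, outdir, counts)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, counts: dict[str, int]
         ) -> dict[str, Any]:
    rng = np.random.default_rng(config.seed)
    design = config.design()

    # ---- stage 1: simulate or load ------------------------------------
    genotypes = None
    if config.vcf is not None:
        records = read_variants(config.vcf, config.annotations)
        log.info("loaded %d records from %s", len(records), config.vcf)
    else:
        specs = simulate.default_variant_panel(
            config.n_variants, rng, n_genes=config.n_genes,
            singleton_fraction=config.singleton_fraction,
            enriched_fraction=config.enriched_fraction, design=design)
        records, genotypes, kept = simulate.build_variant_records(
            design, specs, rng)
        log.info("simulated %d specs; %d survived pooling (%d dropped "
                 "monomorphic/zero-depth)", len(specs), len(records),
                 len(specs) - len(records))
        write_variants(records, outdir / "variants.vcf",
                       outdir / "annotations.tsv")
    counts["input_records"] = len(records)

    # ---- stage 2: minor-allele adjustment -----------------------------
    records = [adjust_minor_allele(r) for r in records]
    counts["adjusted"] = len(records)

    # ---- stage 3: single-variant association --------------------------
    results = stats.associate(records, maf_threshold=config.maf_threshold)
    threshold = stats.correct_multiplicity(
        results, m=max(len(results), 1), alpha=config.alpha)
    stats.manhattan_table(results).to_csv(outdir / "manhattan.tsv",
                                          sep="\t", index=False)
    counts["associated"] = len(results)

    # ---- stage 4: gene-based tests (both singleton policies) ----------
    gene_rows: list[genetests.GeneTestResult] = []
    if genotypes is not None:
        genes = [r.gene for r in records]
        kept_idx = np.flatnonzero(kept)
        G = genotypes[:, kept_idx]
        phen = np.r_[np.ones(design.n_cases), np.zeros(design.n_controls)]
        gene_rows = genetests.run_gene_scan(
            genes, G, phen, singleton_policies=config.singleton_policies,
            maf_threshold=config.maf_threshold, rho_grid=config.rho_grid,
            n_resample=config.gene_test_resample, seed=config.seed)
    else:
        # pooled counts only: flagged count-resampling approximation
        genes = [r.gene for r in records]
        c_case = np.array([r.counts.min_case for r in records])
        c_ctrl = np.array([r.counts.min_ctrl for r in records])
        n_case = records[0].counts.total_case // 2 if records else 0
        n_ctrl = records[0].counts.total_ctrl // 2 if records else 0
        if records:
            G = genetests.genotypes_from_counts(
                c_case, c_ctrl, n_case, n_ctrl, rng)
            phen = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
            gene_rows = genetests.run_gene_scan(
                genes, G, phen,
                singleton_policies=config.singleton_policies,
                maf_threshold=config.maf_threshold,
                rho_grid=config.rho_grid,
                n_resample=config.gene_test_resample, seed=config.seed,
                mode="count_resampling")
    pd.DataFrame([dataclasses.asdict(g) for g in gene_rows]).to_csv(
        outdir / "gene_tests.tsv", sep="\t", index=False)
    counts["gene_rows"] = len(gene_rows)

    # ---- stage 5: amino-acid classification ---------------------------
    records = aa.classify_table(records)

    # ---- stage 6: prioritization --------------------------------------
    prioritized = prioritize.rank(prioritize.apply_criteria(
        results, config.prioritizer_config()))
    hot = prioritize.hotspot_genes(prioritized, config.min_nsv)
    pd.DataFrame([dataclasses.asdict(p) for p in prioritized]).to_csv(
        outdir / "prioritized.tsv", sep="\t", index=False)
    counts["prioritized"] = len(prioritized)

    # ---- stage 7: gene-set enrichment ---------------------------------
    sig_genes = sorted({g.gene for g in gene_rows if g.significant})
    all_genes = sorted({r.gene for r in records})
    enr_rows: list[EnrichmentResult] = []
    if sig_genes and all_genes:
        # synthetic category: genes carrying any rare variant (illustrative
        # default when no catalog file is supplied)
        rare_genes = sorted({r.gene for r, res in zip(records, results)
                             if res.rarity == "rare"})
        enr_rows = run_enrichment(
            sig_genes, {"rare_variant_genes": rare_genes}, all_genes,
            n_permutations=config.enrichment_permutations,
            rng=np.random.default_rng(config.seed + 7),
            background_name="scan_genes")
    pd.DataFrame([dataclasses.asdict(e) for e in enr_rows]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False)

    # ---- stage 8: summary ---------------------------------------------
    summary = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stage_counts": counts,
        "bonferroni_threshold_variants": threshold,
        "bonferroni_threshold_genes": stats.bonferroni_threshold(
            config.alpha, config.bonferroni_m),
        "panels": {
            "with_singletons": stats.summarize_distributions(
                results, exclude_singletons=False, alpha=config.alpha),
            "without_singletons": stats.summarize_distributions(
                results, exclude_singletons=True, alpha=config.alpha),
        },
        "gene_tiers": {
            "significant": sorted({g.gene for g in gene_rows
                                   if g.significant}),
            "top": sorted({g.gene for g in gene_rows if g.top}),
        },
        "lav": prioritize.lav_summary(prioritized),
        "hotspot_genes": hot,
        "enrichment": [dataclasses.asdict(e) for e in enr_rows],
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str))
    log.info("stage counts: %s", counts)
    return summary
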