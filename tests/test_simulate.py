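"""Cohort simulator: genotype sampling, pooling, count estimation."""

import numpy as np
import pytest

from mitolav.simulate import (CohortDesign, DesignError, PoolReads,
                              VariantSpec, build_variant_records,
                              default_variant_panel, estimate_pooled_counts,
                              planted_lav_spec, pool_and_sequence,
                              simulate_genotypes, write_cohort)
from mitolav.variants import adjust_minor_allele
from mitolav import stats


class TestCohortDesign:
    def test_reference_design_pool_arithmetic(self, study_design):
        assert study_design.n_case_pools + study_design.n_control_pools == 43
        assert study_design.per_sample_coverage == pytest.approx(15.1248)

    def test_pools_homogeneous_and_bounded(self, study_design):
        assignment = study_design.pool_assignment()
        groups = study_design.pool_groups()
        n_cases = study_design.n_cases
        for pool in np.unique(assignment):
            members = np.flatnonzero(assignment == pool)
            is_case = members < n_cases
            assert is_case.all() or (~is_case).all()
            assert is_case.all() == groups[pool]
            assert len(members) <= study_design.pool_size

    @pytest.mark.parametrize("kwargs", [
        dict(seq_error_rate=0.06),
        dict(n_pools=0),
        dict(pool_size=25, n_pools=42),  # 42*25 < 1066
        dict(median_pool_coverage=0.0),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(DesignError):
            CohortDesign(**kwargs)


class TestSimulateGenotypes:
    def test_zero_frequency_gives_all_reference(self, small_design):
        specs = [VariantSpec("G", 0.0, 0.0)]
        g = simulate_genotypes(small_design, specs)
        assert (g == 0).all()

    def test_same_seed_reproduces_bitwise(self, small_design):
        specs = [VariantSpec("G", 0.1, 0.1) for _ in range(20)]
        a = simulate_genotypes(small_design, specs)
        b = simulate_genotypes(small_design, specs)
        assert (a == b).all()

    def test_empirical_maf_converges_to_truth(self, study_design):
        # 5000 replicate variants at MAF 0.02: cohort mean within 0.002
        specs = [VariantSpec("G", 0.02, 0.02) for _ in range(5000)]
        g = simulate_genotypes(study_design, specs)
        maf = g.mean(axis=0) / 2
        assert abs(maf.mean() - 0.02) < 0.002

    def test_bad_frequency_rejected(self):
        with pytest.raises(DesignError):
            VariantSpec("G", 0.7, 0.1)

    def test_aa_change_only_on_coding(self):
        with pytest.raises(DesignError):
            VariantSpec("G", 0.1, 0.1, "intronic", aa_change=("K", 5, "E"))


class TestPoolAndSequence:
    def test_no_alt_no_error_gives_zero_alt_reads(self, small_design):
        design = CohortDesign(**{**small_design.__dict__,
                                 "seq_error_rate": 0.0})
        g = np.zeros((design.n_total, 4), dtype=np.int8)
        reads = pool_and_sequence(g, design)
        assert (reads.alt == 0).all()
        assert (reads.alt <= reads.depth).all()

    def test_alt_read_mean_matches_binomial_expectation(self, rng):
        # pool fraction 0.5 at depth ~378: expected alt 189, mean within 3
        # over 10,000 sites (closed-form binomial expectation oracle)
        design = CohortDesign(n_cases=25, n_controls=25, pool_size=25,
                              n_pools=2, median_pool_coverage=378.0,
                              seq_error_rate=0.0, seed=3)
        g = np.ones((50, 10_000), dtype=np.int8)  # every genotype het
        reads = pool_and_sequence(g, design, rng)
        assert abs(reads.alt.mean() * 378.0 / reads.depth.mean() - 189.0) < 3

    def test_error_rate_sets_background_alt_fraction(self, rng):
        design = CohortDesign(n_cases=25, n_controls=25, pool_size=25,
                              n_pools=2, median_pool_coverage=400.0,
                              seq_error_rate=0.005, seed=3)
        g = np.zeros((50, 5000), dtype=np.int8)
        reads = pool_and_sequence(g, design, rng)
        frac = reads.alt.sum() / reads.depth.sum()
        assert frac == pytest.approx(0.005, abs=3e-4)

    def test_conservation_alt_within_depth(self, small_design, rng):
        specs = [VariantSpec("G", 0.3, 0.3) for _ in range(50)]
        g = simulate_genotypes(small_design, specs, rng)
        reads = pool_and_sequence(g, small_design, rng)
        assert (reads.alt <= reads.depth).all()
        with pytest.raises(DesignError):
            PoolReads(alt=reads.depth + 1, depth=reads.depth,
                      pool_n=reads.pool_n, pool_is_case=reads.pool_is_case)


class TestEstimatePooledCounts:
    def test_all_zero_alt_gives_zero_counts(self, small_design):
        design = CohortDesign(**{**small_design.__dict__,
                                 "seq_error_rate": 0.0})
        g = np.zeros((design.n_total, 3), dtype=np.int8)
        reads = pool_and_sequence(g, design)
        ac, at, ok = estimate_pooled_counts(reads, design)
        assert ok.all() and (ac == 0).all() and (at == 0).all()

    def test_exact_recovery_in_noiseless_limit(self):
        # one carrier chromosome among 25 diploid case individuals at
        # effectively infinite depth and zero error -> case count 1
        design = CohortDesign(n_cases=25, n_controls=25, pool_size=25,
                              n_pools=2, median_pool_coverage=2_000_000,
                              seq_error_rate=0.0, seed=9)
        g = np.zeros((50, 1), dtype=np.int8)
        g[0, 0] = 1  # a case carrier
        reads = pool_and_sequence(g, design)
        ac, at, ok = estimate_pooled_counts(reads, design)
        assert ok[0] and ac[0] == 1 and at[0] == 0

    def test_counts_bounded_by_group_chromosomes(self, small_design, rng):
        specs = [VariantSpec("G", 0.5, 0.5) for _ in range(100)]
        g = simulate_genotypes(small_design, specs, rng)
        reads = pool_and_sequence(g, small_design, rng)
        ac, at, ok = estimate_pooled_counts(reads, small_design)
        assert (ac >= 0).all() and (ac <= 2 * small_design.n_cases).all()
        assert (at >= 0).all() and (at <= 2 * small_design.n_controls).all()

    def test_singleton_recovery_rate_at_study_depth(self):
        """A cohort singleton is re-estimated as count 1 more often than
        any other value at ~378x; the estimate is unbiased.

        With ~15x per sample a singleton contributes only ~8 expected
        carrier reads, so Poisson read noise leaves the rounded estimate
        with an SD near 0.5: exact recovery tops out near 60% at a
        per-read miscall rate of 0.001 (repeated-simulation oracle).
        """
        design = CohortDesign(seq_error_rate=0.001, seed=1)
        rng = np.random.default_rng(77)
        estimates = []
        for _ in range(250):
            g = np.zeros((design.n_total, 1), dtype=np.int8)
            g[rng.integers(design.n_total), 0] = 1
            reads = pool_and_sequence(g, design, rng)
            ac, at, ok = estimate_pooled_counts(reads, design)
            assert ok[0]
            estimates.append(int(ac[0] + at[0]))
        estimates = np.array(estimates)
        assert (estimates == 1).mean() > 0.5
        assert abs(estimates.mean() - 1.0) < 0.15


class TestBuildAndWrite:
    def test_monomorphic_estimates_dropped(self, small_design, rng):
        specs = [VariantSpec("G", 0.0, 0.0), VariantSpec("G", 0.3, 0.3)]
        records, _, kept = build_variant_records(small_design, specs, rng)
        assert not kept[0] and kept[1]
        assert len(records) == 1

    def test_cohort_roundtrip_files(self, tmp_path, small_design, rng):
        specs = default_variant_panel(40, rng, n_genes=5,
                                      design=small_design)
        paths = write_cohort(tmp_path, small_design, specs, rng)
        assert paths["vcf"].exists() and paths["truth"].exists()
        from mitolav.variants import read_variants
        records = read_variants(paths["vcf"], paths["annotations"])
        assert 0 < len(records) <= 40
        assert all(r.gene.startswith("GENE") for r in records)

    def test_default_panel_class_mix(self, rng):
        specs = default_variant_panel(4000, rng)
        from mitolav.variants import CODING_CLASSES
        coding = [s for s in specs if s.consequence_class in CODING_CLASSES]
        nsv = [s for s in coding
               if s.consequence_class == "nonsynonymous"]
        # non-coding outnumbers coding; ~67% of coding is nonsynonymous
        assert len(coding) < len(specs) - len(coding)
        assert abs(len(nsv) / len(coding) - 0.67) < 0.06
        assert all(s.aa_change is not None for s in nsv)

    def test_planted_enrichment_detected_in_majority(self):
        """0.02 vs 0.002 planted case-enrichment reaches p <= 0.05 with
        the enriched direction in a majority of replicates."""
        detected = 0
        for rep in range(12):
            design = CohortDesign(seed=300 + rep)
            rng = np.random.default_rng(300 + rep)
            recs, _, _ = build_variant_records(
                design, [planted_lav_spec("G", rng)], rng)
            if not recs:
                continue
            res = stats.associate([adjust_minor_allele(recs[0])])[0]
            detected += int(res.p_value <= 0.05 and res.enriched)
        assert detected >= 7
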