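# Methods

## Study design being modeled

The package targets candidate-gene association studies of extreme human
longevity in which a centenarian cohort and a matched control cohort are
sequenced as equimolar DNA pools. The default design is 494 cases and 572
controls combined into 43 pools of at most 25 individuals each (20 case
pools + 23 control pools; pools are homogeneous by group, membership is a
deterministic round-robin), with a median per-pool depth of 378.12×,
equivalent to ~15× per sample. All of these are `CohortDesign` parameters.

## Synthetic cohort generator

The generator exists because cohorts of this kind are not publicly
deposited; it is first-class, tested code, not a fixture.

* **Genotypes.** Individual genotypes are Binomial(2, MAF) per group
  (Hardy–Weinberg, no linkage disequilibrium, no relatedness). The default
  variant panel seeds ~50% of sites at singleton-scale frequency
  (true MAF = 1/2N; deep sequencing of a capture panel sees a large
  singleton pool) and draws the rest log-uniformly in [10⁻³, 0.5],
  approximating a 1/f site-frequency spectrum. Consequence classes follow
  the coding/non-coding mix of exon-focused capture (~35% coding; among
  coding ~67% nonsynonymous, 26% synonymous, 4% stop gain, ~3%
  frameshift, <1% in-frame indel).
* **Reads.** Per pool and site, depth is Poisson around the median pool
  coverage; alt reads are Binomial(depth, f′) with
  f′ = f(1−e) + (1−f)e, where f is the pool's alt-chromosome fraction and
  e the per-read miscall rate (default 0.002, valid range [0, 0.05]).
* **Count estimation.** Group diploid ALT counts are
  round(2N · f̂) with f̂ = (Σalt/Σdepth − e)/(1 − 2e) over the group's
  pools, clipped to [0, 1]; rounding is half-away-from-zero so a true
  singleton's ≈1.0 expected count survives. The miscall debiasing is
  essential: the raw error floor alone contributes ~2N·e ≈ 2–4 phantom
  alleles per group per site. In a real study e would be estimated from
  monomorphic sites; the simulator passes the generative value through.
  Variants with zero estimated cohort count are dropped as monomorphic;
  variants with zero group depth are dropped with a logged reason.
* **Annotations.** Null variants draw realistic payloads: CADD-phred ~
  Gamma(2, 4) for coding sites (≈14% reach the "possibly damaging" 15
  threshold), Condel deleterious ≈15% of scored nsVs, Regulome ranks
  uniform on 1–7 for non-coding sites, external population MAFs lognormal
  around the simulated frequency, sparse conservation flags and
  Poisson(0.2) evidence notes — all with realistic missingness. Planted
  "fully qualifying" variants get case/control MAFs 0.02/0.002, a
  radical-leaning amino-acid change, CADD ≥ 20, Condel deleterious,
  absence from external populations, and both conservation flags.

**What the generator does not emulate** — LD, population structure,
relatedness, batch/capture-efficiency variation, alignment and calling
artifacts, overdispersed (non-Poisson) depth, strand-biased errors.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real pooled data.

### Known properties at study depth (measured, by simulation)

* A cohort singleton is re-estimated as exactly 1 in ~60% of replicates at
  e = 0.001 (~83% ceiling even at e = 0): only ~8 carrier reads are
  expected, so Poisson noise leaves the rounded estimate with SD ≈ 0.5.
  The estimate is unbiased.
* Fisher type-I error at nominal 0.05 on *estimated* counts is ≈ 0.062 for
  common variants: the finite read depth adds ~2N/D ≈ 13% variance per
  group on top of the (conservative, exact) 0.045 rate on true counts.
* Under the null, *common* variants split 50/50 between
  centenarian-enriched and depleted. Rare variants lean enriched (~54%
  excluding singletons): with fewer case than control chromosomes
  (988 vs 1144), an equal minor-count split already gives the cases the
  higher frequency, and a strict-inequality enrichment definition counts
  it as enriched. This is an intrinsic property of the definition at low
  counts, not an estimator artifact.

## Single-variant statistics

The two-sided Fisher exact p uses the minimum-likelihood rule: the sum of
hypergeometric probabilities, at the observed margins, of all tables no
more probable than the observed one. It is computed directly on scipy's
hypergeometric pmf with a relative tie tolerance of 10⁻¹⁰ — wide enough to
absorb float rounding in exactly-tied (mirror-symmetric) tables, narrow
enough never to pull in a genuinely more probable table; the test suite
checks equality with exact-rational exhaustive enumeration to 10⁻¹².
Reported odds ratios use the Haldane–Anscombe 0.5 correction when any cell
is zero (reporting only, never the p-value). Benjamini–Hochberg q-values
take an explicit total test count m ≥ the number of reported p-values;
Bonferroni thresholds are α/m (0.05/660 = 7.58×10⁻⁵ for the default
gene panel). Rarity (cohort MAF ≤ 0.010, boundary inclusive), singleton
status (cohort minor count exactly 1) and enrichment (strict inequality;
ties are depleted) are decided in exact integer/rational arithmetic.

## Gene-based tests

The null model is an intercept-only logistic fit (no covariates):
residuals r = y − ȳ. For a gene's genotype matrix G (n × m, 0/1/2) and
weights w, the score vector is u = w ⊙ (Gᵀ r) and

* kernel statistic: Q = Σ u² with w = Beta(1, 25) density at the sample
  MAF (the field's standard rare-variant up-weighting);
* combined statistic: variants are partitioned at the rarity threshold;
  the rare partition keeps Beta(1, 25), the common partition uses
  Beta(0.5, 0.5), and the two kernel statistics are added with equal
  weight (φ = 0.5, configurable) by scaling the concatenated weights —
  a gene with an empty partition reduces exactly to the single-partition
  test;
* burden statistic: Q_B = (Σ u)², and the optimal combination scans
  Q_ρ = (1−ρ)Q + ρQ_B over ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}
  (ρ = 1 nudged to 0.999 in the mixture so the null keeps full support).

**Null distribution.** Under label permutation, u has exact covariance
(Σr²)/(n−1) · Zcᵀ Zc with Zc the column-centered weighted genotypes, so
each statistic is a quadratic form whose null law is a mixture
Σ λ_k χ²₁. Tail probabilities use exact numerical inversion of the
characteristic function (Imhof's method) — chosen over pure four-moment
matching because, on 2,500 simulated null genes (n = 200, low-frequency
spectrum), inversion gives KS D = 0.024 against uniform versus D = 0.031
(a borderline-failing calibration) for the Liu-modified four-moment
approximation. The four-moment method remains the far-tail (p < 10⁻⁸) and
non-convergence fallback, and the exact single-eigenvalue case is the
χ²₁ tail.

**Optimal-test correction.** The per-ρ four-moment p-values define the
min-p statistic (only their monotone mapping of Q_ρ matters); the
anti-conservative bias of minimizing over the grid is corrected by
recomputing the min-p statistic under the null — by seeded Gaussian
resampling of u at large n, or by seeded phenotype permutation on small
instances. p_optimal can therefore exceed the per-ρ minimum; ρ_optimal is
the argmin.

**Small samples.** Phenotype permutation is the universal oracle, and it
is also the default method whenever n ≤ 100 or the kernel has fewer than
3 positive eigenvalues: at such sizes the permutation law has discrete
atoms of 0.01–0.14 probability that no continuous approximation can
match. The calibration claim is correspondingly scoped: the analytic path
is validated on low-frequency spectra with expected minor-allele counts
≥ ~8; ultra-rare spectra (expected counts ~2) make any continuous tail
approximation conservative.

**Pooled data.** Individual-level tests require genotypes, which pooled
sequencing does not observe. When only group counts exist, the scan runs
in a count-resampling mode — minor alleles scattered uniformly over each
group's chromosomes — and every result row is flagged
`method="count_resampling"` as the explicit approximation it is.

Scans run twice, including and excluding singletons (cohort minor count
1); untestable genes (no polymorphic variants after filtering) are
reported, never silently dropped. Genes at p ≤ 0.05 in at least one test
are flagged significant; p ≤ 0.01 flags the top tier.

## Amino-acid substitution classification

Each of the 20 canonical residues carries four R-group properties in a
packaged, editable TSV: charge (K/R/H positive, D/E negative), polarity
(S/T/C/Y/N/Q/D/E/K/R/H polar), hydropathy by Kyte–Doolittle sign (> 0
hydrophobic, < −1 hydrophilic, [−1, 0] neutral) and size class by residue
volume (tiny < 95 Å³, small 95–125, medium 125–160, large ≥ 160). A
substitution is C with zero property differences, R with ≥ 2 differences
*including* size (read literally: two differences without a size change
stay NC), otherwise NC. The diff vector is reported with every label so
boundary conventions are auditable; under this table, e.g., S1378G and
D1352E in the C-terminal region of LRPPRC both classify NC (one property
difference each), while K→E is R (charge + size). Non-canonical residue
codes (B, Z, X, J, U, O, `*`) are rejected by name; stop gains have no
alternate residue and are never classified.

## Prioritization cascade

Criterion 1 (p ≤ 0.05) is the only hard gate. Enrichment direction is a
priority key, not a gate — depleted variants survive and rank lower,
matching the observation that a prioritized set can legitimately contain
~12% depleted variants. Predicted impact for nsVs requires an NC/R label
*and* a damaging prediction (Condel deleterious or CADD-phred ≥ 15 by
default; 20 = "likely damaging"); other coding classes use the prediction
scores alone (they have no substitution label); non-coding variants need
Regulome rank ≤ 3 or a curated regulatory-evidence flag. External rarity
corroboration fails if any external population MAF exceeds 0.010 and
passes on total absence (absence is the strongest rarity signal). The
evidence count sums conservation flags and curated evidence lines.
Missing annotation always yields an explicit `unknown`, ranked between
pass and fail; ranking is lexicographic in the criteria's listed order,
then ascending p, then genomic coordinate — deterministic, stable under
input permutation, with no invented composite score. Hotspot genes carry
≥ 2 prioritized nsVs (configurable).

## Gene-set enrichment

Empirical over-representation p-values are
(1 + #{permutations with overlap ≥ observed})/(B + 1) with B = 10,000
seeded draws of |query|-sized sets uniformly (without replacement) from
the chosen background — whole genome (~21,000), mitochondrial proteome
(~2,220) or candidate panel (~660) scale. Uniform gene sampling (no
conditioning on gene length or SNP density) is the documented default;
the permutation p converges to the hypergeometric upper tail, which the
test suite verifies on planted configurations. Catalog preprocessing
keeps disease associations at p ≤ 10⁻⁸ and lifespan/aging/longevity
associations at p ≤ 10⁻⁶ (both inclusive), maps traits to disease
categories through an editable TSV, and deduplicates per
(gene, trait, study) keeping the most significant row (ties: first in
input order).

## Numerical and engineering choices

* Exact integer or rational arithmetic wherever a threshold comparison
  could be corrupted by binary floats (rarity boundary, enrichment ties,
  minor-allele adjustment at exactly 50%).
* The minor-allele adjustment swaps REF/ALT only on a strict cohort
  majority (a 50/50 tie keeps ALT) and is idempotent; group frequencies
  may legitimately exceed 0.5 after cohort-level adjustment.
* Monte-Carlo tails always use the (1 + k)/(B + 1) form, so a reported
  p is never 0; permutation exceedance comparisons carry a 10⁻⁹ relative
  guard against float noise in recomputed statistics.
* All randomness flows through numpy Generators seeded from a single run
  seed; fixed seed ⇒ byte-identical outputs, including the pipeline's
  summary JSON.
* Multi-allelic VCF sites are split into one record per ALT with per-ALT
  counts; positions are 1-based internally (BED inputs are 0-based
  half-open); unknown annotation columns pass through verbatim; missing
  annotation fields are an explicit missing state, never imputed.
* Default problem sizes in the test and acceptance runs (e.g. 2,000 null
  genes at n = 200; 10,000-variant null panels; 10–50 planted-recovery
  replicates) were chosen so the whole suite completes in minutes on a
  single CPU while keeping Monte-Carlo error well below every asserted
  band; each acceptance entry records the size used.

## Limitations

* The generator's independence assumptions (no LD, independent variants,
  Poisson depth) understate the correlation structure of real capture
  data; gene-test calibration on real data would additionally face LD
  within genes.
* Fisher on estimated pooled counts is mildly anti-conservative (~0.06 at
  nominal 0.05 at 15× per sample) because read-sampling variance is not
  propagated into the test; a read-aware likelihood test would remove
  this but is outside the scope of the count-based design.
* Singleton recovery at ~15× per sample is ~60%, so singleton-sensitive
  summaries (singleton share, with/without-singleton contrasts) reflect
  the estimator's resolution as much as the underlying spectrum.
* The strict-inequality enrichment definition is directionally biased for
  very small minor counts when group sizes differ; directionality
  summaries are most interpretable for common variants or large counts.
* The permutation enrichment conditions only on set sizes; if real
  category membership correlates with gene length, uniform sampling will
  overstate significance.
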