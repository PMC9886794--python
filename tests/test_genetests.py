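"""Gene-level kernel/combined/optimal tests and their permutation oracle."""

import numpy as np
import pytest
from scipy.stats import chi2

from mitolav import genetests as gt


@pytest.fixture
def balanced_null_60():
    y = np.zeros(60)
    y[:30] = 1
    return gt.null_model(y)


def toy_genotypes(rng, n=60, m=4, maf_lo=0.05, maf_hi=0.3):
    mafs = rng.uniform(maf_lo, maf_hi, size=m)
    G = rng.binomial(2, mafs, size=(n, m)).astype(float)
    if not (G.std(axis=0) > 0).any():
        G[0, 0] = 1
    return G


class TestNullModel:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(494), np.zeros(572)]
        null = gt.null_model(y)
        assert null.mu == pytest.approx(494 / 1066)
        assert null.residuals[:494].mean() == pytest.approx(1 - 494 / 1066)
        assert null.residuals[494:].mean() == pytest.approx(-494 / 1066)
        assert null.residuals.sum() == pytest.approx(0.0, abs=1e-9)
        # sum of Bernoulli variance weights = n * p(1-p)
        assert null.n * null.variance_weight == pytest.approx(
            1066 * (494 / 1066) * (572 / 1066))

    def test_single_class_rejected(self):
        with pytest.raises(gt.GeneTestError):
            gt.null_model(np.ones(10))
        with pytest.raises(gt.GeneTestError):
            gt.null_model(np.r_[np.ones(3), 2 * np.ones(3)])


class TestKernelStatistic:
    def test_all_reference_untestable(self, balanced_null_60):
        with pytest.raises(gt.UntestableGene):
            gt.kernel_statistic(np.zeros((60, 3)), balanced_null_60,
                                np.ones(3))

    def test_single_variant_reduces_to_score_test(self, rng,
                                                  balanced_null_60):
        G = toy_genotypes(rng, m=1, maf_lo=0.2, maf_hi=0.4)
        q = gt.kernel_statistic(G, balanced_null_60, np.ones(1))
        u = float(G[:, 0] @ balanced_null_60.residuals)
        assert q == pytest.approx(u ** 2)
        # moment matching equals the classical 1-df score-test p
        lam = gt.kernel_eigenvalues(G, balanced_null_60, np.ones(1))
        p = gt.pvalue_quadratic_form(q, lam)
        var_u = balanced_null_60.score_scale * float(
            ((G - G.mean(0)) ** 2).sum())
        p_score = float(chi2.sf(q / var_u, 1))
        assert p == pytest.approx(p_score, abs=1e-6)

    def test_weight_homogeneity(self, rng, balanced_null_60):
        G = toy_genotypes(rng)
        w = np.ones(G.shape[1])
        assert gt.kernel_statistic(G, balanced_null_60, 2 * w) \
            == pytest.approx(4 * gt.kernel_statistic(G, balanced_null_60,
                                                     w))


class TestQuadraticFormPvalue:
    def test_single_eigenvalue_exact_chi2(self):
        for lam, q in ((2.0, 3.7), (0.5, 0.01), (10.0, 45.0)):
            p = gt.pvalue_quadratic_form(q, np.array([lam]))
            assert p == pytest.approx(float(chi2.sf(q / lam, 1)), abs=1e-8)

    def test_zero_statistic_gives_one(self):
        assert gt.pvalue_quadratic_form(0.0, np.array([1.0, 2.0])) == 1.0

    def test_no_positive_eigenvalues_rejected(self):
        with pytest.raises(gt.GeneTestError):
            gt.pvalue_quadratic_form(1.0, np.array([0.0, 0.0]))

    def test_liu_and_imhof_agree_moderately(self, rng):
        # two routes to the same tail; Imhof is exact, Liu approximate
        for _ in range(20):
            lam = rng.uniform(0.2, 3.0, size=6)
            q = float(rng.uniform(0.5, 3) * lam.sum())
            p_i = gt.imhof_pvalue(q, lam)
            p_l = gt.liu_pvalue(q, lam)
            assert p_i is not None
            assert p_l == pytest.approx(p_i, abs=0.02)

    def test_isf_inverts_liu(self, rng):
        lam = rng.uniform(0.5, 2.0, size=5)
        for p in (0.5, 0.05, 0.001):
            q = gt._quadform_isf(p, lam)
            assert gt.liu_pvalue(q, lam) == pytest.approx(p, rel=1e-6)


class TestCombinedTest:
    def test_only_rare_reduces_to_kernel(self, rng):
        G = toy_genotypes(rng, n=400, m=5, maf_lo=0.002, maf_hi=0.012)
        null = gt.null_model(np.r_[np.ones(200), np.zeros(200)])
        # rarity threshold above every sample MAF: common partition empty
        threshold = float(gt._genotype_mafs(G).max()) + 1e-9
        p_comb, q_comb = gt.combined_test(G, null, maf_threshold=threshold,
                                          method="analytic")
        p_rare, q_rare = gt.rare_kernel_test(G, null, method="analytic")
        assert q_comb == pytest.approx(q_rare, rel=1e-12)
        assert p_comb == pytest.approx(p_rare, abs=1e-10)

    def test_only_common_uses_common_weights(self, rng):
        G = toy_genotypes(rng, n=400, m=4, maf_lo=0.1, maf_hi=0.4)
        null = gt.null_model(np.r_[np.ones(200), np.zeros(200)])
        p_comb, _ = gt.combined_test(G, null, method="analytic")
        mafs = gt._genotype_mafs(G)
        w = gt.beta_maf_weights(mafs, 0.5, 0.5)
        q = gt.kernel_statistic(G, null, w)
        lam = gt.kernel_eigenvalues(G, null, w)
        assert p_comb == pytest.approx(
            gt.pvalue_quadratic_form(q, lam), abs=1e-10)


class TestOptimalTest:
    def test_single_variant_all_rho_equal_burden(self, rng,
                                                 balanced_null_60):
        G = toy_genotypes(rng, m=1, maf_lo=0.2, maf_hi=0.4)
        p_opt, rho = gt.optimal_test(G, balanced_null_60)
        p_kernel, _ = gt.rare_kernel_test(G, balanced_null_60,
                                          method="analytic")
        # with one variant the kernel and burden tests coincide
        assert p_opt == pytest.approx(p_kernel, abs=1e-10)

    def test_directional_signal_pulls_rho_toward_burden(self):
        """Uniformly case-enriched variants select a burden-leaning rho,
        while a sign-alternating signal selects the pure kernel end
        (rho = 0). Oracle: direct grid evaluation of per-rho p-values."""
        rng = np.random.default_rng(3)
        n, m = 80, 6
        y = np.zeros(n)
        y[:40] = 1
        null = gt.null_model(y)
        G_dir = np.zeros((n, m))
        G_alt = np.zeros((n, m))
        for j in range(m):
            G_dir[rng.choice(40, size=8, replace=False), j] = 1
            off = 0 if j % 2 == 0 else 40
            G_alt[off + rng.choice(40, size=8, replace=False), j] = 1
        _, rho_dir = gt.optimal_test(G_dir, null,
                                     rng=np.random.default_rng(0))
        _, rho_alt = gt.optimal_test(G_alt, null,
                                     rng=np.random.default_rng(0))
        assert rho_alt == 0.0
        assert rho_dir > rho_alt

        # rho_optimal is exactly the argmin of grid evaluation
        w = gt.beta_maf_weights(gt._genotype_mafs(G_dir))
        u = w * (G_dir.T @ null.residuals)
        grid, lams = gt._grid_setup(G_dir, null, w, gt.DEFAULT_RHO_GRID)
        p_grid = [gt.liu_pvalue((1 - r) * float(u @ u)
                                + r * float(u.sum() ** 2), lam)
                  for r, lam in zip(grid, lams)]
        assert rho_dir == gt.DEFAULT_RHO_GRID[int(np.argmin(p_grid))]

    def test_reproducible_under_fixed_seed(self, rng, balanced_null_60):
        G = toy_genotypes(rng)
        p1, r1 = gt.optimal_test(G, balanced_null_60,
                                 rng=np.random.default_rng(42))
        p2, r2 = gt.optimal_test(G, balanced_null_60,
                                 rng=np.random.default_rng(42))
        assert p1 == p2 and r1 == r2

    def test_pvalue_in_unit_interval(self, rng, balanced_null_60):
        for _ in range(5):
            G = toy_genotypes(rng)
            p, rho = gt.optimal_test(G, balanced_null_60,
                                     n_resample=5000,
                                     rng=np.random.default_rng(1))
            assert 0.0 < p <= 1.0
            assert 0.0 <= rho <= 1.0


class TestPermutationPath:
    def test_small_sample_auto_uses_permutation(self, rng,
                                                balanced_null_60):
        """At n=60 the auto method is permutation: two different seeds give
        close but not identical p (Monte-Carlo), and both match a direct
        re-implementation within MC noise."""
        G = toy_genotypes(rng)
        p1, _ = gt.rare_kernel_test(G, balanced_null_60, n_perm=20_000,
                                    rng=np.random.default_rng(1))
        p2, _ = gt.rare_kernel_test(G, balanced_null_60, n_perm=20_000,
                                    rng=np.random.default_rng(2))
        se = np.sqrt(p1 * (1 - p1) / 20_000)
        assert abs(p1 - p2) < 5 * np.sqrt(2) * se

    def test_permutation_matches_analytic_at_large_n(self, rng):
        n = 600
        y = np.zeros(n)
        y[:300] = 1
        null = gt.null_model(y)
        G = toy_genotypes(rng, n=n, m=5, maf_lo=0.1, maf_hi=0.3)
        p_a, _ = gt.rare_kernel_test(G, null, method="analytic")
        p_p, _ = gt.rare_kernel_test(G, null, method="permutation",
                                     n_perm=50_000,
                                     rng=np.random.default_rng(5))
        se = max(np.sqrt(p_p * (1 - p_p) / 50_000), 1e-4)
        assert abs(p_a - p_p) < 4 * se + 0.01


class TestGeneScan:
    def test_planted_burden_flagged_under_both_policies(self):
        rng = np.random.default_rng(10)
        n = 400
        y = np.r_[np.ones(200), np.zeros(200)]
        genes = ["NULL"] * 4 + ["HIT"] * 4
        G = np.zeros((n, 8))
        G[:, :4] = rng.binomial(2, 0.05, size=(n, 4))
        # strong planted burden: carriers concentrated in cases
        for j in range(4, 8):
            case_carriers = rng.choice(200, size=24, replace=False)
            ctrl_carriers = 200 + rng.choice(200, size=4, replace=False)
            G[case_carriers, j] = 1
            G[ctrl_carriers, j] = 1
        res = gt.run_gene_scan(genes, G, y, n_resample=2000, seed=0)
        hit = {(r.singleton_policy): r for r in res if r.gene == "HIT"}
        assert hit["included"].significant and hit["excluded"].significant

    def test_exclude_singletons_drops_count_one_columns(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        G = np.zeros((100, 2))
        G[0, 0] = 1           # singleton
        G[:20, 1] = 1         # common-ish
        res = gt.run_gene_scan(["G1", "G1"], G, y, n_resample=1000, seed=0)
        by_policy = {r.singleton_policy: r for r in res}
        assert by_policy["included"].n_variants_used == 2
        assert by_policy["excluded"].n_variants_used == 1

    def test_untestable_gene_reported_not_dropped(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        G = np.zeros((60, 1))
        res = gt.run_gene_scan(["EMPTY"], G, y, seed=0)
        assert all(r.untestable for r in res)
        assert len(res) == 2  # one row per singleton policy

    def test_genotypes_from_counts_preserves_counts(self, rng):
        cc = np.array([5, 1, 0])
        ct = np.array([2, 0, 7])
        G = gt.genotypes_from_counts(cc, ct, 50, 60, rng)
        assert G.shape == (110, 3)
        np.testing.assert_array_equal(G[:50].sum(axis=0), cc)
        np.testing.assert_array_equal(G[50:].sum(axis=0), ct)
        assert G.max() <= 2
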