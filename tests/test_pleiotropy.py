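import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pleiogene import pleiotropy as pl
from pleiogene.pleiotropy import (
    PleioPairResult,
    cochran_q,
    decorrelate_z,
    direct_fdr_method,
    effect_correlation,
    estimate_sigma_sq,
    estimate_z_correlation,
    fdr_bh,
    fdr_by,
    hypergeometric_enrichment,
    max_p_method,
    overall_pleiotropy_lrt,
    placo_test,
    product_normal_tail,
    shared_gene_summary,
)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_bh(p):
    """Textbook step-up BH: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def brute_force_by(p):
    c = sum(1.0 / k for k in range(1, len(p) + 1))
    return np.minimum(brute_force_bh(p) * c, 1.0)


def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) by explicit combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


# ---------------------------------------------------------------------------

class TestZCorrelation:
    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(0)
        z1, z2 = rng.standard_normal((2, 20_000))
        assert estimate_z_correlation(z1, z2) == pytest.approx(0.0, abs=3 / np.sqrt(20_000))

    def test_overlap_recovered(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=20_000)
        assert estimate_z_correlation(z[:, 0], z[:, 1]) == pytest.approx(0.3, abs=0.03)

    def test_identical_vectors_give_one(self):
        z = np.random.default_rng(2).standard_normal(5000)
        assert estimate_z_correlation(z, z) == pytest.approx(1.0)

    def test_signal_genes_trimmed_before_estimation(self):
        rng = np.random.default_rng(3)
        z1, z2 = rng.standard_normal((2, 5000))
        # plant strong concordant signal that would inflate a naive estimate
        z1[:100] = z2[:100] = 20.0
        assert abs(estimate_z_correlation(z1, z2)) < 0.05

    def test_few_genes_warns(self):
        with pytest.warns(UserWarning):
            estimate_z_correlation(np.zeros(10), np.zeros(10))


class TestDecorrelate:
    def test_zero_rho_is_identity(self):
        z1, z2 = np.array([1.0, -2.0]), np.array([0.5, 3.0])
        a, b = decorrelate_z(z1, z2, 0.0)
        np.testing.assert_allclose(a, z1)
        np.testing.assert_allclose(b, z2)

    def test_removes_correlation_genome_wide(self):
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=20_000)
        a, b = decorrelate_z(z[:, 0], z[:, 1], 0.5)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.0, abs=3 / np.sqrt(20_000))
        assert np.var(a) == pytest.approx(1.0, abs=0.05)

    def test_symmetric_in_the_two_traits(self):
        a, b = decorrelate_z(1.3, -0.7, 0.4)
        b2, a2 = decorrelate_z(-0.7, 1.3, 0.4)
        assert a == pytest.approx(a2) and b == pytest.approx(b2)

    def test_entangled_traits_rejected(self):
        with pytest.raises(ValueError):
            decorrelate_z(1.0, 1.0, 0.995)


class TestProductNormalTail:
    def test_zero_statistic_gives_one(self):
        assert product_normal_tail(0.0) == 1.0

    def test_scaling_identity(self):
        assert product_normal_tail(2.0, 2.0, 1.0) == pytest.approx(
            product_normal_tail(1.0, 1.0, 1.0), rel=1e-12
        )

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        n = 10**7
        prod = np.abs(rng.standard_normal(n) * rng.standard_normal(n))
        for t in (0.5, 1.0, 2.0):
            mc = float(np.mean(prod >= t))
            se = np.sqrt(mc * (1 - mc) / n)
            assert product_normal_tail(t) == pytest.approx(mc, abs=3 * se)

    def test_monotone_decreasing_in_t(self):
        ts = np.linspace(0, 10, 50)
        ps = product_normal_tail(ts)
        assert (np.diff(ps) <= 1e-15).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            product_normal_tail(np.nan)

    def test_deep_tail_positive(self):
        assert 0 < product_normal_tail(200.0) < 1e-60


class TestSigmaEstimate:
    def test_standard_normal_floored_at_one(self):
        z = np.random.default_rng(6).standard_normal(10_000)
        assert estimate_sigma_sq(z) == pytest.approx(1.0, abs=0.05)

    def test_scaled_z_gives_scaled_variance(self):
        z = 1.5 * np.random.default_rng(7).standard_normal(10_000)
        assert estimate_sigma_sq(z) == pytest.approx(2.25, abs=3 * 2.25 * np.sqrt(2 / 10_000))

    def test_constant_vector_floored(self):
        assert estimate_sigma_sq(np.zeros(100)) == 1.0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma_sq(np.zeros(10))


class TestPlacoTest:
    def test_zero_z_gives_p_one(self):
        T, p = placo_test(0.0, 1.7, 1.0, 1.0)
        assert T == 0.0 and p == 1.0

    def test_symmetry_under_trait_swap(self):
        T1, p1 = placo_test(1.2, -2.0, 1.5, 2.5)
        T2, p2 = placo_test(-2.0, 1.2, 2.5, 1.5)
        assert T1 == T2 and p1 == pytest.approx(p2, rel=1e-12)

    def test_unit_sigmas_reduce_to_h00_tail(self):
        T, p = placo_test(1.5, 2.0, 1.0, 1.0)
        assert p == pytest.approx(product_normal_tail(3.0), rel=1e-12)

    def test_sigma_below_one_rejected(self):
        with pytest.raises(ValueError):
            placo_test(1.0, 1.0, 0.5, 1.0)

    @pytest.mark.parametrize(
        "s1,s2,seed", [(1.0, 1.0, 10), (2.25, 1.0, 11), (1.0, 4.0, 12)]
    )
    def test_type_i_error_controlled_under_sub_nulls(self, s1, s2, seed):
        """Empirical rejection under H00 / H10 / H01 stays at or below nominal."""
        rng = np.random.default_rng(seed)
        n = 10_000
        z1 = np.sqrt(s1) * rng.standard_normal(n)
        z2 = np.sqrt(s2) * rng.standard_normal(n)
        _, p = placo_test(z1, z2, max(s1, 1.0), max(s2, 1.0))
        alpha = 0.05
        assert np.mean(p < alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)

    def test_p_monotone_in_abs_T(self):
        z = np.linspace(0.1, 5, 30)
        _, p = placo_test(z, np.ones_like(z), 2.0, 1.5)
        assert (np.diff(p) <= 1e-15).all()

    def test_decorrelation_restores_type_i_under_pure_overlap(self):
        """Sample overlap alone inflates the naive product test; whitening fixes it."""
        rng = np.random.default_rng(13)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10_000)
        _, p_naive = placo_test(z[:, 0], z[:, 1], 1.0, 1.0)
        rho = estimate_z_correlation(z[:, 0], z[:, 1])
        a, b = decorrelate_z(z[:, 0], z[:, 1], rho)
        _, p_white = placo_test(a, b, 1.0, 1.0)
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / 10_000)
        assert np.mean(p_white < 0.05) <= bound
        assert np.mean(p_naive < 0.05) > np.mean(p_white < 0.05)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)
        assert fdr_by([0.03])[0] == pytest.approx(0.03)

    def test_identical_ps_unchanged_by_bh(self):
        np.testing.assert_allclose(fdr_bh([0.2] * 5), 0.2)

    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=100)
    )
    def test_matches_brute_force_step_up(self, ps):
        np.testing.assert_allclose(fdr_bh(ps), brute_force_bh(ps), rtol=1e-12)
        np.testing.assert_allclose(fdr_by(ps), brute_force_by(ps), rtol=1e-12)

    def test_empty_input(self):
        assert fdr_bh([]).size == 0


class TestComparatorMethods:
    def test_single_trait_significance_excluded(self):
        p1 = np.array([1e-6, 0.5])
        p2 = np.array([0.5, 0.5])
        assert not direct_fdr_method(p1, p2).any()

    def test_empty_input_empty_set(self):
        assert direct_fdr_method([], []).size == 0
        assert max_p_method([], []).size == 0

    def test_direct_fdr_matches_double_thresholding(self):
        rng = np.random.default_rng(14)
        p1 = rng.random(200) ** 3
        p2 = rng.random(200) ** 3
        expected = (brute_force_bh(p1) < 0.05) & (brute_force_bh(p2) < 0.05)
        np.testing.assert_array_equal(direct_fdr_method(p1, p2), expected)

    def test_max_p_uses_pairwise_maximum(self):
        rng = np.random.default_rng(15)
        p1 = rng.random(200) ** 2
        p2 = rng.random(200) ** 2
        expected = brute_force_bh(np.maximum(p1, p2)) < 0.05
        np.testing.assert_array_equal(max_p_method(p1, p2), expected)
        np.testing.assert_array_equal(max_p_method(p1, p1), brute_force_bh(p1) < 0.05)


def _mixture_pair(n, q1, q2, alpha, rng, pi11=None):
    if pi11 is None:
        u1 = rng.random(n) < q1
        u2 = rng.random(n) < q2
    else:
        u1 = rng.random(n) < q1
        u2 = np.where(u1, rng.random(n) < pi11 / q1, rng.random(n) < (q2 - pi11) / (1 - q1))
    p1 = np.where(u1, rng.random(n) ** (1 / alpha), rng.random(n))
    p2 = np.where(u2, rng.random(n) ** (1 / alpha), rng.random(n))
    return p1, p2


class TestOverallPleiotropyLrt:
    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(16)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            p1, p2 = _mixture_pair(1500, 0.2, 0.2, 0.2, rng)
            _, p_lrt, _ = overall_pleiotropy_lrt(p1, p2)
            rej += p_lrt < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))

    def test_shared_architecture_strongly_rejected(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(20):
            p1, p2 = _mixture_pair(1500, 0.2, 0.2, 0.2, rng, pi11=0.15)
            _, p_lrt, _ = overall_pleiotropy_lrt(p1, p2)
            hits += p_lrt < 1e-4
        assert hits >= 19

    def test_uniform_pvalues_degenerate_fit(self):
        rng = np.random.default_rng(18)
        small = 0
        for _ in range(20):
            lrt, _, _ = overall_pleiotropy_lrt(rng.random(800), rng.random(800))
            small += lrt < stats.chi2.ppf(0.5, 1)
        assert small >= 10

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            overall_pleiotropy_lrt(np.full(100, 0.5), np.full(100, 0.5))


class TestEffectCorrelationAndHeterogeneity:
    def test_proportional_effects(self):
        b = np.array([0.1, -0.2, 0.3])
        assert effect_correlation(b, 2 * b) == pytest.approx(1.0)
        assert effect_correlation(b, -b) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(19)
        x, y = rng.standard_normal((2, 30))
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert effect_correlation(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_fewer_than_three_snps_flagged(self):
        assert np.isnan(effect_correlation([0.1, 0.2], [0.3, 0.4]))

    def test_cochran_q_equal_effects(self):
        Q, p = cochran_q(0.5, 0.1, 0.5, 0.2)
        assert Q == 0.0 and p == 1.0

    def test_cochran_q_oracle_value(self):
        Q, p = cochran_q(1.0, 1.0, 0.0, 1.0)
        assert Q == pytest.approx(0.5)
        assert p == pytest.approx(stats.chi2.sf(0.5, 1), rel=1e-12)

    def test_cochran_q_symmetric(self):
        Q1, _ = cochran_q(0.8, 0.1, 0.2, 0.3)
        Q2, _ = cochran_q(0.2, 0.3, 0.8, 0.1)
        assert Q1 == pytest.approx(Q2)

    def test_cochran_q_matches_pooled_weight_formula(self):
        b1, s1, b2, s2 = 0.7, 0.15, 0.2, 0.25
        w1, w2 = 1 / s1**2, 1 / s2**2
        pooled = (w1 * b1 + w2 * b2) / (w1 + w2)
        expected = w1 * (b1 - pooled) ** 2 + w2 * (b2 - pooled) ** 2
        Q, _ = cochran_q(b1, s1, b2, s2)
        assert Q == pytest.approx(expected, rel=1e-12)


class TestHypergeometricEnrichment:
    def test_disjoint_query_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        overlap, p = hypergeometric_enrichment(bg[:5], bg[10:15], bg)
        assert overlap == 0 and p == 1.0

    def test_forced_maximal_overlap(self):
        bg = [f"g{i}" for i in range(10)]
        overlap, p = hypergeometric_enrichment(bg, bg, bg)
        assert overlap == 10 and p == pytest.approx(1.0)

    def test_matches_combinatorial_enumeration(self):
        bg = [f"g{i}" for i in range(20)]
        geneset = bg[:5]
        query = bg[2:10]  # overlap 3 of K=5, n=8
        overlap, p = hypergeometric_enrichment(query, geneset, bg)
        assert overlap == 3
        assert p == pytest.approx(brute_force_hypergeom_tail(20, 5, 8, 3), rel=1e-12)

    def test_random_small_fixtures_match_enumeration(self):
        rng = np.random.default_rng(20)
        bg = [f"g{i}" for i in range(25)]
        for _ in range(20):
            geneset = list(rng.choice(bg, size=rng.integers(1, 12), replace=False))
            query = list(rng.choice(bg, size=rng.integers(1, 12), replace=False))
            overlap, p = hypergeometric_enrichment(query, geneset, bg)
            expected = brute_force_hypergeom_tail(25, len(geneset), len(query), overlap)
            assert p == pytest.approx(expected, rel=1e-10)


class TestSharedGeneSummary:
    def _result(self, pair, gene_qs):
        genes = pd.DataFrame(
            {
                "gene_id": list(gene_qs),
                "p1": 0.5,
                "p2": 0.5,
                "z1": 1.0,
                "z2": -1.0,
                "T": -1.0,
                "p_placo": list(gene_qs.values()),
                "q_fdr": list(gene_qs.values()),
            }
        )
        return PleioPairResult(trait_pair=pair, genes=genes, rho_z=0.0, sigma1_sq=1.0, sigma2_sq=1.0)

    def test_single_pair_counts(self):
        res = self._result(("A", "B"), {"g1": 0.01, "g2": 0.01, "g3": 0.01})
        pair_counts, gene_counts, signs = shared_gene_summary([res])
        assert pair_counts["n_significant"].iloc[0] == 3
        assert (gene_counts["n_disorders"] == 2).all()
        assert set(signs.columns) == {"A", "B"}

    def test_empty_results(self):
        pair_counts, gene_counts, signs = shared_gene_summary([])
        assert pair_counts.empty and gene_counts.empty and signs.empty

    def test_three_trait_counts_match_brute_force(self):
        results = [
            self._result(("A", "B"), {"g1": 0.01, "g2": 0.5}),
            self._result(("A", "C"), {"g1": 0.01, "g3": 0.01}),
            self._result(("B", "C"), {"g1": 0.2, "g3": 0.01}),
        ]
        pair_counts, gene_counts, _ = shared_gene_summary(results)
        # brute-force recount
        expected = {}
        for res in results:
            for _, row in res.genes.iterrows():
                if row["q_fdr"] < 0.05:
                    expected.setdefault(row["gene_id"], set()).update(res.trait_pair)
        got = dict(zip(gene_counts["gene_id"], gene_counts["n_disorders"]))
        assert got == {g: len(ts) for g, ts in expected.items()}
        assert list(pair_counts["n_significant"]) == [1, 2, 1]
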