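"""Exact-test engine: hypergeometric tail, Fisher, chi-squared, BH-FDR."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, hypergeom

from acetylmap.enrich import (
    bh_fdr,
    category_enrichment,
    fisher_exact_greater,
    hypergeom_upper_tail,
    pearson_chi2,
    te_family_enrichment,
)
from acetylmap.model import CategoryMap, GenomicInterval, TEFeature


class TestHypergeomUpperTail:
    def test_enumeration_small_universe(self):
        # N=6, K=3, n=3: of the C(6,3)=20 draws, 10 contain >= 2 successes
        assert hypergeom_upper_tail(2, 3, 3, 6) == pytest.approx(0.5, abs=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 50, 10, 100) == 1.0

    def test_matches_exhaustive_pmf_summation(self):
        """Log-space tail equals direct pmf summation for every configuration
        with N <= 60, to 1e-12 relative error."""

        def brute(k, n, K, N):
            return sum(
                math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
                for x in range(k, min(n, K) + 1)
            )

        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = brute(k, n, K, N)
            got = hypergeom_upper_tail(k, n, K, N)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_far_tail(self):
        # deep-tail configuration where naive summation would underflow
        p = hypergeom_upper_tail(6000, 12442, 108347, 301830)
        assert p == pytest.approx(float(hypergeom.sf(5999, 301830, 108347, 12442)), rel=1e-9)
        assert 0 < p < 1e-100

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 10, 100)  # k > n
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 10, 200, 100)  # K > N


class TestFisherGreater:
    def test_enumerated_table(self):
        assert fisher_exact_greater(3, 1, 1, 3) == pytest.approx(17 / 70, rel=1e-12)

    def test_zero_row_gives_one(self):
        assert fisher_exact_greater(0, 0, 5, 5) == 1.0

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_greater(0, 0, 0, 0) == 1.0

    def test_equals_hypergeometric_tail_on_random_tables(self):
        """One-sided Fisher p equals the hypergeometric upper tail on 1000
        random 2x2 tables (margins <= 500), against scipy's independent
        Fisher implementation."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 251, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_greater(a, b, c, d)
            theirs = float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])
            assert ours == pytest.approx(theirs, rel=1e-8, abs=1e-12)
            assert ours == pytest.approx(
                hypergeom_upper_tail(a, a + b, a + c, a + b + c + d), rel=1e-12
            )


class TestPearsonChi2:
    def test_balanced_table_is_null(self):
        stat, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == 0 and p == 1.0

    def test_closed_form(self):
        stat, p = pearson_chi2([[20, 10], [10, 20]])
        assert stat == pytest.approx(6.6667, abs=1e-4)
        assert p == pytest.approx(0.0098, abs=1e-4)

    def test_statistic_scales_linearly(self):
        s1, _ = pearson_chi2([[20, 10], [10, 20]])
        s2, _ = pearson_chi2([[40, 20], [20, 40]])
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [5, 5]])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_hand_step_up(self):
        assert bh_fdr([0.005, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.02, 0.02, 0.04, 0.04]
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_matches_brute_force_definition(self, ps):
        """q(i) = min_{j>=i} p(j)*m/j over the sorted p's, in input order."""
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        brute = [0.0] * m
        for rank, idx in enumerate(order):
            candidates = [
                ps[order[j]] * m / (j + 1) for j in range(rank, m)
            ]
            brute[idx] = min(1.0, min(candidates))
        got = bh_fdr(ps)
        assert got == pytest.approx(brute, rel=1e-12, abs=1e-12)
        assert np.all(got >= np.asarray(ps) - 1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        ps = rng.uniform(size=40)
        assert bh_fdr(ps) == pytest.approx(
            multipletests(ps, method="fdr_bh")[1], rel=1e-10
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCategoryEnrichment:
    def make_map(self):
        mapping = {f"g{i}": {"cat_a" if i < 30 else "cat_b"} for i in range(100)}
        return CategoryMap(mapping=mapping, universe_size=100)

    def test_whole_universe_selection_is_null(self):
        cmap = self.make_map()
        results = category_enrichment([f"g{i}" for i in range(100)], cmap)
        assert all(r.p == pytest.approx(1.0) for r in results)

    def test_contingency_counts(self):
        cmap = self.make_map()
        sel = [f"g{i}" for i in range(40)]  # 30 of cat_a, 10 of cat_b
        by_cat = {r.category: r for r in category_enrichment(sel, cmap)}
        a = by_cat["cat_a"]
        assert (a.k, a.n, a.K, a.N) == (30, 40, 30, 100)
        assert a.p == pytest.approx(hypergeom_upper_tail(30, 40, 30, 100))
        assert a.q >= a.p

    def test_relabeling_noncategory_genes_invariant(self):
        cmap = self.make_map()
        sel = [f"g{i}" for i in range(25)]
        p1 = {r.category: r.p for r in category_enrichment(sel, cmap)}
        # rename every cat_b gene; cat_a p must not move
        mapping = {
            (f"h{i}" if i >= 30 else f"g{i}"): {"cat_a" if i < 30 else "cat_b"}
            for i in range(100)
        }
        cmap2 = CategoryMap(mapping=mapping, universe_size=100)
        p2 = {r.category: r.p for r in category_enrichment(sel, cmap2)}
        assert p1["cat_a"] == pytest.approx(p2["cat_a"], rel=1e-12)

    def test_chi2_method_used_for_go_style_maps(self):
        cmap = self.make_map()
        sel = [f"g{i}" for i in range(25)]
        results = category_enrichment(sel, cmap, method="chi2")
        assert all(r.method == "chi2" for r in results)
        r = next(r for r in results if r.category == "cat_a")
        stat, p = pearson_chi2([[25, 0], [5, 70]])
        assert r.p == pytest.approx(p)

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning):
            assert category_enrichment([], self.make_map()) == []


class TestTeFamilyEnrichment:
    def make_tes(self, counts):
        tes = []
        for fam, n in counts.items():
            for i in range(n):
                tes.append(
                    TEFeature(
                        te_id=f"{fam}_{i}",
                        interval=GenomicInterval("chr1", i * 10, i * 10 + 5),
                        family=fam,
                    )
                )
        return tes

    def test_counts_and_method_switch(self):
        tes = self.make_tes({"LINE": 200, "MITE": 300, "Gypsy": 100})
        marked = [t for t in tes if t.family == "LINE"][:150] + [
            t for t in tes if t.family == "MITE"
        ][:20]
        results = te_family_enrichment({"WT": marked}, tes, small_count_threshold=100)
        by_fam = {r.category: r for r in results}
        line = by_fam["LINE"]
        assert (line.k, line.n, line.K, line.N) == (150, 170, 200, 600)
        assert line.method == "hypergeometric"  # k = 150 >= 100
        assert by_fam["MITE"].method == "fisher_greater"  # k = 20 < 100
        # both recorded methods compute the identical exact tail
        assert by_fam["MITE"].p == pytest.approx(
            hypergeom_upper_tail(20, 170, 300, 600)
        )

    def test_absent_family_is_not_significant(self):
        tes = self.make_tes({"LINE": 50, "MITE": 50})
        marked = [t for t in tes if t.family == "LINE"][:10]
        by_fam = {
            r.category: r
            for r in te_family_enrichment({"WT": marked}, tes)
        }
        assert by_fam["MITE"].k == 0
        assert by_fam["MITE"].p == 1.0
        assert not by_fam["MITE"].significant

    def test_marked_family_missing_from_universe_is_error(self):
        tes = self.make_tes({"LINE": 50})
        rogue = self.make_tes({"MITE": 1})
        with pytest.raises(ValueError, match="absent from the universe"):
            te_family_enrichment({"WT": rogue}, tes)
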