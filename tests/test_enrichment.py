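"""Weighted-KS enrichment scores, permutation GSEA, ORA against exact
hypergeometric enumeration, and enrichment comparison tables."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epinherit.enrichment import (compare_enrichment, enrichment_score, gsea,
                                  ora_analysis, ora_test,
                                  rank_by_signed_significance)


def series(scores, prefix="g"):
    return pd.Series(scores, index=[f"{prefix}{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_top_gene_unweighted_hits_one(self):
        # hand trace, N=5: running sum jumps to 1 at the first position
        ranked = series([5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, leading = enrichment_score(ranked, {"g0"},
                                                weight_exponent=0.0)
        assert es == pytest.approx(1.0)
        assert leading == ("g0",)
        assert running[0] == pytest.approx(1.0)

    def test_bottom_gene_unweighted_hits_minus_one(self):
        # running sum: -1/4 at each miss, reaching -1 before the final hit
        ranked = series([5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, _ = enrichment_score(ranked, {"g4"},
                                          weight_exponent=0.0)
        assert es == pytest.approx(-1.0)
        assert running[3] == pytest.approx(-1.0)

    def test_reversing_symmetric_ranking_negates_es(self):
        scores = [4.0, 3.0, 1.0, -1.0, -3.0, -4.0]
        ranked = series(scores)
        flipped = pd.Series([-s for s in scores], index=ranked.index)
        for geneset in ({"g0", "g1"}, {"g1", "g2"}):
            es_fwd, _, _ = enrichment_score(ranked, geneset)
            es_rev, _, _ = enrichment_score(flipped, geneset)
            assert es_fwd == pytest.approx(-es_rev)

    def test_hand_traced_weighted_profile(self):
        # N=4, set {g0, g2}, weight 1: hit steps 3/4 and 1/4, miss step 1/2
        ranked = series([3.0, 2.0, 1.0, 0.5])
        es, running, _ = enrichment_score(ranked, {"g0", "g2"})
        assert running == pytest.approx([0.75, 0.25, 0.5, 0.0])
        assert es == pytest.approx(0.75)

    def test_disjoint_set_flagged_undefined(self):
        with pytest.warns(UserWarning, match="disjoint"):
            es, running, leading = enrichment_score(series([1.0, 2.0]),
                                                    {"absent"})
        assert math.isnan(es)
        assert leading == ()

    def test_duplicate_genes_rejected(self):
        ranked = pd.Series([1.0, 2.0], index=["g", "g"])
        with pytest.raises(ValueError, match="duplicate"):
            enrichment_score(ranked, {"g"})


@given(st.integers(10, 60), st.integers(1, 9), st.floats(0.0, 2.0),
       st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_es_always_within_unit_interval(n, set_size, weight, seed):
    """Weighted-KS normalization keeps the score in [-1, 1]."""
    rng = np.random.default_rng(seed)
    ranked = series(np.sort(rng.normal(size=n))[::-1])
    geneset = set(rng.choice(ranked.index, size=min(set_size, n - 1),
                             replace=False))
    es, _, _ = enrichment_score(ranked, geneset, weight_exponent=weight)
    assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestGsea:
    def make_ranked(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return series(np.sort(rng.normal(size=n))[::-1]), rng

    def test_fixed_seed_is_bit_reproducible(self):
        ranked, rng = self.make_ranked()
        sets = {"A": set(ranked.index[:15]),
                "B": set(rng.choice(ranked.index, 25, replace=False))}
        r1 = gsea(ranked, sets, n_perm=150, seed=11)
        r2 = gsea(ranked, sets, n_perm=150, seed=11)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.pvalue, a.fdr_q) == (b.es, b.nes,
                                                        b.pvalue, b.fdr_q)

    def test_planted_top_set_detected(self):
        ranked, _ = self.make_ranked()
        (res,) = gsea(ranked, {"TOP": set(ranked.index[:20])},
                      n_perm=200, seed=11)
        assert res.es > 0
        assert res.nes > 0
        assert res.pvalue <= 1 / 200

    def test_random_set_unremarkable(self):
        ranked, rng = self.make_ranked(seed=11)
        sets = {f"R{j}": set(rng.choice(ranked.index, 30, replace=False))
                for j in range(5)}
        results = gsea(ranked, sets, n_perm=200, seed=11)
        assert np.median([abs(r.nes) for r in results]) < 1.5
        assert np.median([r.fdr_q for r in results]) > 0.25

    def test_size_filters_exclude_sets(self):
        ranked, _ = self.make_ranked()
        results = gsea(ranked, {"tiny": set(ranked.index[:2]),
                                "ok": set(ranked.index[:10])},
                       n_perm=100, seed=1, min_size=5)
        assert [r.name for r in results] == ["ok"]

    def test_es_matches_gseapy_reference(self, tmp_path):
        """Cross-check the weighted-KS score against gseapy's prerank."""
        gseapy = pytest.importorskip("gseapy")
        ranked, rng = self.make_ranked(n=100, seed=3)
        members = sorted(rng.choice(ranked.index, 15, replace=False))
        rnk = ranked.reset_index()
        rnk.columns = ["gene_name", "rank"]
        res = gseapy.prerank(
            rnk=rnk, gene_sets={"S": members}, permutation_num=10,
            min_size=2, max_size=500, weight=1.0, seed=7,
            outdir=None, no_plot=True)
        gseapy_es = float(res.res2d.loc[res.res2d.Term == "S", "ES"].iloc[0])
        ours, _, _ = enrichment_score(ranked, members, weight_exponent=1.0)
        assert ours == pytest.approx(gseapy_es, abs=1e-6)


class TestOra:
    def test_worked_hypergeometric_example(self):
        # universe 10, set 5, query 5, overlap 4:
        # p = (C(5,4)C(5,1) + C(5,5)C(5,0)) / C(10,5) = 26/252
        universe = [f"u{i}" for i in range(10)]
        geneset = universe[:5]
        query = universe[:4] + [universe[7]]
        res = ora_test(query, geneset, universe)
        assert res.overlap == 4
        assert res.pvalue == pytest.approx(26 / 252, abs=1e-12)

    def test_zero_overlap_p_near_one(self):
        universe = [f"u{i}" for i in range(30)]
        res = ora_test(universe[:10], universe[28:], universe)
        assert res.pvalue == pytest.approx(1.0, abs=0.5)
        assert res.overlap == 0

    def test_degenerate_full_overlap_p_one(self):
        universe = [f"u{i}" for i in range(6)]
        res = ora_test(universe, universe, universe)
        assert res.pvalue == pytest.approx(1.0)

    def test_out_of_universe_members_trimmed(self):
        with pytest.warns(UserWarning, match="trimmed"):
            res = ora_test(["a", "zzz"], ["a", "b"], ["a", "b", "c"])
        assert res.overlap == 1

    def test_exact_enumeration_small_universes(self):
        """p equals the rational hypergeometric upper tail for every
        configuration with universe size <= 12."""
        for n_uni in range(1, 13):
            universe = [f"u{i}" for i in range(n_uni)]
            for k_set in range(n_uni + 1):
                for n_query in range(n_uni + 1):
                    geneset = universe[:k_set]
                    query = universe[n_uni - n_query:]
                    k = len(set(geneset) & set(query))
                    tail = sum(
                        Fraction(math.comb(k_set, j)
                                 * math.comb(n_uni - k_set, n_query - j),
                                 math.comb(n_uni, n_query))
                        for j in range(k, min(k_set, n_query) + 1))
                    if k_set == 0 or n_query == 0:
                        tail = Fraction(1) if k == 0 else tail
                    res = ora_test(query, geneset, universe)
                    assert res.pvalue == pytest.approx(float(tail),
                                                       abs=1e-10), (
                        n_uni, k_set, n_query)

    def test_bh_across_sets(self):
        universe = [f"u{i}" for i in range(40)]
        sets = {"hit": universe[:10], "miss": universe[30:]}
        results = {r.name: r for r in
                   ora_analysis(universe[:10], sets, universe)}
        assert results["hit"].pvalue < results["miss"].pvalue
        assert 0 <= results["hit"].fdr_q <= 1


class TestCompareEnrichment:
    def make(self, name, q):
        from epinherit.enrichment import EnrichmentResult

        return EnrichmentResult(name, 10, 0.5, 1.0, 0.01, q)

    def test_more_enriched_side_flagged(self):
        table = compare_enrichment([self.make("S", 0.01)],
                                   [self.make("S", 0.10)])
        assert table.loc[0, "more_enriched"] == "A"

    def test_no_shared_sets_empty(self):
        table = compare_enrichment([self.make("S1", 0.01)],
                                   [self.make("S2", 0.01)])
        assert table.empty

    def test_identical_inputs_all_ties(self):
        res = [self.make("S1", 0.2), self.make("S2", 0.4)]
        table = compare_enrichment(res, res)
        assert (table["more_enriched"] == "tie").all()


def test_rank_by_signed_significance_orders_by_signed_logp():
    from epinherit.expression import ExpressionResult

    results = [ExpressionResult("up", 2.0, 1e-4, 1e-3, "p"),
               ExpressionResult("down", -2.0, 1e-6, 1e-5, "n"),
               ExpressionResult("flat", 0.5, 0.5, 0.8, "none")]
    ranked = rank_by_signed_significance(results)
    assert list(ranked.index) == ["up", "flat", "down"]
    assert ranked["up"] == pytest.approx(4.0)
    assert ranked["down"] == pytest.approx(-6.0)
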