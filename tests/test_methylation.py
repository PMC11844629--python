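"""Coverage filtering, tiling, promoter windows, location labels, and the
global rank-sum comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epinherit.io_formats import CpGRecord, GeneModel
from epinherit.methylation import (ConfigurationError, GenomicInterval,
                                   LocationClassifier, aggregate_regions,
                                   filter_coverage,
                                   global_methylation_compare,
                                   promoter_windows, tile_genome)


def cpg(pos, m, u, chrom="chr1"):
    return CpGRecord(chrom, pos, m, u)


class TestFilterCoverage:
    def test_minimum_coverage_three(self):
        sites = [cpg(1, 1, 1), cpg(2, 2, 1), cpg(3, 2, 2)]
        kept = filter_coverage(sites, min_cov=3)
        assert [s.pos for s in kept] == [2, 3]

    def test_min_cov_one_is_identity(self):
        sites = [cpg(1, 1, 0), cpg(2, 0, 1)]
        assert filter_coverage(sites, min_cov=1) == sites

    def test_empty_input(self):
        assert filter_coverage([], min_cov=3) == []

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            filter_coverage([], min_cov=0)


class TestTiling:
    def test_counts_conserved_within_tile(self):
        samples = {"s1": [cpg(5, 3, 1), cpg(50, 1, 3)]}
        (tile,) = tile_genome(samples, window=100, step=100)
        assert tile.region_id == "chr1:0"
        assert tile.counts["s1"] == (4, 4)

    def test_half_open_boundary_site_goes_to_next_tile(self):
        samples = {"s1": [cpg(100, 1, 0)]}
        (tile,) = tile_genome(samples, window=100, step=100)
        assert (tile.region.start, tile.region.end) == (100, 200)

    def test_tile_requires_coverage_in_every_sample(self):
        # brute-force membership over a 3-sample fixture: only tiles covered
        # by all three samples survive the intersection rule
        samples = {
            "s1": [cpg(10, 1, 1), cpg(110, 1, 1), cpg(210, 1, 1)],
            "s2": [cpg(20, 1, 1), cpg(120, 1, 1)],
            "s3": [cpg(30, 1, 1), cpg(230, 1, 1)],
        }
        covered = {s: {r.pos // 100 for r in recs}
                   for s, recs in samples.items()}
        expected = sorted(set.intersection(*covered.values()))
        tiles = tile_genome(samples, window=100, step=100)
        assert sorted(t.region.start // 100 for t in tiles) == expected
        assert expected == [0]  # only tile 0-100 is covered by all

        union_tiles = tile_genome(samples, window=100, step=100,
                                  require_all_samples=False)
        expected_union = sorted(set.union(*covered.values()))
        assert sorted(t.region.start // 100
                      for t in union_tiles) == expected_union

    def test_each_site_in_exactly_one_tile_when_step_equals_window(self):
        rng = np.random.default_rng(0)
        positions = rng.integers(0, 5000, size=200)
        sites = [cpg(int(p), 1, 1) for p in positions]
        tiles = tile_genome({"s": sites}, window=100, step=100)
        total = sum(t.counts["s"][0] + t.counts["s"][1] for t in tiles)
        assert total == 2 * len(sites)  # conservation across the partition

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ConfigurationError):
            tile_genome({"s": []}, window=100, step=200)

    def test_overlapping_tiles_with_smaller_step(self):
        tiles = tile_genome({"s": [cpg(150, 2, 0)]}, window=200, step=100)
        anchors = sorted(t.region.start for t in tiles)
        assert anchors == [0, 100]  # site at 150 falls in both windows


class TestPromoterWindows:
    @pytest.mark.parametrize(
        "strand,tss,expected",
        [("+", 10_000, (7_000, 10_300)),
         ("-", 10_000, (9_700, 13_000)),
         ("+", 100, (0, 400))],  # clamped at the origin
    )
    def test_window_geometry(self, strand, tss, expected):
        if strand == "+":
            g = GeneModel.from_exons("g", "chr1", "+", [(tss, tss + 500)])
        else:
            g = GeneModel.from_exons("g", "chr1", "-", [(tss - 500, tss)])
        ((gid, iv),) = promoter_windows([g], upstream=3000, downstream=300)
        assert gid == "g"
        assert (iv.start, iv.end) == expected

    def test_width_is_upstream_plus_downstream_unless_clamped(self):
        g = GeneModel.from_exons("g", "chr1", "+", [(50_000, 50_100)])
        ((_, iv),) = promoter_windows([g])
        assert iv.width == 3300


class TestAggregateRegions:
    def test_promoter_counts_are_sums_of_member_sites(self):
        g = GeneModel.from_exons("g", "chr1", "+", [(5_000, 5_500)])
        promoters = promoter_windows([g])  # [2000, 5300)
        samples = {
            "a": [cpg(2_000, 1, 2), cpg(5_299, 3, 4), cpg(5_300, 100, 100)],
            "b": [cpg(3_000, 5, 6)],
        }
        (region,) = aggregate_regions(samples, promoters)
        assert region.region_id == "g"
        assert region.counts["a"] == (4, 6)  # boundary site 5300 excluded
        assert region.counts["b"] == (5, 6)

    def test_region_dropped_unless_all_samples_covered(self):
        g = GeneModel.from_exons("g", "chr1", "+", [(5_000, 5_500)])
        promoters = promoter_windows([g])
        samples = {"a": [cpg(3_000, 1, 1)], "b": [cpg(9_999, 1, 1)]}
        assert aggregate_regions(samples, promoters) == []
        (region,) = aggregate_regions(samples, promoters,
                                      require_all_samples=False)
        assert set(region.counts) == {"a"}


class TestLocationClassification:
    @pytest.fixture
    def classifier(self, two_gene_models):
        promoters = promoter_windows(two_gene_models)
        return LocationClassifier(two_gene_models, promoters)

    def test_promoter_takes_precedence_over_exon(self, classifier):
        # geneA promoter is [7000, 10300); exon 1 is [10000, 10200)
        region = GenomicInterval("chr1", 10_150, 10_250)
        assert classifier.classify(region) == "promoter"

    def test_intergenic_between_genes(self, classifier):
        assert classifier.classify(
            GenomicInterval("chr1", 15_000, 15_100)) == "intergenic"

    def test_exon_beats_intron_across_genes(self, two_gene_models):
        # brute-force oracle: enumerate labels over a fixture where geneB's
        # gene body is dragged next to geneA's intron so a region overlaps
        # intron-of-A and exon-of-B
        gene_a = two_gene_models[0]
        gene_b = GeneModel.from_exons("geneB", "chr1", "-",
                                      [(10_250, 10_290)])
        promoters = []  # isolate the exon/intron precedence
        clf = LocationClassifier([gene_a, gene_b], promoters)
        region = GenomicInterval("chr1", 10_240, 10_260)

        def brute_force(region, genes):
            labels = set()
            for g in genes:
                in_body = region.start < g.end and g.start < region.end
                in_exon = any(region.start < e and s < region.end
                              for s, e in g.exons)
                if in_exon:
                    labels.add("exon")
                elif in_body:
                    labels.add("intron")
            for label in ("promoter", "exon", "intron"):
                if label in labels:
                    return label
            return "intergenic"

        assert brute_force(region, [gene_a, gene_b]) == "exon"
        assert clf.classify(region) == "exon"

    def test_intron_when_inside_body_but_not_exon(self):
        # long gene whose intron lies beyond the promoter window's reach
        g = GeneModel.from_exons("g", "chr1", "+",
                                 [(50_000, 50_100), (52_000, 52_100)])
        clf = LocationClassifier([g], promoter_windows([g]))
        assert clf.classify(GenomicInterval("chr1", 51_000, 51_100)) == "intron"
        # the 5' intron stretch still inside -3000/+300 is promoter instead
        assert clf.classify(GenomicInterval("chr1", 50_150, 50_250)) == "promoter"


class TestGlobalComparison:
    def test_identical_samples_tie(self):
        stat, p, direction = global_methylation_compare(
            [10, 20, 30], [10, 20, 30])
        assert p == 0.5
        assert direction == "none"

    def test_exact_tail_matches_exhaustive_permutation(self):
        a, b = [90.0, 95.0, 99.0], [1.0, 2.0, 3.0]
        # oracle: enumerate all C(6,3)=20 assignments of the pooled values
        pooled = a + b
        obs = sum(sorted(pooled).index(v) + 1 for v in a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            ranks = sum(sorted(pooled).index(pooled[i]) + 1 for i in combo)
            total += 1
            if ranks >= obs:
                count += 1
        expected = count / total
        assert expected == pytest.approx(0.05)
        _, p, direction = global_methylation_compare(a, b)
        assert direction == "a"
        assert p == pytest.approx(expected, abs=1e-12)

    def test_swapping_samples_flips_direction(self, rng):
        a = rng.normal(60, 5, size=50)
        b = rng.normal(40, 5, size=50)
        stat_ab, p_ab, dir_ab = global_methylation_compare(a, b)
        stat_ba, p_ba, dir_ba = global_methylation_compare(b, a)
        assert (dir_ab, dir_ba) == ("a", "b")
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            global_methylation_compare([], [1.0])


@given(st.lists(st.integers(0, 10_000), min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_partition_property_every_site_lands_in_one_tile(positions):
    """With step == window every covered CpG belongs to exactly one tile."""
    sites = [CpGRecord("chr1", p, 1, 1) for p in positions]
    tiles = tile_genome({"s": sites}, window=100, step=100)
    assigned = sum(t.counts["s"][0] for t in tiles)
    assert assigned == len(sites)
    for t in tiles:
        assert t.region.start % 100 == 0
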