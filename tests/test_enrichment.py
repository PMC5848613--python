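"""Context labels, exact binomial tail and randomization enrichment."""

import math
import random

import pytest

from l1array import (
    ContextLabel,
    GeneFeature,
    GenomeMap,
    binomial_pvalue,
    classify_context,
    cluster_enrichment,
)
from l1array.scan import ArrayRegion


def gene(chrom, start, end, name="g"):
    return GeneFeature(chrom, start, end, "+", name)


def region(chrom, start, end):
    return ArrayRegion(chrom, start, end)


class TestContextLabels:
    def test_no_genes_anywhere_means_intergenic(self):
        report = classify_context([region("chr1", 0, 100)], [])
        assert report.records[0].label is ContextLabel.INTERGENIC
        assert report.contains_genes_count == 0

    # enumerate relation combinations against the label table: a region can
    # relate to genes as CONTAINED-in-gene (C), CONTAINS-gene (G), PARTIAL (P)
    @pytest.mark.parametrize(
        "genes,expected",
        [
            # region (100, 200) inside a transcript -> INTRAGENIC
            ([(0, 500)], ContextLabel.INTRAGENIC),
            # only a straddling gene -> GENE_FLANKING
            ([(150, 800)], ContextLabel.GENE_FLANKING),
            ([(50, 150)], ContextLabel.GENE_FLANKING),
            # a gene fully inside the region -> WITHIN_AND_FLANKING
            ([(120, 180)], ContextLabel.WITHIN_AND_FLANKING),
            # contained + straddling mixture
            ([(120, 180), (150, 800)], ContextLabel.WITHIN_AND_FLANKING),
            # enclosing + straddling mixture
            ([(0, 500), (150, 800)], ContextLabel.WITHIN_AND_FLANKING),
            # enclosing + contained gene
            ([(0, 500), (120, 180)], ContextLabel.WITHIN_AND_FLANKING),
            # all three relations at once
            ([(0, 500), (120, 180), (150, 800)], ContextLabel.WITHIN_AND_FLANKING),
            # two enclosing transcripts stay INTRAGENIC
            ([(0, 500), (50, 300)], ContextLabel.INTRAGENIC),
            # identical interval counts as containing the gene
            ([(100, 200)], ContextLabel.WITHIN_AND_FLANKING),
            # gene outside -> INTERGENIC
            ([(300, 400)], ContextLabel.INTERGENIC),
            # book-ended (no base shared) -> INTERGENIC
            ([(200, 300)], ContextLabel.INTERGENIC),
        ],
    )
    def test_relation_combinations_map_to_expected_label(self, genes, expected):
        gs = [gene("chr1", s, e, f"g{i}") for i, (s, e) in enumerate(genes)]
        report = classify_context([region("chr1", 100, 200)], gs)
        assert report.records[0].label is expected

    def test_every_region_gets_exactly_one_label_and_counts_sum(self, rng):
        regions = [
            region("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 100_000, size=40)
        ]
        genes = [
            gene("chr1", int(s), int(s) + int(l) + 1, f"g{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 100_000, 60), rng.integers(0, 400, 60))
            )
        ]
        report = classify_context(regions, genes)
        assert sum(report.counts.values()) == len(regions)
        assert len(report.records) == len(regions)


class TestBinomialPvalue:
    def test_zero_successes_always_give_one(self):
        for n in (0, 1, 10):
            for p in (0.0, 0.2, 1.0):
                assert binomial_pvalue(0, n, p) == 1.0

    def test_closed_form_example(self):
        assert binomial_pvalue(2, 2, 0.5) == pytest.approx(0.25, abs=1e-15)

    def test_matches_exhaustive_enumeration(self):
        # independent oracle: exact pmf via integer binomial coefficients
        def oracle(k, n, p):
            return sum(
                math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
            )

        assert binomial_pvalue(7, 10, 0.2) == pytest.approx(
            oracle(7, 10, 0.2), abs=1e-14
        )
        for n in range(13):
            for k in range(n + 1):
                for p in (0.01, 0.3, 0.5, 0.77, 0.99):
                    assert binomial_pvalue(k, n, p) == pytest.approx(
                        oracle(k, n, p), abs=1e-12
                    )

    def test_monotone_in_k_and_p(self):
        for n in (5, 12):
            vals = [binomial_pvalue(k, n, 0.3) for k in range(n + 1)]
            assert vals == sorted(vals, reverse=True)
            ps = [binomial_pvalue(3, n, p) for p in (0.1, 0.3, 0.5, 0.9)]
            assert ps == sorted(ps)

    @pytest.mark.parametrize("k,n,p", [(5, 3, 0.5), (-1, 3, 0.5), (1, 3, 1.5), (1, 3, -0.1)])
    def test_invalid_arguments_rejected(self, k, n, p):
        with pytest.raises(ValueError):
            binomial_pvalue(k, n, p)


class TestClusterEnrichment:
    GENOME = GenomeMap({"chr1": 1_000_000})

    def _genes(self):
        gs = [gene("chr1", 10_000 * i, 10_000 * i + 2_000, f"Olfr{i}") for i in range(5)]
        gs += [gene("chr1", 500_000 + 7_000 * i, 500_000 + 7_000 * i + 2_000, f"Gm{i}")
               for i in range(5)]
        return gs

    def test_zero_observed_successes_give_p_one(self):
        regions = [region("chr1", 900_000, 950_000)]
        res = cluster_enrichment(
            regions, self._genes(), "^Olfr", self.GENOME, n_random=200, seed=1
        )
        assert res.k_observed == 0
        assert res.p_value == 1.0

    def test_pattern_matching_no_gene_is_an_error(self):
        with pytest.raises(ValueError, match="matches no gene"):
            cluster_enrichment(
                [region("chr1", 0, 1_000)], self._genes(), "^Vmn", self.GENOME,
                n_random=200, seed=1,
            )

    def test_n_random_below_100_rejected(self):
        with pytest.raises(ValueError, match="n_random"):
            cluster_enrichment(
                [region("chr1", 0, 1_000)], self._genes(), "^Olfr", self.GENOME,
                n_random=50, seed=1,
            )

    def test_result_is_reproducible_and_order_invariant(self):
        regions = [
            region("chr1", 0, 30_000),
            region("chr1", 600_000, 640_000),
            region("chr1", 200_000, 260_000),
        ]
        genes = self._genes()
        res1 = cluster_enrichment(regions, genes, "^Olfr", self.GENOME, 200, seed=5)
        shuffled_regions = list(regions)
        shuffled_genes = list(genes)
        random.Random(3).shuffle(shuffled_regions)
        random.Random(4).shuffle(shuffled_genes)
        res2 = cluster_enrichment(
            shuffled_regions, shuffled_genes, "^Olfr", self.GENOME, 200, seed=5
        )
        assert res1 == res2
        res3 = cluster_enrichment(regions, genes, "^Olfr", self.GENOME, 200, seed=6)
        assert res3.k_observed == res1.k_observed
        assert res3 != res1  # background redrawn

    def test_single_bp_overlap_counts_but_full_containment_mode_does_not(self):
        # region overlaps Olfr0 (0..2000) by exactly one base and contains
        # no gene body (Olfr1 starts at 10,000)
        regions = [region("chr1", 1_999, 9_000)]
        res_any = cluster_enrichment(
            regions, self._genes(), "^Olfr", self.GENOME, 200, seed=2,
        )
        assert res_any.k_observed == 1
        res_full = cluster_enrichment(
            regions, self._genes(), "^Olfr", self.GENOME, 200, seed=2,
            containment="full",
        )
        assert res_full.k_observed == 0

    def test_continuity_correction_bounds_p_hat_away_from_zero(self):
        regions = [region("chr1", 0, 30_000)]
        res = cluster_enrichment(
            regions, self._genes(), "^Olfr", self.GENOME, 200, seed=7
        )
        assert 0.0 < res.p_hat < 1.0

    def test_strong_planted_enrichment_yields_small_p(self):
        import l1array as la

        cfg = la.SimConfig(
            genome={f"chr{i}": 10_000_000 for i in (1, 2)},
            n_arrays=20, n_background_genes=100, n_clusters=14,
            enrichment_factor=10.0,
        )
        b = la.simulate_annotation(cfg, seed=99, parts=("genes",))
        regions = [ArrayRegion(a.chrom, a.start, a.end) for a in b.truth.arrays]
        res = cluster_enrichment(regions, b.genes, "^Olfr", b.genome, 500, seed=99)
        assert res.p_value < 0.01
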