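"""LAD overlap classification and lineage stratification."""

import pytest

from l1array import (
    IntervalSet,
    LADCollection,
    LADStatus,
    LineageMap,
    RepeatFeature,
    lad_overlap,
    lineage_stratify,
)
from l1array.scan import ArrayRegion


def track(*intervals):
    return IntervalSet.from_tuples([("chr1", s, e) for s, e in intervals])


def l1(start, end, name="L1Md_A", chrom="chr1"):
    return RepeatFeature(chrom, start, end, "+", name, "LINE", "L1")


class TestLadOverlap:
    def test_overlap_threshold_edge_is_inclusive_at_exactly_10kb(self):
        region_9999 = ArrayRegion("chr1", 0, 9_999)
        region_10000 = ArrayRegion("chr1", 0, 10_000)
        lads = LADCollection({"ESC": track((0, 1_000_000))})
        _, s1 = lad_overlap([region_9999], lads, min_overlap=10_000)
        _, s2 = lad_overlap([region_10000], lads, min_overlap=10_000)
        assert (s1.n_any, s2.n_any) == (0, 1)

    def test_status_from_cell_type_counts(self):
        region = ArrayRegion("chr1", 0, 50_000)
        all4 = LADCollection({ct: track((0, 60_000)) for ct in "ABCD"})
        records, summary = lad_overlap([region], all4)
        assert records[0].status is LADStatus.CONSTITUTIVE
        assert summary.n_constitutive == 1

        one_of4 = LADCollection(
            {"A": track((0, 60_000)), **{ct: track((900_000, 950_000)) for ct in "BCD"}}
        )
        records, summary = lad_overlap([region], one_of4)
        assert records[0].status is LADStatus.FACULTATIVE
        assert records[0].overlapping_cell_types == ("A",)

        none = LADCollection({ct: track((900_000, 950_000)) for ct in "ABCD"})
        records, summary = lad_overlap([region], none)
        assert records[0].status is LADStatus.NONE
        assert summary.n_none == 1

    def test_adjacent_fragments_jointly_satisfy_the_rule(self):
        # two 6-kb fragments: each alone is below 10 kb, their union passes
        region = ArrayRegion("chr1", 0, 50_000)
        frag = LADCollection({"A": track((0, 6_000), (6_000, 12_000))})
        _, summary = lad_overlap([region], frag, min_overlap=10_000)
        assert summary.n_any == 1

    def test_counts_monotone_nonincreasing_in_min_overlap(self):
        regions = [ArrayRegion("chr1", i * 100_000, i * 100_000 + 50_000) for i in range(5)]
        lads = LADCollection(
            {"A": track((0, 20_000), (100_000, 130_000), (200_000, 215_000))}
        )
        prev = None
        for mo in (1, 5_000, 10_000, 15_000, 25_000):
            _, summary = lad_overlap(regions, lads, min_overlap=mo)
            if prev is not None:
                assert summary.n_any <= prev
            prev = summary.n_any

    def test_summary_partition_identity(self):
        regions = [ArrayRegion("chr1", i * 50_000, i * 50_000 + 30_000) for i in range(6)]
        lads = LADCollection(
            {"A": track((0, 40_000)), "B": track((0, 40_000), (100_000, 140_000))}
        )
        _, s = lad_overlap(regions, lads)
        assert s.n_any + s.n_none == s.n_regions == 6
        assert s.n_any == s.n_constitutive + s.n_facultative

    def test_synthetic_tracks_reproduce_generator_truth(self):
        import l1array as la

        cfg = la.SimConfig(genome={"chr1": 4_000_000, "chr2": 4_000_000}, n_arrays=8)
        b = la.simulate_annotation(cfg, seed=17, parts=("lads",))
        regions = [ArrayRegion(a.chrom, a.start, a.end) for a in b.truth.arrays]
        records, summary = lad_overlap(regions, b.lads, min_overlap=10_000)
        n_types = len(cfg.cell_types)
        per_array = [
            sum(i in b.truth.lad_covered[ct] for ct in cfg.cell_types)
            for i in range(len(regions))
        ]
        assert summary.n_constitutive == sum(c == n_types for c in per_array)
        assert summary.n_facultative == sum(0 < c < n_types for c in per_array)
        assert summary.n_none == sum(c == 0 for c in per_array)

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            lad_overlap([ArrayRegion("chr1", 0, 1000)], LADCollection({"A": track()}), 0)


class TestLineageMap:
    def test_default_mouse_prefix_rules(self):
        m = LineageMap.default_mouse()
        assert m.assign("L1Md_Tf") == "Mus"
        assert m.assign("Lx2") == "Muridae"
        assert m.assign("L1_Mur1") == "Rodent"
        assert m.assign("L1ME1") == "Eutherian"
        assert m.assign("HAL1") == "unassigned"

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("# prefix label\nL1PA Hominoid\nL1PB Primate\n")
        m = LineageMap.from_tsv(p)
        assert m.lineages == ("Hominoid", "Primate")
        assert m.assign("L1PA3") == "Hominoid"

    def test_rule_with_undeclared_label_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            LineageMap(rules=(("L1", "Ghost"),), lineages=("Mus",))


class TestLineageStratify:
    def test_no_regions_means_no_within_counts(self):
        repeats = [l1(0, 600), l1(1_000, 1_500, "Lx2")]
        table = lineage_stratify(repeats, [], LineageMap.default_mouse())
        assert all(v == 0 for v in table.within_arrays.values())
        assert table.genomewide["Mus"] == 1
        assert table.genomewide["Muridae"] == 1

    def test_every_repeat_inside_one_region_conserves_totals(self):
        repeats = [l1(i * 1_000, i * 1_000 + 500) for i in range(10)]
        regions = [ArrayRegion("chr1", 0, 100_000)]
        table = lineage_stratify(repeats, regions, LineageMap.default_mouse())
        assert table.within_arrays == table.genomewide

    def test_conservation_identity_on_arbitrary_input(self, rng):
        names = ["L1Md_A", "Lx3", "L1_Mur2", "L1MB5", "WeirdName"]
        repeats = [
            l1(int(s), int(s) + 300, names[int(rng.integers(0, len(names)))])
            for s in rng.integers(0, 1_000_000, 500)
        ]
        regions = [ArrayRegion("chr1", 100_000, 400_000)]
        table = lineage_stratify(repeats, regions, LineageMap.default_mouse())
        for lin in table.lineages:
            assert (
                table.within_arrays[lin] + table.outside_arrays[lin]
                == table.genomewide[lin]
            )
        n_l1 = sum(1 for r in repeats if r.rep_family.startswith("L1"))
        assert (
            sum(table.genomewide.values()) + table.unassigned_genomewide == n_l1
        )

    def test_membership_is_by_midpoint(self):
        region = ArrayRegion("chr1", 1_000, 2_000)
        straddle_in = l1(900, 1_200)    # midpoint 1050 inside
        straddle_out = l1(1_900, 3_000)  # midpoint 2450 outside
        table = lineage_stratify(
            [straddle_in, straddle_out], [region], LineageMap.default_mouse()
        )
        assert table.within_arrays["Mus"] == 1
        assert table.outside_arrays["Mus"] == 1

    def test_element_filter_restricts_to_l1_by_default(self):
        sine = RepeatFeature("chr1", 0, 300, "+", "B1_Mus1", "SINE", "Alu")
        table = lineage_stratify([sine, l1(0, 300)], [], LineageMap.default_mouse())
        assert sum(table.genomewide.values()) == 1

    def test_ratios_normalized_to_first_lineage(self):
        repeats = [l1(i * 1_000, i * 1_000 + 100, "L1MB5") for i in range(2)]
        repeats += [l1(i * 1_000 + 500, i * 1_000 + 600, "L1Md_A") for i in range(6)]
        table = lineage_stratify(repeats, [], LineageMap.default_mouse())
        ratios = table.ratios_genomewide()
        assert ratios["Eutherian"] == 1.0
        assert ratios["Mus"] == 3.0
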