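"""Window scanning, array calling and composition against per-base oracles."""

import math

import numpy as np
import pytest

from l1array import (
    GenomeMap,
    Interval,
    RepeatFeature,
    ScanParams,
    call_arrays,
    region_composition,
    window_scan,
)
from conftest import mask_of


def _line(chrom, start, end, name="L1Md_A"):
    return RepeatFeature(chrom, start, end, "+", name, "LINE", "L1")


def _sine(chrom, start, end):
    return RepeatFeature(chrom, start, end, "+", "B1_Mus1", "SINE", "Alu")


SMALL = ScanParams(window=100, step=100, min_density=0.7, min_length=100)


class TestScanParams:
    def test_presets_carry_the_standard_parameters(self):
        p = ScanParams.preset("line_array")
        assert (p.window, p.step, p.min_density, p.min_length) == (
            100_000, 10_000, 0.70, 100_000,
        )
        q = ScanParams.preset("imprinted")
        assert (q.window, q.step, q.min_density, q.min_length) == (
            50_000, 10_000, 0.40, 50_000,
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(step=0),
            dict(step=200_000),
            dict(min_density=0.0),
            dict(min_density=1.5),
            dict(min_length=50_000),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScanParams(**kwargs)


class TestWindowScan:
    def test_full_coverage_gives_unit_fractions(self):
        genome = GenomeMap({"chrT": 300})
        windows = window_scan([_line("chrT", 0, 300)], genome, SMALL)
        assert [(w.start, w.fraction) for w in windows] == [
            (0, 1.0), (100, 1.0), (200, 1.0),
        ]

    def test_no_line_features_gives_zero_fractions(self):
        genome = GenomeMap({"chrT": 300})
        windows = window_scan([_sine("chrT", 0, 300)], genome, SMALL)
        assert all(w.fraction == 0.0 for w in windows)

    def test_partial_windows_at_chromosome_end_are_dropped(self):
        genome = GenomeMap({"chrT": 250})
        windows = window_scan([], genome, SMALL)
        assert [w.start for w in windows] == [0, 100]  # 200+100 > 250

    def test_chromosome_shorter_than_window_yields_no_windows(self):
        genome = GenomeMap({"tiny": 50, "chrT": 300})
        windows = window_scan([], genome, SMALL)
        assert {w.chrom for w in windows} == {"chrT"}

    def test_fractions_match_per_base_oracle_on_random_annotations(self, rng):
        genome = GenomeMap({"chrT": 5_000})
        params = ScanParams(window=500, step=100, min_density=0.5, min_length=500)
        for _ in range(30):
            feats = []
            for _ in range(int(rng.integers(0, 60))):
                s = int(rng.integers(0, 4_900))
                e = min(5_000, s + 1 + int(rng.integers(0, 400)))
                cls = "LINE" if rng.random() < 0.7 else "SINE"
                feats.append(
                    RepeatFeature("chrT", s, e, "+", "x", cls, "L1" if cls == "LINE" else "Alu")
                )
            mask = mask_of(
                [Interval(f.chrom, f.start, f.end) for f in feats if f.rep_class == "LINE"],
                5_000,
            )
            for w in window_scan(feats, genome, params):
                assert w.covered_bp == int(mask[w.start : w.end].sum())
                assert w.fraction == pytest.approx(w.covered_bp / 500)

    def test_tiling_identity_when_step_equals_window(self, rng):
        # with s = W the scan tiles the chromosome: the mean fraction equals
        # the union coverage over the tiled bases exactly
        genome = GenomeMap({"chrT": 4_000})
        params = ScanParams(window=400, step=400, min_density=0.5, min_length=400)
        feats = [
            _line("chrT", int(s), int(s) + 1 + int(l))
            for s, l in zip(rng.integers(0, 3_900, 40), rng.integers(0, 300, 40))
        ]
        windows = window_scan(feats, genome, params)
        tiled = 400 * len(windows)
        mask = mask_of([Interval(f.chrom, f.start, min(f.end, tiled)) for f in feats], tiled)
        assert sum(w.fraction for w in windows) / len(windows) == pytest.approx(
            mask.sum() / tiled
        )


class TestCallArrays:
    def test_merge_arithmetic_of_qualifying_windows(self):
        params = ScanParams.preset("line_array")
        from l1array import WindowRecord

        windows = [
            WindowRecord("chr1", s, s + 100_000, 80_000, 0.8)
            for s in range(0, 60_000, 10_000)
        ]
        (region,) = call_arrays(windows, params)
        assert (region.start, region.end, region.n_windows) == (0, 150_000, 6)
        assert math.isnan(region.density)  # no repeats supplied

    def test_no_qualifying_windows_gives_empty_result(self):
        from l1array import WindowRecord

        params = ScanParams.preset("line_array")
        windows = [WindowRecord("chr1", 0, 100_000, 50_000, 0.5)]
        assert call_arrays(windows, params) == []

    def test_qualification_is_strictly_greater_than_threshold(self):
        from l1array import WindowRecord

        params = ScanParams.preset("line_array")
        at = WindowRecord("chr1", 0, 100_000, 70_000, 0.7)
        above = WindowRecord("chr1", 0, 100_000, 70_001, 0.70001)
        assert call_arrays([at], params) == []
        assert len(call_arrays([above], params)) == 1

    def test_span_shorter_than_min_length_is_dropped(self):
        from l1array import WindowRecord

        params = ScanParams(window=100_000, step=10_000, min_density=0.7,
                            min_length=120_000)
        windows = [WindowRecord("chr1", 0, 100_000, 90_000, 0.9)]
        assert call_arrays(windows, params) == []

    def test_density_recomputation_matches_per_base_oracle(self, rng):
        genome = GenomeMap({"chrT": 50_000})
        params = ScanParams(window=5_000, step=500, min_density=0.6, min_length=5_000)
        feats = []
        for _ in range(120):
            s = int(rng.integers(0, 49_000))
            feats.append(_line("chrT", s, min(50_000, s + 1 + int(rng.integers(0, 800)))))
        windows = window_scan(feats, genome, params)
        regions = call_arrays(windows, params, repeats=feats)
        mask = mask_of([Interval(f.chrom, f.start, f.end) for f in feats], 50_000)
        for r in regions:
            assert r.density == pytest.approx(mask[r.start : r.end].mean(), abs=1e-12)

    def test_raising_min_density_never_adds_or_extends_regions(self, rng):
        genome = GenomeMap({"chrT": 50_000})
        feats = []
        for _ in range(150):
            s = int(rng.integers(0, 49_000))
            feats.append(_line("chrT", s, min(50_000, s + 1 + int(rng.integers(0, 800)))))
        base = dict(window=5_000, step=500, min_length=5_000)
        prev = None
        for d in (0.5, 0.6, 0.7, 0.8):
            params = ScanParams(min_density=d, **base)
            regions = call_arrays(window_scan(feats, genome, params), params)
            if prev is not None:
                for r in regions:
                    assert any(
                        p.start <= r.start and r.end <= p.end for p in prev
                    ), f"region at d={d} not contained in any region at lower d"
            prev = regions

    def test_refined_region_is_contained_in_raw_span(self, rng):
        genome = GenomeMap({"chrT": 50_000})
        params = ScanParams(window=5_000, step=500, min_density=0.6, min_length=5_000)
        feats = []
        for _ in range(150):
            s = int(rng.integers(0, 49_000))
            feats.append(_line("chrT", s, min(50_000, s + 1 + int(rng.integers(0, 800)))))
        windows = window_scan(feats, genome, params)
        raw = call_arrays(windows, params)
        refined = call_arrays(windows, params, repeats=feats)
        for r in refined:
            assert any(p.start <= r.start and r.end <= p.end for p in raw)


class TestRegionComposition:
    def test_interval_fully_covered_by_one_l1(self):
        summary = region_composition(
            Interval("chrT", 100, 200), [_line("chrT", 0, 500)]
        )
        assert summary.fraction_of("LINE") == 1.0
        assert summary.total_interspersed_fraction == 1.0

    def test_mixed_classes_and_total(self):
        feats = [_line("chrT", 0, 500), _sine("chrT", 500, 750)]
        summary = region_composition(Interval("chrT", 0, 1_000), feats)
        assert summary.fraction_of("LINE") == 0.5
        assert summary.fraction_of("SINE") == 0.25
        assert summary.fraction_of("LTR") == 0.0
        assert summary.total_interspersed_fraction == 0.75

    def test_total_union_not_double_counted_for_overlapping_classes(self):
        feats = [_line("chrT", 0, 600), _sine("chrT", 400, 800)]
        summary = region_composition(Interval("chrT", 0, 1_000), feats)
        assert summary.total_interspersed_fraction == 0.8

    def test_matches_per_base_class_masks(self, rng):
        for _ in range(50):
            feats = []
            for _ in range(int(rng.integers(0, 40))):
                s = int(rng.integers(0, 900))
                e = min(1_000, s + 1 + int(rng.integers(0, 200)))
                cls = ("LINE", "SINE", "LTR")[int(rng.integers(0, 3))]
                feats.append(RepeatFeature("chrT", s, e, "+", "x", cls, ""))
            iv = Interval("chrT", 100, 900)
            summary = region_composition(iv, feats)
            union_mask = np.zeros(1_000, dtype=bool)
            for cls in ("LINE", "SINE", "LTR"):
                mask = mask_of(
                    [Interval(f.chrom, f.start, f.end) for f in feats if f.rep_class == cls],
                    1_000,
                )
                union_mask |= mask
                assert summary.fraction_of(cls) == pytest.approx(
                    mask[100:900].mean(), abs=1e-12
                )
            assert summary.total_interspersed_fraction == pytest.approx(
                union_mask[100:900].mean(), abs=1e-12
            )
            assert summary.total_interspersed_fraction <= 1.0
            assert summary.total_interspersed_fraction >= max(
                summary.fraction_of(c) for c in ("LINE", "SINE", "LTR")
            )
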