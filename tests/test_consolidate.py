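"""Summit extension, replicate intersection, and region filtering,
checked against brute-force per-bp oracles."""

import numpy as np
import pytest

from rubychip.consolidate import (
    ConsolidatedPeak,
    extend_summits,
    filter_regions,
    intersect_replicates,
)
from rubychip.intervals import GenomicInterval, merge_intervals
from rubychip.peaks import BlacklistRegion, PeakCall
from rubychip.tracks import CoverageTrack


def peak_at(summit, chrom="c"):
    return PeakCall(
        GenomicInterval(chrom, max(0, summit - 10), summit + 10),
        summit=summit,
        score=50.0,
        p_value=0.001,
        q_value=0.01,
    )


class TestExtendSummits:
    @pytest.mark.parametrize(
        "summit,flank,expected",
        [
            (10_000, 150, (9_850, 10_150)),
            (50, 150, (0, 200)),  # clamped at chromosome start
            (10_000, 0, (10_000, 10_001)),  # degenerate single-bp
        ],
    )
    def test_arithmetic(self, summit, flank, expected):
        (iv,) = extend_summits([peak_at(summit)], flank=flank)
        assert (iv.start, iv.end) == expected

    def test_clamped_at_chromosome_end(self):
        (iv,) = extend_summits(
            [peak_at(990)], flank=150, chrom_lengths={"c": 1000}
        )
        assert (iv.start, iv.end) == (840, 1000)

    def test_summit_outside_chromosome_errors(self):
        with pytest.raises(ValueError, match="outside"):
            extend_summits([peak_at(2000)], chrom_lengths={"c": 1000})

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            extend_summits([peak_at(100)], flank=-1)


class TestIntersectReplicates:
    def test_identical_regions_self_intersect(self):
        regions = [GenomicInterval("c", 9_850, 10_150)]
        (out,) = intersect_replicates(regions, regions)
        assert (out.interval.start, out.interval.end) == (9_850, 10_150)

    def test_recentering_on_midpoint(self):
        """[9850,10150) ∩ [9950,10250) = [9950,10150); midpoint 10050
        recenters to [9900,10200)."""
        a = [GenomicInterval("c", 9_850, 10_150)]
        b = [GenomicInterval("c", 9_950, 10_250)]
        (out,) = intersect_replicates(a, b)
        assert out.center == 10_050
        assert (out.interval.start, out.interval.end) == (9_900, 10_200)

    def test_disjoint_replicates_empty(self):
        a = [GenomicInterval("c", 0, 300)]
        b = [GenomicInterval("c", 1_000, 1_300)]
        assert intersect_replicates(a, b) == []

    def test_commutativity(self, rng):
        for _ in range(50):
            a = [
                GenomicInterval("c", int(s), int(s) + 300)
                for s in rng.integers(0, 5_000, 6)
            ]
            b = [
                GenomicInterval("c", int(s), int(s) + 300)
                for s in rng.integers(0, 5_000, 6)
            ]
            ab = intersect_replicates(a, b)
            ba = intersect_replicates(b, a)
            assert ab == ba

    def test_uniform_width_away_from_edges(self, rng):
        a = [
            GenomicInterval("c", int(s), int(s) + 300)
            for s in rng.integers(500, 5_000, 10)
        ]
        b = [
            GenomicInterval("c", int(s), int(s) + 300)
            for s in rng.integers(500, 5_000, 10)
        ]
        for out in intersect_replicates(a, b, chrom_lengths={"c": 10_000}):
            assert len(out.interval) == 300

    def test_matches_brute_force_oracle(self, rng):
        """Midpoints of per-bp intersection runs, re-centered to 300 bp."""
        for _ in range(100):
            a = merge_intervals(
                [
                    GenomicInterval("c", int(s), int(s) + int(w))
                    for s, w in zip(
                        rng.integers(200, 4_000, 5), rng.integers(50, 400, 5)
                    )
                ]
            )
            b = merge_intervals(
                [
                    GenomicInterval("c", int(s), int(s) + int(w))
                    for s, w in zip(
                        rng.integers(200, 4_000, 5), rng.integers(50, 400, 5)
                    )
                ]
            )
            got = intersect_replicates(a, b)

            # oracle: paint bases, find runs, recenter
            mask = np.zeros(6_000, dtype=bool)
            in_a = np.zeros(6_000, dtype=bool)
            in_b = np.zeros(6_000, dtype=bool)
            for iv in a:
                in_a[iv.start : iv.end] = True
            for iv in b:
                in_b[iv.start : iv.end] = True
            mask = in_a & in_b
            runs = []
            pos = 0
            while pos < len(mask):
                if mask[pos]:
                    start = pos
                    while pos < len(mask) and mask[pos]:
                        pos += 1
                    runs.append((start, pos))
                else:
                    pos += 1
            expected = sorted(
                {((s + e) // 2 - 150, (s + e) // 2 + 150) for s, e in runs}
            )
            assert [(p.interval.start, p.interval.end) for p in got] == expected


class TestFilterRegions:
    def region(self, start, end, chrom="c"):
        return ConsolidatedPeak(
            GenomicInterval(chrom, start, end), center=(start + end) // 2
        )

    def test_single_bp_blacklist_overlap_drops(self):
        regions = [self.region(100, 400)]
        blacklist = [BlacklistRegion(GenomicInterval("c", 399, 500))]
        kept, report = filter_regions(regions, blacklist)
        assert kept == []
        assert report.n_blacklisted == 1

    def test_abutting_blacklist_is_kept(self):
        regions = [self.region(100, 400)]
        blacklist = [BlacklistRegion(GenomicInterval("c", 400, 500))]
        kept, _ = filter_regions(regions, blacklist)
        assert len(kept) == 1

    def test_mappability_below_threshold_drops(self):
        regions = [self.region(100, 400)]
        mapp = CoverageTrack({"c": np.full(1_000, 0.24)}, scale="fraction")
        kept, report = filter_regions(regions, mappability=mapp, map_min=0.25)
        assert kept == []
        assert report.n_low_mappability == 1

    def test_clean_region_retained(self):
        regions = [self.region(100, 400)]
        mapp = CoverageTrack({"c": np.ones(1_000)}, scale="fraction")
        blacklist = [BlacklistRegion(GenomicInterval("c", 600, 700))]
        kept, report = filter_regions(regions, blacklist, mapp)
        assert len(kept) == 1 and report.n_kept == 1

    def test_min_criterion_stricter_than_mean(self):
        regions = [self.region(0, 100)]
        vec = np.ones(1_000)
        vec[50] = 0.0  # one dead base
        mapp = CoverageTrack({"c": vec}, scale="fraction")
        kept_mean, _ = filter_regions(regions, mappability=mapp, criterion="mean")
        kept_min, _ = filter_regions(regions, mappability=mapp, criterion="min")
        assert len(kept_mean) == 1 and kept_min == []

    def test_matches_brute_force_oracle(self, rng):
        mapp_vec = rng.random(5_000)
        mapp = CoverageTrack({"c": mapp_vec}, scale="fraction")
        for _ in range(100):
            regions = [
                self.region(int(s), int(s) + 300)
                for s in rng.integers(0, 4_500, 8)
            ]
            bl_iv = [
                GenomicInterval("c", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 4_500, 3), rng.integers(10, 400, 3))
            ]
            blacklist = [BlacklistRegion(iv) for iv in bl_iv]
            kept, _ = filter_regions(regions, blacklist, mapp, map_min=0.5)
            expected = []
            for r in regions:
                s, e = r.interval.start, r.interval.end
                hits_black = any(
                    any(s <= p < e for p in range(iv.start, iv.end))
                    for iv in bl_iv
                )
                if hits_black:
                    continue
                if mapp_vec[s:e].mean() < 0.5:
                    continue
                expected.append(r)
            assert kept == expected
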