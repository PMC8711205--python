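import math

import numpy as np
import pandas as pd
import pytest

from chromintegrate.intervals import FormatError, GenomicInterval
from chromintegrate.peakcalling import (
    FragmentFilterSpec,
    PeakSet,
    SignalBlock,
    call_peaks,
    condition_unique,
    filter_fragments,
    half_mean_filter,
    read_peakset,
    replicate_consensus,
    segment_signal_blocks,
    write_peakset,
)

from _oracles import allpairs_consensus, perbase_segment, random_blocks


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def block(start, end, auc, maxv=1.0, chrom="chr1"):
    return SignalBlock(iv(start, end, chrom), auc, maxv)


def track(*records):
    return pd.DataFrame(records, columns=["chrom", "start", "end", "value"])


class TestFilterFragments:
    def test_strictly_below_cap(self):
        frags = [iv(0, 150), iv(0, 999), iv(0, 1000), iv(0, 1500)]
        kept = filter_fragments(frags, FragmentFilterSpec(1000))
        assert [f.length for f in kept] == [150, 999]

    def test_empty_and_identity(self):
        assert filter_fragments([]) == []
        frags = [iv(0, 10), iv(5, 20)]
        assert filter_fragments(frags) == frags


class TestSegmentation:
    def test_adjacent_records_merge(self):
        blocks = segment_signal_blocks(
            track(("chr1", 0, 100, 2), ("chr1", 100, 200, 3),
                  ("chr1", 300, 400, 1))
        )
        assert [(b.region.start, b.region.end, b.auc, b.max_value)
                for b in blocks] == [(0, 200, 500.0, 3.0), (300, 400, 100.0, 1.0)]

    def test_zero_records_separate_blocks(self):
        blocks = segment_signal_blocks(
            track(("chr1", 0, 100, 2), ("chr1", 100, 200, 0),
                  ("chr1", 200, 300, 2))
        )
        assert len(blocks) == 2

    def test_all_zero_track_empty(self):
        assert segment_signal_blocks(track(("chr1", 0, 100, 0))) == []

    def test_unsorted_rejected(self):
        with pytest.raises(FormatError):
            segment_signal_blocks(
                track(("chr1", 100, 200, 1), ("chr1", 0, 50, 1))
            )

    def test_overlapping_rejected(self):
        with pytest.raises(FormatError):
            segment_signal_blocks(
                track(("chr1", 0, 100, 1), ("chr1", 50, 150, 1))
            )

    def test_matches_perbase_oracle_on_random_tracks(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            rows = []
            for chrom in ("chr1", "chr2"):
                pos = 0
                for _ in range(rng.integers(5, 40)):
                    gap = int(rng.integers(0, 3))
                    width = int(rng.integers(1, 30))
                    value = int(rng.integers(0, 4))
                    rows.append((chrom, pos + gap, pos + gap + width, value))
                    pos += gap + width
            df = track(*rows)
            got = sorted(
                (b.region.chrom, b.region.start, b.region.end, b.auc,
                 b.max_value)
                for b in segment_signal_blocks(df)
            )
            assert got == perbase_segment(rows)

    def test_auc_conservation(self):
        rng = np.random.default_rng(9)
        rows = []
        pos = 0
        for _ in range(100):
            gap = int(rng.integers(0, 2))
            width = int(rng.integers(1, 20))
            rows.append(("chr1", pos + gap, pos + gap + width,
                         int(rng.integers(0, 5))))
            pos += gap + width
        df = track(*rows)
        total = sum(v * (e - s) for _, s, e, v in rows if v > 0)
        assert sum(b.auc for b in segment_signal_blocks(df)) == total


class TestCallPeaks:
    def test_top_fraction_by_auc(self):
        blocks = [block(i * 10, i * 10 + 5, auc=i + 1) for i in range(100)]
        peaks = call_peaks(blocks, 0.05)
        assert sorted(p.auc for p in peaks.peaks) == [96, 97, 98, 99, 100]

    def test_ceiling_keeps_one_block(self):
        peaks = call_peaks([block(0, 5, auc=1)], 0.05)
        assert len(peaks) == 1

    def test_empty_input(self):
        assert len(call_peaks([], 0.05)) == 0

    def test_output_size_is_ceil(self):
        rng = np.random.default_rng(2)
        for n in (1, 7, 19, 100, 333):
            blocks = [
                block(i * 10, i * 10 + 5, auc=float(rng.integers(1, 50)))
                for i in range(n)
            ]
            for thr in (0.05, 0.3, 0.999):
                assert len(call_peaks(blocks, thr)) == math.ceil(thr * n)

    def test_matches_sort_slice_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        blocks = [
            block(i * 10, i * 10 + 5, auc=float(rng.integers(1, 10)))
            for i in range(50)
        ]
        peaks = call_peaks(blocks, 0.2)
        ranked = sorted(
            blocks, key=lambda b: (-b.auc, b.region.chrom, b.region.start)
        )
        assert set(
            (p.region.start, p.auc) for p in peaks.peaks
        ) == set((b.region.start, b.auc) for b in ranked[:10])

    def test_bad_mode_and_threshold(self):
        with pytest.raises(ValueError):
            call_peaks([], 0.05, mode="relaxed")
        with pytest.raises(ValueError):
            call_peaks([], 1.5)


class TestHalfMeanFilter:
    def test_arithmetic_example(self):
        ps = PeakSet("c", "r1", [block(0, 5, 10), block(10, 15, 10),
                                 block(20, 25, 1)])
        kept = half_mean_filter(ps)
        assert sorted(p.auc for p in kept.peaks) == [10, 10]

    def test_all_equal_all_retained(self):
        ps = PeakSet("c", "r1", [block(i * 10, i * 10 + 5, 7.0)
                                 for i in range(4)])
        assert len(half_mean_filter(ps)) == 4

    def test_dominant_peak_example(self):
        aucs = [100, 1, 1, 1, 1]
        ps = PeakSet("c", "r1", [block(i * 10, i * 10 + 5, a)
                                 for i, a in enumerate(aucs)])
        kept = half_mean_filter(ps)
        assert [p.auc for p in kept.peaks] == [100]

    def test_never_removes_max(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            aucs = rng.integers(1, 1000, size=rng.integers(1, 30))
            ps = PeakSet("c", "r1", [block(i * 10, i * 10 + 5, float(a))
                                     for i, a in enumerate(aucs)])
            kept = half_mean_filter(ps)
            assert max(aucs) in {p.auc for p in kept.peaks}

    def test_empty(self):
        assert len(half_mean_filter(PeakSet("c", "r1", []))) == 0


class TestReplicateConsensus:
    def test_containment_union(self):
        r1 = PeakSet("c", "r1", [block(100, 500, 10)])
        r2 = PeakSet("c", "r2", [block(150, 480, 20)])
        cons = replicate_consensus(r1, r2, 300)
        assert [(p.region.start, p.region.end, p.auc) for p in cons.peaks] == [
            (100, 500, 30)
        ]

    def test_below_min_overlap_dropped(self):
        r1 = PeakSet("c", "r1", [block(100, 500, 10)])
        r2 = PeakSet("c", "r2", [block(300, 900, 20)])
        assert len(replicate_consensus(r1, r2, 300)) == 0

    def test_chained_pairs_merge(self):
        r1 = PeakSet("c", "r1", [block(0, 1000, 1), block(1500, 2500, 2)])
        r2 = PeakSet("c", "r2", [block(500, 2000, 4)])
        cons = replicate_consensus(r1, r2, 300)
        assert [(p.region.start, p.region.end, p.auc) for p in cons.peaks] == [
            (0, 2500, 7)
        ]

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            r1 = random_blocks(rng, 30, chrom_length=30000, max_len=1500)
            r2 = random_blocks(rng, 30, chrom_length=30000, max_len=1500)
            cons = replicate_consensus(
                PeakSet("c", "r1", r1), PeakSet("c", "r2", r2), 300
            )
            got = sorted(
                (p.region.chrom, p.region.start, p.region.end, p.auc)
                for p in cons.peaks
            )
            r1s = sorted(r1, key=lambda b: (b.region.chrom, b.region.start))
            r2s = sorted(r2, key=lambda b: (b.region.chrom, b.region.start))
            assert got == allpairs_consensus(r1s, r2s, 300)

    def test_consensus_within_replicate_footprint(self):
        rng = np.random.default_rng(13)
        r1 = random_blocks(rng, 40, chrom_length=20000, max_len=1200)
        r2 = random_blocks(rng, 40, chrom_length=20000, max_len=1200)
        cons = replicate_consensus(
            PeakSet("c", "r1", r1), PeakSet("c", "r2", r2), 300
        )
        footprint = set()
        for b in r1 + r2:
            footprint.update(
                (b.region.chrom, p)
                for p in range(b.region.start, b.region.end)
            )
        for p in cons.peaks:
            for base in range(p.region.start, p.region.end):
                assert (p.region.chrom, base) in footprint


class TestConditionUnique:
    def test_disjoint_kept(self):
        a = PeakSet("t", "consensus", [block(0, 1000, 1)])
        b = PeakSet("c", "consensus", [block(2000, 3000, 1)])
        assert len(condition_unique(a, b)) == 1

    def test_single_base_overlap_disqualifies(self):
        a = PeakSet("t", "consensus", [block(0, 1000, 1)])
        b = PeakSet("c", "consensus", [block(999, 3000, 1)])
        assert len(condition_unique(a, b)) == 0

    def test_empty_other_is_identity(self):
        a = PeakSet("t", "consensus", [block(0, 1000, 1)])
        assert condition_unique(a, PeakSet("c", "consensus", [])).peaks == a.peaks


class TestPeakSetIO:
    def test_roundtrip(self, tmp_path):
        ps = PeakSet("t", "r1", [block(0, 500, 12.5, 3.0),
                                 block(900, 1400, 7.0, 2.0, chrom="chr2")])
        path = tmp_path / "peaks.tsv"
        write_peakset(path, ps)
        back = read_peakset(path, "t", "r1")
        assert [(p.region, p.auc, p.max_value) for p in back.peaks] == [
            (p.region, p.auc, p.max_value) for p in ps.peaks
        ]

    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValueError):
            PeakSet("c", "r1", [block(0, 100, 1), block(50, 150, 1)])
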