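import numpy as np
import pytest

from chromintegrate.annotation import (
    FeatureAssignment,
    TEAnnotation,
    assign_genes,
    feature_fractions,
    read_te_table,
    te_overlap_proportions,
    write_te_table,
)
from chromintegrate.differential import DifferentialRegion
from chromintegrate.intervals import GeneModel, GenomicInterval, genebody_flank
from chromintegrate.peakcalling import PeakSet, SignalBlock

from _oracles import allpairs_best_gene, random_intervals


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def peakset(*regions):
    return PeakSet(
        "c", "r", [SignalBlock(r, 1.0, 1.0) for r in regions]
    )


class TestAssignGenes:
    def test_promoter_precedence_over_genebody(self):
        # plus-strand gene: TSS window [45000, 53000) overlaps body start
        g = GeneModel("g", iv(50000, 80000, strand="+"))
        inside = assign_genes(peakset(iv(52000, 52500)), [g])
        assert inside[0].feature == "promoter"  # touches the TSS window
        deep = assign_genes(peakset(iv(60000, 60500)), [g])
        assert deep[0].feature == "genebody"

    def test_flank_assignment_and_intergenic(self):
        g = GeneModel("g", iv(50000, 60000, strand="+"))
        near = assign_genes(peakset(iv(64000, 64500)), [g])  # within 10 kb
        assert near[0] == FeatureAssignment(iv(64000, 64500), "g", "genebody")
        far = assign_genes(peakset(iv(90000, 90500)), [g])  # 30 kb away
        assert far[0] == FeatureAssignment(iv(90000, 90500), None, "intergenic")

    def test_largest_overlap_wins(self):
        g1 = GeneModel("g1", iv(10000, 30000, strand="+"))
        g2 = GeneModel("g2", iv(29000, 60000, strand="+"))
        # peak covers 1 kb of g1's body but 11 kb of g2's
        out = assign_genes(peakset(iv(29000, 40000)), [g1, g2], flank=0)
        assert out[0].gene_id == "g2"

    def test_every_peak_assigned_once(self):
        rng = np.random.default_rng(31)
        genes = [
            GeneModel(f"g{i}", iv(i * 30000 + 5000, i * 30000 + 15000,
                                  strand="+"))
            for i in range(5)
        ]
        peaks = sorted(
            random_intervals(rng, 30, n_chroms=1, chrom_length=160000),
            key=lambda r: r.start,
        )
        # thin to non-overlapping
        kept, prev = [], -1
        for p in peaks:
            if p.start > prev:
                kept.append(p)
                prev = p.end
        out = assign_genes(peakset(*kept), genes)
        assert len(out) == len(kept)

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(15):
            genes = []
            pos = 0
            for i in range(rng.integers(3, 10)):
                start = pos + int(rng.integers(1000, 20000))
                length = int(rng.integers(2000, 20000))
                genes.append(
                    GeneModel(f"g{i}", iv(start, start + length, strand="+"))
                )
                pos = start + length
            flank = int(rng.integers(0, 15000))
            flanked = [(g, genebody_flank(g, flank)) for g in genes]
            peaks, prev = [], -1
            for p in sorted(
                random_intervals(rng, 20, n_chroms=1, chrom_length=pos + 30000),
                key=lambda r: r.start,
            ):
                if p.start > prev:
                    peaks.append(p)
                    prev = p.end
            out = assign_genes(peakset(*peaks), genes, flank)
            for a in out:
                assert a.gene_id == allpairs_best_gene(a.peak, flanked)


class TestFeatureFractions:
    def test_proportions(self):
        assignments = (
            [FeatureAssignment(iv(i * 10, i * 10 + 5), "g", "genebody")
             for i in range(6)]
            + [FeatureAssignment(iv(100 + i * 10, 105 + i * 10), "g",
                                 "promoter") for i in range(3)]
            + [FeatureAssignment(iv(200, 205), None, "intergenic")]
        )
        assert feature_fractions(assignments) == {
            "genebody": 0.6, "promoter": 0.3, "intergenic": 0.1
        }

    def test_all_promoter(self):
        a = [FeatureAssignment(iv(0, 5), "g", "promoter")]
        assert feature_fractions(a) == {"promoter": 1.0}

    def test_order_invariant_and_sums_to_one(self):
        rng = np.random.default_rng(33)
        feats = rng.choice(["promoter", "genebody", "intergenic"], 50)
        assignments = [
            FeatureAssignment(
                iv(i * 10, i * 10 + 5),
                None if f == "intergenic" else "g",
                str(f),
            )
            for i, f in enumerate(feats)
        ]
        fwd = feature_fractions(assignments)
        rev = feature_fractions(assignments[::-1])
        assert fwd == rev
        assert sum(fwd.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            feature_fractions([])


def diff(start, end, direction, chrom="chr1"):
    lfc = 3.0 if direction == "gained-open" else -3.0
    return DifferentialRegion(iv(start, end, chrom), lfc, 1e-5, direction)


class TestTEOverlapProportions:
    def test_counting_rule(self):
        # 10 gained-open TE-overlapped peaks; 4 hit LTR, 2 hit SINE,
        # one of them hits both
        peaks = [diff(i * 10000, i * 10000 + 500, "gained-open")
                 for i in range(10)]
        tes = []
        for i in range(4):
            tes.append(TEAnnotation(iv(i * 10000, i * 10000 + 100), "LTR"))
        tes.append(TEAnnotation(iv(3 * 10000 + 200, 3 * 10000 + 300), "SINE"))
        tes.append(TEAnnotation(iv(4 * 10000, 4 * 10000 + 100), "SINE"))
        # peaks 5..9 overlap a LINE so all ten count as TE-overlapped
        for i in range(5, 10):
            tes.append(TEAnnotation(iv(i * 10000, i * 10000 + 50), "LINE"))
        props = te_overlap_proportions(peaks, tes)
        assert props[("gained-open", "LTR")] == pytest.approx(40.0)
        assert props[("gained-open", "SINE")] == pytest.approx(20.0)

    def test_no_te_overlap_empty(self):
        peaks = [diff(0, 500, "gained-open")]
        tes = [TEAnnotation(iv(5000, 6000), "LTR")]
        assert te_overlap_proportions(peaks, tes) == {}

    def test_all_peaks_denominator_switch(self):
        peaks = [diff(0, 500, "gained-open"),
                 diff(10000, 10500, "gained-open")]
        tes = [TEAnnotation(iv(0, 100), "LTR")]
        default = te_overlap_proportions(peaks, tes)
        assert default[("gained-open", "LTR")] == pytest.approx(100.0)
        alla = te_overlap_proportions(peaks, tes, denominator="all")
        assert alla[("gained-open", "LTR")] == pytest.approx(50.0)

    def test_unchanged_rejected(self):
        with pytest.raises(ValueError):
            te_overlap_proportions(
                [DifferentialRegion(iv(0, 500), 0.0, 1.0, "unchanged")], []
            )

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(10):
            peaks = []
            for i, r in enumerate(
                random_intervals(rng, 40, n_chroms=2, chrom_length=50000)
            ):
                d = "gained-open" if i % 2 else "gained-closed"
                peaks.append(
                    DifferentialRegion(r, 3.0 if i % 2 else -3.0, 1e-5, d)
                )
            tes = [
                TEAnnotation(r, ["LTR", "SINE", "LINE", "DNA"][i % 4])
                for i, r in enumerate(
                    random_intervals(rng, 60, n_chroms=2, chrom_length=50000)
                )
            ]
            props = te_overlap_proportions(peaks, tes)
            for (direction, cls), pct in props.items():
                assert 0.0 <= pct <= 100.0
                dirs = [p for p in peaks if p.direction == direction]
                member = [
                    {
                        t.te_class
                        for t in tes
                        if t.region.chrom == p.region.chrom
                        and min(t.region.end, p.region.end)
                        > max(t.region.start, p.region.start)
                    }
                    for p in dirs
                ]
                n_te = sum(1 for m in member if m)
                hits = sum(1 for m in member if cls in m)
                assert pct == pytest.approx(100.0 * hits / n_te)


class TestTEIO:
    def test_roundtrip(self, tmp_path):
        tes = [TEAnnotation(iv(0, 300), "LTR"),
               TEAnnotation(iv(500, 900, chrom="chr2"), "SINE")]
        path = tmp_path / "te.tsv"
        write_te_table(path, tes)
        assert read_te_table(path) == tes
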