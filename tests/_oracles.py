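"""Independent brute-force oracles used by the property and acceptance tests.

Each oracle computes the expected answer by per-base marking or exhaustive
pair enumeration, deliberately avoiding the package's sweep/sort code paths.
"""

from __future__ import annotations

import math

import numpy as np

from chromintegrate.intervals import GenomicInterval
from chromintegrate.peakcalling import SignalBlock


def perbase_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length by marking occupied bases in arrays."""
    if a.chrom != b.chrom:
        return 0
    hi = max(a.end, b.end)
    occ_a = np.zeros(hi, dtype=bool)
    occ_b = np.zeros(hi, dtype=bool)
    occ_a[a.start:a.end] = True
    occ_b[b.start:b.end] = True
    return int((occ_a & occ_b).sum())


def perbase_segment(records) -> list[tuple[str, int, int, float, float]]:
    """Signal-block segmentation by scanning a dense per-base signal array.

    ``records`` is an iterable of (chrom, start, end, value).  Returns
    (chrom, start, end, auc, max_value) per maximal positive run.
    """
    by_chrom: dict[str, list] = {}
    for chrom, start, end, value in records:
        by_chrom.setdefault(chrom, []).append((start, end, value))
    blocks = []
    for chrom in by_chrom:
        hi = max(e for _, e, _ in by_chrom[chrom])
        sig = np.zeros(hi + 1)
        for s, e, v in by_chrom[chrom]:
            sig[s:e] = v
        i = 0
        while i <= hi:
            if sig[i] > 0:
                j = i
                while j <= hi and sig[j] > 0:
                    j += 1
                run = sig[i:j]
                blocks.append(
                    (chrom, i, j, float(run.sum()), float(run.max()))
                )
                i = j
            else:
                i += 1
    return sorted(blocks)


def allpairs_consensus(
    rep1: list[SignalBlock], rep2: list[SignalBlock], min_overlap: int
) -> list[tuple[str, int, int, float]]:
    """Consensus regions by exhaustive pair enumeration plus span merging.

    Returns sorted (chrom, start, end, auc) tuples.
    """
    spans = []
    for i, p1 in enumerate(rep1):
        for j, p2 in enumerate(rep2):
            if perbase_overlap(p1.region, p2.region) >= min_overlap:
                spans.append(
                    (
                        p1.region.chrom,
                        min(p1.region.start, p2.region.start),
                        max(p1.region.end, p2.region.end),
                        i,
                        j,
                    )
                )
    # merge strictly overlapping spans, pooling contributors
    merged: list[list] = []
    for chrom, s, e, i, j in sorted(spans):
        if merged and merged[-1][0] == chrom and s < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][3].add(("a", i))
            merged[-1][3].add(("b", j))
        else:
            merged.append([chrom, s, e, {("a", i), ("b", j)}])
    out = []
    for chrom, s, e, contributors in merged:
        auc = sum(
            (rep1[i].auc if side == "a" else rep2[i].auc)
            for side, i in contributors
        )
        out.append((chrom, s, e, auc))
    return sorted(out)


def allpairs_best_gene(peak: GenomicInterval, flanked) -> str | None:
    """Gene assignment by exhaustive overlap comparison.

    ``flanked`` is a list of (gene, flanked_interval); ties break by
    smallest gene start, then gene_id.
    """
    best = None
    for g, fb in flanked:
        ov = perbase_overlap(peak, fb)
        if ov > 0:
            key = (-ov, g.body.start, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g.gene_id)
    return None if best is None else best[1]


def binom_minlike_exact(k: int, n: int, pi: float) -> float:
    """Two-sided minlike binomial p by direct pmf enumeration (math.comb)."""
    pmf = [
        math.comb(n, x) * pi**x * (1 - pi) ** (n - x) for x in range(n + 1)
    ]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7)))


def random_intervals(
    rng: np.random.Generator,
    n: int,
    n_chroms: int = 3,
    chrom_length: int = 100_000,
    max_len: int = 2000,
) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(n_chroms) + 1}"
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, chrom_length - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_blocks(
    rng: np.random.Generator, n: int, **kw
) -> list[SignalBlock]:
    """Random non-overlapping blocks (per chrom) for consensus tests."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in random_intervals(rng, 3 * n, **kw):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    blocks = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: i.start)
        prev_end = -1
        for iv in ivs:
            if iv.start > prev_end:
                blocks.append(
                    SignalBlock(iv, float(rng.integers(1, 1000)),
                                float(rng.integers(1, 50)))
                )
                prev_end = iv.end
            if len(blocks) >= n:
                break
    return blocks
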