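"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: intersection by O(n*m)
pairwise comparison, densities by per-base bitmaps, and the exact test by
integer enumeration of the hypergeometric support.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from lnccensus.genomic_io import GenomicInterval


def brute_force_hits(
    query: GenomicInterval,
    stored: list[GenomicInterval],
    min_overlap_nt: int = 1,
) -> list[tuple[str, int, int]]:
    out = []
    for s in stored:
        if s.chrom != query.chrom:
            continue
        if min(s.end, query.end) - max(s.start, query.start) >= min_overlap_nt:
            out.append((s.chrom, s.start, s.end))
    return sorted(out)


def hypergeom_tail_enum(a: int, b: int, c: int, d: int, direction: str = "greater") -> float:
    """Exact tail by integer enumeration over the support."""
    r1, c1 = a + b, a + c
    N = a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    ks = range(a, hi + 1) if direction == "greater" else range(lo, a + 1)
    num = sum(comb(r1, k) * comb(N - r1, c1 - k) for k in ks)
    return float(Fraction(num, comb(N, c1)))


def bitmap_coverage(
    intervals: list[GenomicInterval], chrom_sizes: dict[str, int]
) -> dict[str, list[bool]]:
    cover = {c: [False] * n for c, n in chrom_sizes.items()}
    for iv in intervals:
        for i in range(iv.start, min(iv.end, chrom_sizes[iv.chrom])):
            cover[iv.chrom][i] = True
    return cover


def bitmap_total(intervals: list[GenomicInterval], chrom_sizes: dict[str, int]) -> int:
    return sum(sum(v) for v in bitmap_coverage(intervals, chrom_sizes).values())


def bitmap_overlap_nt(
    a: list[GenomicInterval], b: list[GenomicInterval], chrom_sizes: dict[str, int]
) -> int:
    ca = bitmap_coverage(a, chrom_sizes)
    cb = bitmap_coverage(b, chrom_sizes)
    return sum(
        sum(x and y for x, y in zip(ca[c], cb[c])) for c in chrom_sizes
    )


def mean_score_per_base(
    intervals: list[GenomicInterval],
    track: list[tuple[GenomicInterval, float]],
    chrom_sizes: dict[str, int],
) -> float:
    score = {c: [0.0] * n for c, n in chrom_sizes.items()}
    for iv, v in track:
        for i in range(iv.start, min(iv.end, chrom_sizes[iv.chrom])):
            score[iv.chrom][i] = v
    cover = bitmap_coverage(intervals, chrom_sizes)
    total = acc = 0
    for c in chrom_sizes:
        for i, covered in enumerate(cover[c]):
            if covered:
                total += 1
                acc += score[c][i]
    return acc / total if total else float("nan")
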