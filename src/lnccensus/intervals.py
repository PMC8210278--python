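"""Interval intersection, exon projection, shuffling and permutation nulls.

The intersection index is the workhorse behind every ">= 1 nt overlap"
operation in the pipeline. Stored intervals are held per chromosome in an
interval tree for hit retrieval, plus merged sorted arrays for fast
overlap-any counting during permutation nulls.

The shuffle places each interval uniformly at random over all valid start
positions in the genome (length preserved exactly, overlaps among shuffled
intervals permitted), which is the null model for the overlap-enrichment
permutation test: the empirical p-value uses the add-one estimator
``(1 + #{null >= observed}) / (n_iter + 1)`` so it can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import GeneModel, GenomicInterval


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Output is sorted by (chrom, start) and therefore deterministic.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


class IntervalIndex:
    """Searchable per-chromosome structure over a fixed set of intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        # the payload carries the input position so duplicate intervals are
        # kept distinct inside the tree (it is set-backed)
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = (i, iv)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in _group_by_chrom(self.intervals).items():
            m = merge_intervals(ivs)
            self._merged[chrom] = (
                np.array([i.start for i in m], dtype=np.int64),
                np.array([i.end for i in m], dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def query(self, iv: GenomicInterval, min_overlap_nt: int = 1) -> list[GenomicInterval]:
        """Stored intervals overlapping ``iv`` by at least ``min_overlap_nt``."""
        if min_overlap_nt < 1:
            raise ValueError("min_overlap_nt must be >= 1")
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [t.data for t in tree.overlap(iv.start, iv.end)]
        hits = [(i, h) for i, h in hits if iv.overlap_length(h) >= min_overlap_nt]
        hits.sort(key=lambda ih: (ih[1].start, ih[1].end, ih[1].name or "", ih[0]))
        return [h for _, h in hits]

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        return bool(self.query(iv))

    def overlaps_any_bulk(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized overlap-any for arrays of query coordinates on one chrom."""
        if chrom not in self._merged:
            return np.zeros(len(starts), dtype=bool)
        m_starts, m_ends = self._merged[chrom]
        n_before_end = np.searchsorted(m_starts, ends, side="left")
        n_closed = np.searchsorted(m_ends, starts, side="right")
        return n_before_end > n_closed


def _group_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def intersect(
    query_intervals: Sequence[GenomicInterval],
    index: IntervalIndex,
    min_overlap_nt: int = 1,
) -> list[tuple[GenomicInterval, list[GenomicInterval]]]:
    """Pair each query with all stored intervals it overlaps by >= min_overlap_nt."""
    return [(q, index.query(q, min_overlap_nt)) for q in query_intervals]


def project_exons(gene_set: Iterable[GeneModel]) -> tuple[list[GenomicInterval], int]:
    """Merged, disjoint exonic intervals of a gene set (the "exon body")
    and the total exonic nt. Empty gene set projects to nothing."""
    exons = [e for g in gene_set for e in g.exons()]
    if not exons:
        return [], 0
    merged = merge_intervals(exons)
    return merged, total_length(merged)


# ---------------------------------------------------------------------------
# Shuffling and the permutation null
# ---------------------------------------------------------------------------


def _placement_weights(length: int, chrom_names: list[str], sizes: np.ndarray) -> np.ndarray:
    """Number of valid start positions per chromosome for an interval length."""
    return np.maximum(sizes - length + 1, 0)


def shuffle(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    mode: str = "genome_wide",
    rng: np.random.Generator | int | None = None,
) -> list[GenomicInterval]:
    """Randomly re-place intervals, preserving each length exactly.

    ``genome_wide`` draws the chromosome proportionally to its number of
    valid start positions, so placement is uniform over all valid starts in
    the genome; ``per_chrom`` keeps each interval on its own chromosome.
    Shuffled intervals may overlap each other.
    """
    rng = np.random.default_rng(rng)
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[n] for n in names], dtype=np.int64)
    out: list[GenomicInterval] = []
    for iv in intervals:
        if mode == "genome_wide":
            w = _placement_weights(iv.length, names, sizes)
            total = w.sum()
            if total <= 0:
                raise ValueError(f"interval of length {iv.length} exceeds every chromosome")
            u = rng.integers(0, total)
            cum = np.cumsum(w)
            ci = int(np.searchsorted(cum, u, side="right"))
            start = int(u - (cum[ci - 1] if ci else 0))
            chrom = names[ci]
        elif mode == "per_chrom":
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {iv.chrom}")
            npos = chrom_sizes[iv.chrom] - iv.length + 1
            if npos <= 0:
                raise ValueError(f"interval of length {iv.length} exceeds {iv.chrom}")
            start = int(rng.integers(0, npos))
            chrom = iv.chrom
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        out.append(GenomicInterval(chrom, start, start + iv.length, name=iv.name))
    return out


@dataclass
class ShuffleNullResult:
    """Observed overlap count against its permutation null distribution."""

    observed_overlap_count: int
    null_counts: list[int]
    empirical_p: float
    n_iterations: int
    seed: int | None
    observed_targets_hit: int = 0

    def write_null_counts(self, path) -> None:
        with open(path, "wt") as fh:
            for c in self.null_counts:
                fh.write(f"{c}\n")


def shuffle_null_overlap(
    query_intervals: Sequence[GenomicInterval],
    target_index: IntervalIndex,
    chrom_sizes: Mapping[str, int],
    n_iter: int = 1000,
    rng_seed: int | None = None,
    mode: str = "genome_wide",
) -> ShuffleNullResult:
    """Permutation test: do queries overlap targets more than shuffled queries?

    The statistic is the number of query intervals hitting >= 1 target (not
    the number of pairs). The number of distinct targets hit by the observed
    queries is also reported, since both tallies are of interest when the
    targets are transcripts.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng_seed)
    observed = sum(1 for q in query_intervals if target_index.overlaps_any(q))
    hit_targets = {
        t.as_key() for q in query_intervals for t in target_index.query(q)
    }

    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[n] for n in names], dtype=np.int64)
    null_hits = np.zeros(n_iter, dtype=np.int64)
    for q in query_intervals:
        L = q.length
        if mode == "genome_wide":
            w = _placement_weights(L, names, sizes)
            total = w.sum()
            if total <= 0:
                raise ValueError(f"interval of length {L} exceeds every chromosome")
            cum = np.cumsum(w)
            u = rng.integers(0, total, size=n_iter)
            cidx = np.searchsorted(cum, u, side="right")
            starts = u - np.where(cidx > 0, cum[cidx - 1], 0)
        elif mode == "per_chrom":
            npos = chrom_sizes[q.chrom] - L + 1
            if npos <= 0:
                raise ValueError(f"interval of length {L} exceeds {q.chrom}")
            cidx = np.full(n_iter, names.index(q.chrom))
            starts = rng.integers(0, npos, size=n_iter)
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        for ci in np.unique(cidx):
            sel = cidx == ci
            s = starts[sel]
            hit = target_index.overlaps_any_bulk(names[int(ci)], s, s + L)
            null_hits[np.flatnonzero(sel)[hit]] += 1

    empirical_p = (1 + int((null_hits >= observed).sum())) / (n_iter + 1)
    return ShuffleNullResult(
        observed_overlap_count=observed,
        null_counts=null_hits.tolist(),
        empirical_p=empirical_p,
        n_iterations=n_iter,
        seed=rng_seed,
        observed_targets_hit=len(hit_targets),
    )
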