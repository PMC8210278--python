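"""Chain-based remapping of common insertion sites and gene assignment.

Transposon insertional-mutagenesis screens in mouse yield common insertion
sites (CIS): loci recurrently hit by transposons in tumours. To transfer
those hits to the human annotation, each CIS is remapped through UCSC chain
alignments (the same machinery as LiftOver, reimplemented here on parsed
chains) and the resulting human-coordinate interval (hCIS) is assigned to a
gene category with protein-coding precedence:

* any overlapping protein-coding gene span (>= 1 nt) -> category ``pc``;
* else any overlapping lncRNA gene span -> category ``lncRNA``;
* else ``intergenic``.

Genes of other biotypes are transparent: they never capture an hCIS. All
overlapped gene IDs of the winning category are reported.

Only the single best-scoring chain overlapping an interval is used (the
default single-hit behaviour of LiftOver); an interval maps when at least
``min_match`` of its bases fall inside that chain's aligned blocks.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .genomic_io import Annotation, ChainAlignment, GenomicInterval
from .intervals import IntervalIndex

CATEGORY_PC = "pc"
CATEGORY_LNC = "lncRNA"
CATEGORY_INTERGENIC = "intergenic"


@dataclass
class CISRecord:
    """A common insertion site in the source (mouse) genome."""

    interval: GenomicInterval
    study_id: str
    predicted_effect: str | None = None  # gain | loss | unknown

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")


@dataclass
class LiftoverParams:
    """Remapping thresholds.

    ``min_match`` is the minimum fraction of the interval's bases that must
    fall in aligned blocks of the chosen chain; ``min_blocks`` is the
    minimum fraction of its bases inside blocks relative to its bases inside
    the chain's span. Defaults of 0.1/0.1 are the permissive settings used
    for cross-species remapping of insertion sites.
    """

    min_match: float = 0.1
    min_blocks: float = 0.1

    def __post_init__(self) -> None:
        for v in (self.min_match, self.min_blocks):
            if not (0 < v <= 1):
                raise ValueError("liftover thresholds must be in (0, 1]")


@dataclass
class Unmapped:
    """Machine-readable reason an interval failed to remap."""

    interval: GenomicInterval
    reason: str  # no_chain | empty_projection | min_match | min_blocks


@dataclass
class HCISAssignment:
    """A lifted CIS (hCIS) with its gene category in the target genome."""

    hcis: GenomicInterval
    source_cis: CISRecord
    category: str
    gene_ids: list[str] = field(default_factory=list)


class _ChainLifter:
    """Precomputed block offsets for mapping intervals through one chain."""

    def __init__(self, chain: ChainAlignment):
        self.chain = chain
        self.s_starts: list[int] = []
        self.t_starts: list[int] = []
        self.sizes: list[int] = []
        s, t = chain.s_start, chain.t_start
        for size, ds, dt in chain.blocks:
            self.s_starts.append(s)
            self.t_starts.append(t)
            self.sizes.append(size)
            s += size + ds
            t += size + dt

    def map_interval(self, iv: GenomicInterval) -> tuple[int, int, int] | None:
        """Return (target_lo, target_hi, mapped_bases) in chain target
        coordinates (pre strand flip), or None if no base maps."""
        lo, hi, mapped = None, None, 0
        # first block that could overlap: the one preceding iv.start
        i = max(0, bisect_right(self.s_starts, iv.start) - 1)
        for j in range(i, len(self.sizes)):
            bs, bt, size = self.s_starts[j], self.t_starts[j], self.sizes[j]
            if bs >= iv.end:
                break
            o_lo = max(iv.start, bs)
            o_hi = min(iv.end, bs + size)
            if o_hi <= o_lo:
                continue
            mapped += o_hi - o_lo
            t_lo = bt + (o_lo - bs)
            t_hi = bt + (o_hi - bs)
            lo = t_lo if lo is None else min(lo, t_lo)
            hi = t_hi if hi is None else max(hi, t_hi)
        if mapped == 0:
            return None
        return lo, hi, mapped


def liftover_interval(
    iv: GenomicInterval,
    chains: Sequence[ChainAlignment],
    params: LiftoverParams = LiftoverParams(),
) -> GenomicInterval | Unmapped:
    """Map one interval through the best-scoring overlapping chain.

    Every source base inside aligned blocks is mapped by block arithmetic;
    the result spans from the minimum to the maximum mapped target position.
    Reverse-strand chains have their target coordinates flipped back to
    forward-strand convention.
    """
    candidates = [
        c for c in chains
        if c.s_name == iv.chrom and min(iv.end, c.s_end) > max(iv.start, c.s_start)
    ]
    if not candidates:
        return Unmapped(iv, "no_chain")
    best = max(candidates, key=lambda c: c.score)
    res = _ChainLifter(best).map_interval(iv)
    if res is None:
        return Unmapped(iv, "empty_projection")
    lo, hi, mapped = res
    if mapped / iv.length < params.min_match:
        return Unmapped(iv, "min_match")
    span_overlap = min(iv.end, best.s_end) - max(iv.start, best.s_start)
    if mapped / span_overlap < params.min_blocks:
        return Unmapped(iv, "min_blocks")
    if best.t_strand == "-":
        lo, hi = best.t_size - hi, best.t_size - lo
    return GenomicInterval(best.t_name, lo, hi, name=iv.name)


@dataclass
class LiftoverReport:
    n_input: int = 0
    n_mapped: int = 0
    unmapped_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped_by_reason.values())


def liftover_cis(
    cis_set: Sequence[CISRecord],
    chains: Sequence[ChainAlignment],
    params: LiftoverParams = LiftoverParams(),
) -> tuple[list[tuple[CISRecord, GenomicInterval]], LiftoverReport, list[tuple[CISRecord, Unmapped]]]:
    """Remap a CIS collection; output order follows input order."""
    # group chains by source chromosome once to avoid rescanning
    by_chrom: dict[str, list[ChainAlignment]] = {}
    for c in chains:
        by_chrom.setdefault(c.s_name, []).append(c)
    report = LiftoverReport(n_input=len(cis_set))
    mapped: list[tuple[CISRecord, GenomicInterval]] = []
    failed: list[tuple[CISRecord, Unmapped]] = []
    for cis in cis_set:
        res = liftover_interval(cis.interval, by_chrom.get(cis.interval.chrom, []), params)
        if isinstance(res, Unmapped):
            report.unmapped_by_reason[res.reason] = (
                report.unmapped_by_reason.get(res.reason, 0) + 1
            )
            failed.append((cis, res))
        else:
            report.n_mapped += 1
            mapped.append((cis, res))
    return mapped, report, failed


def assign_hcis(
    hcis_list: Sequence[tuple[CISRecord, GenomicInterval]],
    annotation: Annotation,
) -> list[HCISAssignment]:
    """Assign each hCIS to pc / lncRNA / intergenic with pc precedence.

    Overlap is evaluated at gene-span level (>= 1 nt). The categorisation is
    independent of annotation input order because both candidate gene lists
    are consulted for every hCIS.
    """
    pc_index = IntervalIndex(annotation.spans(["protein_coding"]))
    lnc_index = IntervalIndex(annotation.spans(["lncRNA"]))
    out: list[HCISAssignment] = []
    for cis, hcis in hcis_list:
        pc_hits = pc_index.query(hcis)
        if pc_hits:
            out.append(
                HCISAssignment(hcis, cis, CATEGORY_PC, sorted({h.name for h in pc_hits}))
            )
            continue
        lnc_hits = lnc_index.query(hcis)
        if lnc_hits:
            out.append(
                HCISAssignment(hcis, cis, CATEGORY_LNC, sorted({h.name for h in lnc_hits}))
            )
            continue
        out.append(HCISAssignment(hcis, cis, CATEGORY_INTERGENIC, []))
    return out


@dataclass
class AssignmentSummary:
    hcis_per_category: dict[str, int]
    hcis_per_gene: dict[str, int]
    genes_per_category: dict[str, int]


def summarize_assignments(assignments: Sequence[HCISAssignment]) -> AssignmentSummary:
    """Tally hCIS per category, distinct hCIS per gene and distinct genes hit."""
    per_cat = {CATEGORY_PC: 0, CATEGORY_LNC: 0, CATEGORY_INTERGENIC: 0}
    per_gene: dict[str, int] = {}
    genes_by_cat: dict[str, set[str]] = {CATEGORY_PC: set(), CATEGORY_LNC: set()}
    for a in assignments:
        per_cat[a.category] += 1
        for gid in a.gene_ids:
            per_gene[gid] = per_gene.get(gid, 0) + 1
            genes_by_cat.setdefault(a.category, set()).add(gid)
    return AssignmentSummary(
        hcis_per_category=per_cat,
        hcis_per_gene=per_gene,
        genes_per_category={k: len(v) for k, v in genes_by_cat.items()},
    )


def write_assignments(assignments: Sequence[HCISAssignment], path) -> None:
    with open(path, "wt") as fh:
        fh.write("chrom\tstart\tend\tcis_id\tcategory\tgene_ids\n")
        for a in assignments:
            fh.write(
                f"{a.hcis.chrom}\t{a.hcis.start}\t{a.hcis.end}\t"
                f"{a.source_cis.interval.name or a.source_cis.study_id}\t"
                f"{a.category}\t{','.join(a.gene_ids) if a.gene_ids else '.'}\n"
            )
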