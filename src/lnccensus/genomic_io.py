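"""Readers and writers for the genomic file formats used by the pipeline.

All coordinates are held internally as 0-based half-open intervals on a named
sequence. Formats with other conventions (GTF, SNP tables: 1-based) are
converted at the parsing boundary and converted back on write, so no other
module needs to know about coordinate dialects.

Every reader transparently accepts gzip-compressed input (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Core positional types
# ---------------------------------------------------------------------------


@dataclass
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval coordinates [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def as_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)


@dataclass
class GeneModel:
    """A gene with its transcripts and a collapsed biotype.

    ``biotype`` is one of ``protein_coding``, ``lncRNA`` or ``other``; the
    mapping from raw annotation gene_type values is configurable
    (see :func:`load_biotype_map`).
    """

    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    gene_name: str | None = None
    strand: str | None = None
    raw_biotype: str | None = None
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        """Interval from the minimum start to maximum end over transcripts."""
        starts = [self.start] + [e.start for t in self.transcripts for e in t.exons]
        ends = [self.end] + [e.end for t in self.transcripts for e in t.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), name=self.gene_id,
                               strand=self.strand)

    def exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


class Annotation:
    """Collection of :class:`GeneModel` keyed by gene_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise FormatError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == biotype]

    def ids_by_biotype(self, biotype: str) -> set[str]:
        return {g.gene_id for g in self.genes.values() if g.biotype == biotype}

    def spans(self, biotypes: Sequence[str] | None = None) -> list[GenomicInterval]:
        genes = self.genes.values()
        if biotypes is not None:
            genes = [g for g in genes if g.biotype in biotypes]
        return [g.span for g in genes]

    def biotype_of(self, gene_id: str) -> str:
        return self.genes[gene_id].biotype


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, preserving file order.

    BED is already 0-based half-open, so fields map directly. Column 4
    becomes ``name``, column 5 ``score`` (kept verbatim as text), column 6
    ``strand``.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            try:
                out.append(
                    GenomicInterval(
                        fields[0],
                        start,
                        end,
                        name=fields[3] if len(fields) > 3 else None,
                        score=fields[4] if len(fields) > 4 else None,
                        strand=fields[5] if len(fields) > 5 else None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, emitting as many columns as are populated."""
    with open(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            tail = [iv.name, iv.score, iv.strand]
            while tail and tail[-1] is None:
                tail.pop()
            fields += [t if t is not None else "." for t in tail]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF (GENCODE dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_biotype_map(path: str | Path | None = None) -> dict[str, str]:
    """Return raw gene_type -> collapsed biotype mapping.

    The vocabulary ships as a YAML config file so that annotation dialects
    can be accommodated without code changes; ``path`` overrides the default.
    """
    if path is None:
        text = resources.files("lnccensus").joinpath("data/biotypes.yaml").read_text()
    else:
        with _open_text(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    collapsed: dict[str, str] = {}
    for target, sources in raw.items():
        for s in sources:
            collapsed[str(s)] = target
    return collapsed


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path, biotype_map: Mapping[str, str] | None = None) -> Annotation:
    """Parse a GENCODE-dialect GTF into an :class:`Annotation`.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open here. Feature rows other than gene/transcript/exon are skipped
    (a count is logged). An exon whose transcript_id has not been declared is
    a format error.
    """
    if biotype_map is None:
        biotype_map = load_biotype_map()
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    tx_gene: dict[str, str] = {}
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon"):
                skipped += 1
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            a = _parse_attrs(attrs)
            gene_id = a.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}: line {lineno}: missing gene_id")
            if feature == "gene":
                raw_bt = a.get("gene_type", "")
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    biotype=biotype_map.get(raw_bt, "other"),
                    chrom=chrom,
                    start=start,
                    end=end,
                    gene_name=a.get("gene_name"),
                    strand=strand if strand in VALID_STRANDS else None,
                    raw_biotype=raw_bt,
                )
            elif feature == "transcript":
                tx_id = a.get("transcript_id")
                if not tx_id:
                    raise FormatError(f"{path}: line {lineno}: transcript without transcript_id")
                if gene_id not in genes:
                    # tolerate annotations without explicit gene rows
                    raw_bt = a.get("gene_type", "")
                    genes[gene_id] = GeneModel(
                        gene_id=gene_id,
                        biotype=biotype_map.get(raw_bt, "other"),
                        chrom=chrom,
                        start=start,
                        end=end,
                        gene_name=a.get("gene_name"),
                        strand=strand if strand in VALID_STRANDS else None,
                        raw_biotype=raw_bt,
                    )
                tx = TranscriptModel(tx_id)
                transcripts[tx_id] = tx
                tx_gene[tx_id] = gene_id
                genes[gene_id].transcripts.append(tx)
            else:  # exon
                tx_id = a.get("transcript_id")
                if tx_id is None or tx_id not in transcripts:
                    raise FormatError(
                        f"{path}: line {lineno}: exon without parent transcript ({tx_id!r})"
                    )
                transcripts[tx_id].exons.append(
                    GenomicInterval(chrom, start, end, name=tx_id, strand=strand)
                )
    if skipped:
        log.info("read_gtf(%s): skipped %d non gene/transcript/exon rows", path, skipped)
    return Annotation(genes.values())


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write gene/transcript/exon rows, restoring 1-based closed coordinates."""
    with open(path, "wt") as fh:
        for g in annotation:
            strand = g.strand or "."
            bt = g.raw_biotype or g.biotype
            gattrs = f'gene_id "{g.gene_id}"; gene_type "{bt}";'
            if g.gene_name:
                gattrs += f' gene_name "{g.gene_name}";'
            fh.write(
                "\t".join(
                    [g.chrom, "lnccensus", "gene", str(g.start + 1), str(g.end), ".", strand, ".", gattrs]
                )
                + "\n"
            )
            for t in g.transcripts:
                tstart = min(e.start for e in t.exons) if t.exons else g.start
                tend = max(e.end for e in t.exons) if t.exons else g.end
                tattrs = gattrs + f' transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [g.chrom, "lnccensus", "transcript", str(tstart + 1), str(tend), ".", strand, ".", tattrs]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [g.chrom, "lnccensus", "exon", str(e.start + 1), str(e.end), ".", strand, ".", tattrs]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------


@dataclass
class ChainAlignment:
    """One UCSC chain: colinear ungapped blocks between two assemblies.

    ``source`` is the assembly coordinates are lifted *from* (the ``t`` side
    of the chain header as emitted by alignment pipelines), ``target`` the
    assembly lifted *to* (the ``q`` side). Blocks are
    ``(size, gap_after_in_source, gap_after_in_target)`` with the final
    block carrying zero gaps.
    """

    score: float
    s_name: str
    s_size: int
    s_strand: str
    s_start: int
    s_end: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    chain_id: str
    blocks: list[tuple[int, int, int]]

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        sgaps = sum(b[1] for b in self.blocks)
        tgaps = sum(b[2] for b in self.blocks)
        if any(b[0] <= 0 for b in self.blocks):
            raise FormatError(f"chain {self.chain_id}: non-positive block size")
        if sizes + sgaps != self.s_end - self.s_start:
            raise FormatError(
                f"chain {self.chain_id}: source block arithmetic "
                f"({sizes}+{sgaps}) != span {self.s_end - self.s_start}"
            )
        if sizes + tgaps != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.chain_id}: target block arithmetic "
                f"({sizes}+{tgaps}) != span {self.t_end - self.t_start}"
            )

    def aligned_source_bases(self) -> int:
        return sum(b[0] for b in self.blocks)


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; chains are returned sorted by score descending.

    Block arithmetic is verified against the header spans for every chain.
    """
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise FormatError(
                f"chain {header[-1]}: missing terminal single-field block line"
            )
        c = ChainAlignment(
            score=float(header[1]),
            s_name=header[2], s_size=int(header[3]), s_strand=header[4],
            s_start=int(header[5]), s_end=int(header[6]),
            t_name=header[7], t_size=int(header[8]), t_strand=header[9],
            t_start=int(header[10]), t_end=int(header[11]),
            chain_id=header[12] if len(header) > 12 else "",
            blocks=list(blocks),
        )
        c.validate()
        chains.append(c)
        header, blocks = None, []

    with _open_text(path) as fh:
        open_block = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                if open_block:
                    raise FormatError(f"{path}: line {lineno}: chain without terminal block line")
                finish()
                header = line.split()
                if len(header) < 12:
                    raise FormatError(f"{path}: line {lineno}: short chain header")
                open_block = True
                continue
            if header is None:
                raise FormatError(f"{path}: line {lineno}: block line outside a chain")
            parts = line.split()
            if len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
                open_block = False
            elif len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            else:
                raise FormatError(f"{path}: line {lineno}: malformed block line")
        if open_block:
            raise FormatError(f"{path}: missing terminal block line in final chain")
        finish()
    chains.sort(key=lambda c: -c.score)
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.s_name} {c.s_size} {c.s_strand} {c.s_start} {c.s_end} "
                f"{c.t_name} {c.t_size} {c.t_strand} {c.t_start} {c.t_end} {c.chain_id}\n"
            )
            for i, (size, ds, dt) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n\n")
                else:
                    fh.write(f"{size} {ds} {dt}\n")


# ---------------------------------------------------------------------------
# Chromosome sizes, ID maps, tables
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected name and length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


@dataclass
class IdMapping:
    """Pairs of (foreign_id, canonical gene_id); a foreign ID may map to many."""

    pairs: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for f, c in self.pairs:
            if not f or not c:
                raise ValueError("empty ID in mapping")

    def lookup(self) -> dict[str, list[str]]:
        table: dict[str, list[str]] = {}
        for f, c in self.pairs:
            table.setdefault(f, [])
            if c not in table[f]:
                table[f].append(c)
        return table


def map_ids(foreign_ids: Iterable[str], mapping: IdMapping) -> tuple[list[str], list[str]]:
    """Map foreign IDs to canonical ones; unmapped IDs are reported, not errors.

    All canonical IDs for each foreign ID are returned; the output is
    deduplicated while preserving first-seen order.
    """
    table = mapping.lookup()
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for fid in foreign_ids:
        if fid in table:
            for cid in table[fid]:
                if cid not in seen:
                    seen.add(cid)
                    mapped.append(cid)
        else:
            unmapped.append(fid)
    return mapped, unmapped


def read_id_mapping(path: str | Path, provenance: str = "") -> IdMapping:
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            pairs.append((fields[0], fields[1]))
    return IdMapping(pairs, provenance or str(path))


# Keyword vocabulary for cancer-trait filtering of GWAS-style SNP tables.
CANCER_TRAIT_KEYWORDS = (
    "carcinoma", "lymphoma", "cancer", "leukemia", "tumor", "glioma",
    "sarcoma", "blastoma", "astrocytoma", "melanoma", "meningioma",
)


def read_trait_snps(
    path: str | Path,
    keywords: Sequence[str] = CANCER_TRAIT_KEYWORDS,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Read a (chrom, pos, trait) TSV, keeping rows whose trait text contains
    any keyword (case-insensitive substring match).

    Positions are 1-based in the file and become width-1 intervals
    ``[pos-1, pos)``. When ``chrom_sizes`` is given, rows on unlisted
    sequences are dropped with a logged count (e.g. patch scaffolds).
    """
    kws = [k.lower() for k in keywords]
    out: list[GenomicInterval] = []
    dropped_chrom = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected chrom, pos, trait")
            chrom, pos_s, trait = fields[0], fields[1], fields[2]
            if lineno == 1 and not pos_s.strip().lstrip("-").isdigit():
                continue  # header row
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric position {pos_s!r}") from exc
            trait_l = trait.lower()
            if not any(k in trait_l for k in kws):
                continue
            if chrom_sizes is not None and chrom not in chrom_sizes:
                dropped_chrom += 1
                continue
            out.append(GenomicInterval(chrom, pos - 1, pos, name=trait))
    if dropped_chrom:
        log.info("read_trait_snps(%s): dropped %d rows on unknown sequences", path, dropped_chrom)
    return out


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """Read a BedGraph score track as (interval, value) runs."""
    out: list[tuple[GenomicInterval, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(fields[3]))
            )
    return out


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene_id, mean_fpkm) with header; FPKM must be >= 0."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_fpkm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if (df["mean_fpkm"] < 0).any():
        raise FormatError(f"{path}: negative mean_fpkm")
    return df[["gene_id", "mean_fpkm"]]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Per-gene per-cancer-type differential expression results."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "cancer_type", "log2_fc", "fdr"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise FormatError(f"{path}: fdr outside [0,1]")
    return df[["gene_id", "cancer_type", "log2_fc", "fdr"]]


def read_cnv_table(path: str | Path) -> pd.DataFrame:
    """CNV calls: gene_id, chrom, start, end (0-based half-open), significance."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "significance"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if ((df["significance"] < 0) | (df["significance"] > 1)).any():
        raise FormatError(f"{path}: significance outside [0,1]")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: start >= end")
    return df[["gene_id", "chrom", "start", "end", "significance"]]


def read_evidence_table(path: str | Path, source: str) -> pd.DataFrame:
    """Evidence table for one source: gene_id, function, cancer_types, evidence_level."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"gene_id", "function", "cancer_types", "evidence_level"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    df = df[["gene_id", "function", "cancer_types", "evidence_level"]].copy()
    df["source"] = source
    return df
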