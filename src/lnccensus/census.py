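"""Integration of multi-source evidence into a labelled cancer-lncRNA census.

Three evidence streams contribute genes: manual literature curation,
insertional-mutagenesis orthology hits, and validated CRISPRi proliferation
screen hits. The census is their union over genes that are lncRNAs in the
supplied annotation; each entry accumulates its sources, the union of
reported cancer types, and a resolved functional label:

* any combination containing both oncogene and tumour-suppressor evidence
  (or an explicit ``both``) resolves to ``both``;
* a single direction resolves to itself;
* mutagenesis-only entries stay ``unknown`` — an insertion site implicates
  a gene without revealing the direction of its effect.

Novelty is counted in a declared source order (literature -> mutagenesis ->
crispri by default): a gene is novel to the first listed source containing
it, so the per-source novel counts always sum to the union size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic_io import Annotation

SOURCES = ("literature", "mutagenesis", "crispri")
FUNCTIONS = ("og", "ts", "both", "unknown")


@dataclass
class EvidenceRecord:
    gene_id: str
    source: str
    function: str = "unknown"
    cancer_types: tuple[str, ...] = ()
    evidence_level: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown function {self.function!r}")


@dataclass
class CensusEntry:
    gene_id: str
    sources: set[str]
    function: str
    cancer_types: tuple[str, ...]
    evidence_levels: tuple[str, ...] = ()
    gene_name: str | None = None


def resolve_function(labels: Iterable[str]) -> str:
    """Combine per-source functional labels; commutative and associative."""
    labs = {l for l in labels if l != "unknown"}
    if "both" in labs or {"og", "ts"} <= labs:
        return "both"
    if "og" in labs:
        return "og"
    if "ts" in labs:
        return "ts"
    return "unknown"


def evidence_from_frame(df: pd.DataFrame, source: str) -> list[EvidenceRecord]:
    """Convert a read evidence table into records (cancer_types comma-split)."""
    out = []
    for r in df.itertuples():
        types = tuple(x for x in str(r.cancer_types).split(",") if x and x != "nan")
        out.append(
            EvidenceRecord(
                gene_id=r.gene_id,
                source=source,
                function=r.function if r.function else "unknown",
                cancer_types=types,
                evidence_level=str(r.evidence_level),
            )
        )
    return out


@dataclass
class IntegrationReport:
    per_source_totals: dict[str, int]
    pairwise_overlaps: dict[tuple[str, str], int]
    novel_counts: dict[str, int]
    dropped: list[tuple[str, str]]
    union_size: int


def integrate_sources(
    literature: Sequence[EvidenceRecord],
    mutagenesis: Sequence[EvidenceRecord],
    crispri: Sequence[EvidenceRecord],
    annotation: Annotation | Mapping[str, str],
    source_order: Sequence[str] = SOURCES,
) -> tuple[list[CensusEntry], IntegrationReport]:
    """Union evidence into census entries, dropping non-lncRNA genes.

    ``annotation`` is either a full :class:`Annotation` or a plain mapping
    gene_id -> biotype. The report carries per-source totals (after the
    biotype filter), pairwise overlaps and the ordered novel counts, whose
    sum always equals the union size.
    """
    if isinstance(annotation, Annotation):
        biotype = {g.gene_id: g.biotype for g in annotation}
        names = {g.gene_id: g.gene_name for g in annotation}
    else:
        biotype = dict(annotation)
        names = {}
    by_source: dict[str, list[EvidenceRecord]] = {
        "literature": list(literature),
        "mutagenesis": list(mutagenesis),
        "crispri": list(crispri),
    }
    dropped: list[tuple[str, str]] = []
    kept: dict[str, list[EvidenceRecord]] = {s: [] for s in SOURCES}
    for source, records in by_source.items():
        for rec in records:
            if rec.source != source:
                raise ValueError(f"record for {rec.gene_id} has source {rec.source}, expected {source}")
            bt = biotype.get(rec.gene_id)
            if bt is None:
                dropped.append((rec.gene_id, "not in annotation"))
            elif bt != "lncRNA":
                dropped.append((rec.gene_id, "not lncRNA"))
            else:
                kept[source].append(rec)

    gene_sets = {s: {r.gene_id for r in kept[s]} for s in SOURCES}
    per_gene: dict[str, list[EvidenceRecord]] = {}
    for s in source_order:
        for rec in kept[s]:
            per_gene.setdefault(rec.gene_id, []).append(rec)

    entries: list[CensusEntry] = []
    for gid in sorted(per_gene):
        recs = per_gene[gid]
        types = sorted({t for r in recs for t in r.cancer_types})
        levels = tuple(dict.fromkeys(r.evidence_level for r in recs if r.evidence_level))
        entries.append(
            CensusEntry(
                gene_id=gid,
                sources={r.source for r in recs},
                function=resolve_function(r.function for r in recs),
                cancer_types=tuple(types),
                evidence_levels=levels,
                gene_name=names.get(gid),
            )
        )

    novel: dict[str, int] = {}
    seen: set[str] = set()
    for s in source_order:
        novel[s] = len(gene_sets[s] - seen)
        seen |= gene_sets[s]
    pairwise = {
        (a, b): len(gene_sets[a] & gene_sets[b])
        for i, a in enumerate(SOURCES)
        for b in SOURCES[i + 1:]
    }
    report = IntegrationReport(
        per_source_totals={s: len(gene_sets[s]) for s in SOURCES},
        pairwise_overlaps=pairwise,
        novel_counts=novel,
        dropped=dropped,
        union_size=len(entries),
    )
    assert sum(novel.values()) == report.union_size
    return entries, report


def census_to_frame(entries: Sequence[CensusEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in entries],
            "gene_name": [e.gene_name or "" for e in entries],
            "sources": [",".join(sorted(e.sources)) for e in entries],
            "function": [e.function for e in entries],
            "cancer_types": [",".join(e.cancer_types) for e in entries],
            "evidence_level": [";".join(e.evidence_levels) for e in entries],
        }
    )


def function_counts(entries: Sequence[CensusEntry]) -> dict[str, int]:
    out = {f: 0 for f in FUNCTIONS}
    for e in entries:
        out[e.function] += 1
    return out


def compare_gene_sets(
    named_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Pairwise overlap matrix, per-set unique counts, and the common core."""
    sets = {k: set(v) for k, v in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    matrix = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names, columns=names,
    )
    uniques = {
        a: len(sets[a] - set().union(*(sets[b] for b in names if b != a)))
        for a in names
    }
    common = len(set.intersection(*sets.values()))
    return matrix, uniques, common
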