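"""Density and enrichment statistics for gene-set comparisons.

Every comparison in the pipeline reduces to a 2x2 table tested with a
one-sided exact (hypergeometric / Fisher) test. For per-nucleotide density
comparisons the table treats each nt as a Bernoulli unit:

    (hits_in_set, set_nt - hits, hits_in_baseline, baseline_nt - hits)

with ``fold = (hits_set / set_nt) / (hits_baseline / baseline_nt)``.

Gene "length" is the merged gene span for insertion-site and CNV analyses
and the merged exon body for SNP density (germline variants are counted in
exons only). Differential-expression direction concordance asks whether
oncogenes are enriched for positive fold changes (and tumour suppressors
for negative ones) among differentially expressed genes, relative to
expression-matched controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genomic_io import Annotation, GenomicInterval
from .intervals import (
    IntervalIndex,
    merge_intervals,
    project_exons,
    total_length,
)
from .liftover import CATEGORY_INTERGENIC, HCISAssignment


# ---------------------------------------------------------------------------
# Exact one-sided test
# ---------------------------------------------------------------------------


@dataclass
class TwoByTwo:
    """Counts (a, b, c, d); ``a`` is the in-set & positive-class cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def exact_test_one_sided(t: TwoByTwo, direction: str = "greater") -> float:
    """One-sided exact tail probability for a 2x2 table with fixed margins.

    ``greater`` returns P(X >= a) under the hypergeometric law for cell
    ``a``; ``less`` returns P(X <= a). Computed in log space from the exact
    pmf, so it is stable for nt-scale margins.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("all four margins must be positive")
    N, K, n = r1 + r2, c1, r1  # draw n=row1 from N with K positives
    lo, hi = max(0, n - (N - K)), min(n, K)
    if direction == "greater":
        if t.a <= lo:  # whole support is in the tail
            return 1.0
        ks = np.arange(t.a, hi + 1)
    elif direction == "less":
        if t.a >= hi:
            return 1.0
        ks = np.arange(lo, t.a + 1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p = float(np.exp(logsumexp(_log_hypergeom_pmf(ks, N, K, n))))
    return min(max(p, 5e-324), 1.0)


# ---------------------------------------------------------------------------
# Enrichment containers
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Densities, fold enrichment and exact-test p for set vs baseline."""

    set_hits: int
    set_nt: int
    baseline_hits: int
    baseline_nt: int
    p_value: float
    comparison: str = ""

    @property
    def set_density(self) -> float:
        return self.set_hits / self.set_nt if self.set_nt else math.nan

    @property
    def baseline_density(self) -> float:
        return self.baseline_hits / self.baseline_nt if self.baseline_nt else math.nan

    @property
    def fold(self) -> float:
        bd = self.baseline_density
        if bd == 0:
            return math.inf
        return self.set_density / bd

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "set_hits": self.set_hits,
            "set_nt": self.set_nt,
            "baseline_hits": self.baseline_hits,
            "baseline_nt": self.baseline_nt,
            "fold": self.fold,
            "p_value": self.p_value,
        }


def density_enrichment(
    set_hits: int, set_nt: int, baseline_hits: int, baseline_nt: int,
    comparison: str = "",
) -> EnrichmentResult:
    """Build the per-nt Bernoulli 2x2 and test set > baseline one-sided.

    Degenerate tables (a zero margin, e.g. saturated coverage on both
    sides) carry no evidence of enrichment and report p = 1.
    """
    t = TwoByTwo(set_hits, set_nt - set_hits, baseline_hits, baseline_nt - baseline_hits)
    p = 1.0 if min(t.margins) <= 0 else exact_test_one_sided(t, "greater")
    return EnrichmentResult(
        set_hits, set_nt, baseline_hits, baseline_nt, p, comparison,
    )


# ---------------------------------------------------------------------------
# hCIS density
# ---------------------------------------------------------------------------


def _set_span_nt(annotation: Annotation, gene_set: set[str], length_mode: str) -> int:
    genes = [annotation[g] for g in gene_set]
    if length_mode == "span":
        return total_length(merge_intervals([g.span for g in genes]))
    if length_mode == "exonic":
        return project_exons(genes)[1]
    raise ValueError(f"unknown length_mode {length_mode!r}")


def intergenic_nt(annotation: Annotation, chrom_sizes: Mapping[str, int]) -> int:
    """Genome size minus the merged pc+lncRNA gene spans.

    Only the biotypes that can capture an insertion site are subtracted, so
    the baseline matches the ``intergenic`` assignment category.
    """
    genic = total_length(merge_intervals(annotation.spans(["protein_coding", "lncRNA"])))
    return sum(chrom_sizes.values()) - genic


def hcis_density(
    assignments: Sequence[HCISAssignment],
    gene_set: Iterable[str],
    annotation: Annotation,
    chrom_sizes: Mapping[str, int],
    length_mode: str = "span",
    comparison: str = "hcis_density",
) -> EnrichmentResult:
    """Insertion-site density of a gene set against the intergenic baseline.

    ``set_hits`` counts distinct hCIS assigned to >= 1 gene of the set (an
    hCIS overlapping several set genes contributes once); the baseline is
    the intergenic hCIS count over intergenic nt.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = gene_set - set(annotation.genes)
    if missing:
        raise ValueError(f"gene_set not in annotation: {sorted(missing)[:5]}")
    set_hits = sum(1 for a in assignments if gene_set.intersection(a.gene_ids))
    set_nt = _set_span_nt(annotation, gene_set, length_mode)
    base_hits = sum(1 for a in assignments if a.category == CATEGORY_INTERGENIC)
    base_nt = intergenic_nt(annotation, chrom_sizes)
    return density_enrichment(set_hits, set_nt, base_hits, base_nt, comparison)


# ---------------------------------------------------------------------------
# SNP density over exon bodies
# ---------------------------------------------------------------------------


@dataclass
class SetDensity:
    hits: int
    nt: int

    @property
    def density(self) -> float:
        return self.hits / self.nt if self.nt else math.nan


def snp_density(
    snps: Sequence[GenomicInterval],
    gene_sets: Mapping[str, Iterable[str]],
    annotation: Annotation,
) -> tuple[dict[str, SetDensity], dict[tuple[str, str], EnrichmentResult]]:
    """SNPs per nt of merged exon body for each named gene set, plus
    one-sided pairwise comparisons (first-named set tested as enriched)."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two named gene sets")
    per_set: dict[str, SetDensity] = {}
    for name, ids in gene_sets.items():
        genes = [annotation[g] for g in set(ids)]
        exons, nt = project_exons(genes)
        if nt == 0:
            raise ValueError(f"gene set {name!r} has zero exonic nt")
        idx = IntervalIndex(exons)
        hits = sum(1 for s in snps if idx.overlaps_any(s))
        per_set[name] = SetDensity(hits, nt)
    names = list(per_set)
    pairwise: dict[tuple[str, str], EnrichmentResult] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a, b = per_set[na], per_set[nb]
            pairwise[(na, nb)] = density_enrichment(
                a.hits, a.nt, b.hits, b.nt, comparison=f"snp_density:{na}_vs_{nb}"
            )
    return per_set, pairwise


# ---------------------------------------------------------------------------
# CNV overlap rate
# ---------------------------------------------------------------------------


def cnv_overlap_rate(
    cnvs: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    annotation: Annotation,
    sig_threshold: float = 0.05,
) -> tuple[dict[str, SetDensity], dict[tuple[str, str], EnrichmentResult]]:
    """Length-normalised CNV coverage of merged gene spans per set.

    CNVs are filtered to ``significance <= sig_threshold``; the per-set rate
    is overlapped nt / total span nt, and sets are compared pairwise with a
    one-sided exact test on the nt counts.
    """
    sig = cnvs[cnvs["significance"] <= sig_threshold]
    cnv_iv = merge_intervals(
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sig.itertuples()
    ) if len(sig) else []
    per_set: dict[str, SetDensity] = {}
    for name, ids in gene_sets.items():
        spans = merge_intervals([annotation[g].span for g in set(ids)])
        nt = total_length(spans)
        overlap = 0
        for span in spans:
            for c in cnv_iv:
                overlap += span.overlap_length(c)
        per_set[name] = SetDensity(overlap, nt)
    names = list(per_set)
    pairwise: dict[tuple[str, str], EnrichmentResult] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a, b = per_set[na], per_set[nb]
            pairwise[(na, nb)] = density_enrichment(
                a.hits, a.nt, b.hits, b.nt, comparison=f"cnv_overlap:{na}_vs_{nb}"
            )
    return per_set, pairwise


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def de_classify(
    de_records: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Flag genes differentially expressed in >= 1 cancer type.

    A record passes iff ``fdr < fdr_cut`` and ``|log2_fc| > lfc_cut``
    (strict inequalities). The reported sign comes from the passing record
    with the smallest FDR. Returns a frame indexed by gene_id with columns
    ``flagged`` and ``sign`` (+1/-1; 0 when unflagged).
    """
    passing = de_records[
        (de_records["fdr"] < fdr_cut) & (de_records["log2_fc"].abs() > lfc_cut)
    ]
    best = (
        passing.sort_values(["fdr", "cancer_type"], kind="stable")
        .groupby("gene_id", sort=True)
        .first()
    )
    all_genes = pd.Index(sorted(de_records["gene_id"].unique()), name="gene_id")
    out = pd.DataFrame(index=all_genes)
    out["flagged"] = out.index.isin(best.index)
    signs = np.sign(best["log2_fc"]).astype(int)
    out["sign"] = signs.reindex(all_genes).fillna(0).astype(int)
    return out


@dataclass
class ConcordanceResult:
    table: TwoByTwo | None
    p_value: float | None
    fold: float | None
    skipped_reason: str | None = None


def de_direction_concordance(
    de_flags: pd.DataFrame,
    labels: Mapping[str, str],
    matched_controls: Iterable[str],
) -> dict[str, ConcordanceResult]:
    """Test og-up and ts-down direction concordance among DE genes.

    ``labels`` maps gene_id -> 'og' or 'ts' (genes labelled both must be
    excluded upstream). Controls are the expression-matched gene set. Only
    differentially expressed genes enter the tables.
    """
    de = de_flags[de_flags["flagged"]]
    controls = [g for g in matched_controls if g in de.index and g not in labels]
    ctrl_pos = sum(1 for g in controls if de.loc[g, "sign"] > 0)
    ctrl_neg = len(controls) - ctrl_pos
    out: dict[str, ConcordanceResult] = {}
    for cls, wanted in (("og", 1), ("ts", -1)):
        members = [g for g, lab in labels.items() if lab == cls and g in de.index]
        if not members:
            out[cls] = ConcordanceResult(None, None, None, f"no DE genes labelled {cls}")
            continue
        pos = sum(1 for g in members if de.loc[g, "sign"] > 0)
        neg = len(members) - pos
        if wanted > 0:
            t = TwoByTwo(pos, neg, ctrl_pos, ctrl_neg)
            prop_set = pos / len(members)
            prop_ctrl = ctrl_pos / len(controls) if controls else math.nan
        else:
            t = TwoByTwo(neg, pos, ctrl_neg, ctrl_pos)
            prop_set = neg / len(members)
            prop_ctrl = ctrl_neg / len(controls) if controls else math.nan
        if min(t.margins) <= 0:
            out[cls] = ConcordanceResult(t, None, None, "degenerate margins")
            continue
        fold = prop_set / prop_ctrl if prop_ctrl else math.inf
        out[cls] = ConcordanceResult(t, exact_test_one_sided(t, "greater"), fold)
    return out


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


@dataclass
class ConservationSummary:
    mean_score: float
    total_nt: int
    covered_nt: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_nt / self.total_nt if self.total_nt else math.nan


def mean_conservation(
    score_track: Sequence[tuple[GenomicInterval, float]],
    interval_sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, ConservationSummary]:
    """Length-weighted mean per-base score over each named interval set.

    The track is BedGraph-style runs of per-base scores in [0, 1]. Bases of
    an interval absent from the track score 0 and are flagged through
    ``covered_fraction``.
    """
    runs_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for iv, v in score_track:
        runs_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
    for runs in runs_by_chrom.values():
        runs.sort()
    out: dict[str, ConservationSummary] = {}
    for name, ivs in interval_sets.items():
        if not ivs:
            raise ValueError(f"interval set {name!r} is empty")
        merged = merge_intervals(ivs)
        total = total_length(merged)
        acc = 0.0
        covered = 0
        for iv in merged:
            for s, e, v in runs_by_chrom.get(iv.chrom, []):
                o = max(0, min(iv.end, e) - max(iv.start, s))
                if o:
                    acc += v * o
                    covered += o
        out[name] = ConservationSummary(acc / total, total, covered)
    return out


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Collect results in the standard TSV layout."""
    return pd.DataFrame([r.as_row() for r in results])
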