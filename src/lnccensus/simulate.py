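"""Synthetic datasets with the statistical structure the analysis assumes.

The generator builds a pair of toy genomes related by a blockwise chain
alignment, places protein-coding / lncRNA / other genes on the target
genome, and plants every signal the pipeline is meant to detect:

* insertion sites at a configurable per-nt rate fold-elevated inside
  designated "cancer" genes relative to the rest of the genome;
* cancer-trait SNPs fold-enriched in cancer-lncRNA exon bodies;
* CNVs biased towards cancer-gene spans;
* tumour expression drawn log-normally, with cancer genes shifted about an
  order of magnitude higher (which is what makes expression matching a
  necessary control);
* differential expression with oncogenes pushed up and tumour suppressors
  pushed down at the stated log2FC / FDR thresholds;
* evidence tables for the three census sources.

A truth file records every planted quantity so that parameter-recovery
tests can compare pipeline estimates against ground truth. Everything is
reproducible bit-for-bit from the seed.

The default genome is two chromosomes of 1 Mb per species — roughly a
thousandfold reduction of a mammalian genome that keeps the full pipeline
fast; counts and element sizes are scaled accordingly (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .census import EvidenceRecord
from .genomic_io import (
    Annotation,
    ChainAlignment,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_chain,
    write_chrom_sizes,
    write_gtf,
)
from .liftover import CISRecord

CANCER_TRAITS = (
    "Breast cancer", "Lung carcinoma", "Melanoma risk", "Glioma",
    "Chronic lymphocytic leukemia", "Prostate cancer", "Colorectal cancer",
    "Neuroblastoma susceptibility",
)
NON_CANCER_TRAITS = ("Height", "Body mass index", "Type 2 diabetes", "Blood pressure")
CANCER_TYPE_VOCAB = ("BRCA", "LUAD", "COAD", "PRAD", "SKCM", "LAML", "GBM", "KIRC")
EVIDENCE_LEVELS = ("in vitro", "in vivo", "germline mutation", "somatic mutation")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study. Defaults are the standard
    conditions used throughout the test-suite and acceptance runs."""

    seed: int = 0
    target_chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"hchr1": 1_000_000, "hchr2": 1_000_000}
    )
    # gene universe
    n_pc_genes: int = 50
    n_lnc_genes: int = 400
    n_other_genes: int = 10
    pc_len_range: tuple[int, int] = (2000, 5000)
    lnc_len_range: tuple[int, int] = (800, 1600)
    other_len_range: tuple[int, int] = (100, 300)
    max_exons: int = 3
    fraction_cancer_pc: float = 0.2
    fraction_cancer_lnc: float = 0.15
    # functional labels among cancer lncRNAs
    og_fraction: float = 0.45
    ts_fraction: float = 0.35
    both_fraction: float = 0.05
    # insertion sites
    n_cis: int = 4000
    cis_enrichment_fold: float = 10.0
    cis_len_range: tuple[int, int] = (1, 500)  # log-uniform
    # chain geometry
    chain_block_range: tuple[int, int] = (5000, 20000)
    chain_target_gap_max: int = 200
    chain_source_coverage: float = 0.85
    source_flank: int = 1000
    # unannotated transcripts (targets of the intergenic permutation test)
    n_unannotated: int = 150
    unannotated_len_range: tuple[int, int] = (500, 2000)
    # SNPs
    n_snps: int = 2000
    n_noncancer_snps: int = 300
    snp_enrichment_fold: float = 4.0
    # CNVs
    n_cnvs: int = 300
    cnv_sig_fraction: float = 0.7
    cnv_cancer_fraction: float = 0.5
    # expression (log10 FPKM)
    expr_mu_lnc: float = 0.0
    expr_mu_pc: float = 0.5
    expr_sigma: float = 0.9
    expr_cancer_shift: float = 1.1
    expr_high_fraction: float = 0.25  # non-cancer genes drawn from the high component
    # differential expression
    n_cancer_types: int = 20
    de_effect_lfc: float = 2.0
    de_fdr_alpha: float = 0.05
    de_prob_cancer: float = 0.8
    de_prob_null: float = 0.45
    de_sign_concordance: float = 0.97
    # evidence tables
    literature_fraction: float = 0.7
    crispri_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.cis_enrichment_fold < 1 or self.snp_enrichment_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        for fr in (
            self.fraction_cancer_pc, self.fraction_cancer_lnc,
            self.og_fraction, self.ts_fraction, self.both_fraction,
            self.cnv_sig_fraction, self.cnv_cancer_fraction,
            self.literature_fraction, self.crispri_fraction,
        ):
            if not (0 <= fr <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if min(self.n_cis, self.n_snps, self.n_cnvs) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Bundle:
    """A complete in-memory fixture; ``write`` emits it as plain-text files."""

    source_chrom_sizes: dict[str, int]
    target_chrom_sizes: dict[str, int]
    chains: list[ChainAlignment]
    annotation: Annotation
    cis_records: list[CISRecord]
    snps: pd.DataFrame
    cnvs: pd.DataFrame
    expression: pd.DataFrame
    de: pd.DataFrame
    evidence: dict[str, list[EvidenceRecord]]
    truth: dict
    unannotated: list[GenomicInterval] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.source_chrom_sizes, out / "source.chrom.sizes")
        write_chrom_sizes(self.target_chrom_sizes, out / "target.chrom.sizes")
        write_chain(self.chains, out / "alignment.chain")
        write_gtf(self.annotation, out / "annotation.gtf")
        write_bed([c.interval for c in self.cis_records], out / "cis.bed")
        if self.unannotated:
            write_bed(self.unannotated, out / "unannotated.bed")
        self.snps.to_csv(out / "snps.tsv", sep="\t", index=False)
        self.cnvs.to_csv(out / "cnvs.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        self.de.to_csv(out / "de.tsv", sep="\t", index=False)
        for source, records in self.evidence.items():
            with open(out / f"evidence_{source}.tsv", "wt") as fh:
                fh.write("gene_id\tfunction\tcancer_types\tevidence_level\n")
                for r in records:
                    fh.write(
                        f"{r.gene_id}\t{r.function}\t{','.join(r.cancer_types)}\t{r.evidence_level}\n"
                    )
        with open(out / "truth.json", "wt") as fh:
            json.dump(self.truth, fh, sort_keys=True, indent=1, default=_jsonable)
            fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def cis_from_bed(intervals: Sequence[GenomicInterval]) -> list[CISRecord]:
    """Reconstruct CIS records from a BED file (name column = CIS id)."""
    return [CISRecord(iv, study_id=iv.name or f"cis{i}") for i, iv in enumerate(intervals)]


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------


def _make_chain(
    rng: np.random.Generator,
    t_name: str,
    t_size: int,
    s_name: str,
    cfg: SimulationConfig,
    chain_id: str,
) -> ChainAlignment:
    """One chain tiling (almost all of) the target chromosome.

    Source gaps are sized so that blocks cover about
    ``chain_source_coverage`` of the source chromosome; target gaps are kept
    small so nearly every target base is liftable — unmapped mass lives on
    the source side, as it does for a diverged genome pair.
    """
    lo, hi = cfg.chain_block_range
    mean_block = (lo + hi) / 2
    mean_sgap = mean_block * (1 / cfg.chain_source_coverage - 1)
    blocks: list[tuple[int, int, int]] = []
    t_pos = 0
    while True:
        size = int(rng.integers(lo, hi + 1))
        if t_pos + size >= t_size:
            last = t_size - t_pos
            if last > 0:
                blocks.append((last, 0, 0))
            else:
                s, _, _ = blocks.pop()
                blocks.append((s, 0, 0))
            break
        sgap = int(rng.integers(0, max(1, int(2 * mean_sgap)) + 1))
        tgap = int(rng.integers(0, cfg.chain_target_gap_max + 1))
        if t_pos + size + tgap >= t_size:
            blocks.append((size, 0, 0))
            t_pos += size
            break
        blocks.append((size, sgap, tgap))
        t_pos += size + tgap
    sizes = sum(b[0] for b in blocks)
    sgaps = sum(b[1] for b in blocks)
    tgaps = sum(b[2] for b in blocks)
    s_start = cfg.source_flank
    s_end = s_start + sizes + sgaps
    s_size = s_end + cfg.source_flank
    chain = ChainAlignment(
        score=float(sizes),
        s_name=s_name, s_size=s_size, s_strand="+", s_start=s_start, s_end=s_end,
        t_name=t_name, t_size=t_size, t_strand="+", t_start=0, t_end=sizes + tgaps,
        chain_id=chain_id, blocks=blocks,
    )
    chain.validate()
    return chain


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[Annotation, dict]:
    lengths: list[tuple[str, str, int]] = []  # (gene_id, class, length)
    for i in range(cfg.n_pc_genes):
        lengths.append((f"PC{i:04d}", "protein_coding",
                        int(rng.integers(*cfg.pc_len_range))))
    for i in range(cfg.n_lnc_genes):
        lengths.append((f"LNC{i:04d}", "lncRNA",
                        int(rng.integers(*cfg.lnc_len_range))))
    for i in range(cfg.n_other_genes):
        lengths.append((f"OTH{i:03d}", "other",
                        int(rng.integers(*cfg.other_len_range))))
    order = rng.permutation(len(lengths))
    lengths = [lengths[i] for i in order]

    chrom_names = list(cfg.target_chrom_sizes)
    genome = sum(cfg.target_chrom_sizes.values())
    total_genic = sum(l for _, _, l in lengths)
    if total_genic >= genome:
        raise ValueError("genes exceed genome size; infeasible placement")

    # split the gene list over chromosomes proportionally to size
    per_chrom: dict[str, list[tuple[str, str, int]]] = {c: [] for c in chrom_names}
    budgets = {c: cfg.target_chrom_sizes[c] for c in chrom_names}
    used = {c: 0 for c in chrom_names}
    for item in lengths:
        free = np.array([budgets[c] - used[c] - item[2] for c in chrom_names], dtype=float)
        free = np.maximum(free, 0)
        if free.sum() <= 0:
            raise ValueError("genes exceed genome size; infeasible placement")
        c = chrom_names[int(rng.choice(len(chrom_names), p=free / free.sum()))]
        per_chrom[c].append(item)
        used[c] += item[2]

    genes: list[GeneModel] = []
    raw_bt = {"protein_coding": "protein_coding", "lncRNA": "lncRNA", "other": "snRNA"}
    for c in chrom_names:
        items = per_chrom[c]
        free_nt = cfg.target_chrom_sizes[c] - sum(l for _, _, l in items)
        gaps = rng.multinomial(free_nt, np.full(len(items) + 1, 1 / (len(items) + 1)))
        pos = 0
        for (gid, bt, length), gap in zip(items, gaps[:-1]):
            pos += int(gap)
            start, end = pos, pos + length
            pos = end
            n_ex = int(rng.integers(1, cfg.max_exons + 1))
            n_seg = 2 * n_ex - 1
            if length < n_seg:
                n_ex, n_seg = 1, 1
            seg = rng.multinomial(length - n_seg, np.full(n_seg, 1 / n_seg)) + 1
            exons = []
            p = start
            for si, s in enumerate(seg):
                if si % 2 == 0:
                    exons.append(GenomicInterval(c, p, p + int(s), name=gid + ".1"))
                p += int(s)
            tx = TranscriptModel(gid + ".1", exons)
            genes.append(
                GeneModel(
                    gene_id=gid, biotype=bt, chrom=c, start=start, end=end,
                    gene_name=gid, strand="+" if rng.random() < 0.5 else "-",
                    raw_biotype=raw_bt[bt], transcripts=[tx],
                )
            )
    annotation = Annotation(sorted(genes, key=lambda g: g.gene_id))

    pc_ids = sorted(g.gene_id for g in genes if g.biotype == "protein_coding")
    lnc_ids = sorted(g.gene_id for g in genes if g.biotype == "lncRNA")
    n_cpc = int(round(cfg.fraction_cancer_pc * len(pc_ids)))
    n_clnc = int(round(cfg.fraction_cancer_lnc * len(lnc_ids)))
    cancer_pc = sorted(rng.choice(pc_ids, size=n_cpc, replace=False).tolist())
    cancer_lnc = sorted(rng.choice(lnc_ids, size=n_clnc, replace=False).tolist())

    n_og = int(round(cfg.og_fraction * n_clnc))
    n_ts = int(round(cfg.ts_fraction * n_clnc))
    n_both = int(round(cfg.both_fraction * n_clnc))
    perm = rng.permutation(cancer_lnc).tolist()
    labels = {g: "og" for g in perm[:n_og]}
    labels.update({g: "ts" for g in perm[n_og:n_og + n_ts]})
    labels.update({g: "both" for g in perm[n_og + n_ts:n_og + n_ts + n_both]})
    labels.update({g: "unknown" for g in perm[n_og + n_ts + n_both:]})
    meta = {
        "cancer_pc": cancer_pc,
        "cancer_lnc": cancer_lnc,
        "labels": labels,
    }
    return annotation, meta


def _block_pairs(chain: ChainAlignment) -> list[tuple[int, int, int]]:
    """(source_start, target_start, size) for each aligned block."""
    out = []
    s, t = chain.s_start, chain.t_start
    for size, ds, dt in chain.blocks:
        out.append((s, t, size))
        s += size + ds
        t += size + dt
    return out


def _source_preimage(
    chains: Sequence[ChainAlignment],
    target_intervals: Sequence[GenomicInterval],
) -> list[tuple[str, int, int, str]]:
    """Map target intervals back through chain blocks to source segments."""
    segs: list[tuple[str, int, int, str]] = []
    by_target: dict[str, list[ChainAlignment]] = {}
    for c in chains:
        by_target.setdefault(c.t_name, []).append(c)
    for iv in target_intervals:
        for chain in by_target.get(iv.chrom, []):
            for bs, bt, size in _block_pairs(chain):
                o_lo = max(iv.start, bt)
                o_hi = min(iv.end, bt + size)
                if o_hi > o_lo:
                    segs.append(
                        (chain.s_name, bs + (o_lo - bt), bs + (o_hi - bt), iv.name or "")
                    )
    return segs


def _sample_positions(
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    n: int,
) -> list[tuple[str, int]]:
    names = list(weights)
    totals = np.array([w.sum() for w in weights.values()])
    cum_chrom = np.cumsum(totals)
    out: list[tuple[str, int]] = []
    u = rng.random(n) * cum_chrom[-1]
    chrom_idx = np.searchsorted(cum_chrom, u, side="right")
    for ci in range(len(names)):
        k = int((chrom_idx == ci).sum())
        if k == 0:
            continue
        w = weights[names[ci]]
        cum = np.cumsum(w)
        v = rng.random(k) * cum[-1]
        pos = np.searchsorted(cum, v, side="right")
        out.extend((names[ci], int(p)) for p in pos)
    return out


def simulate(config: SimulationConfig, out_dir: str | Path | None = None) -> Bundle:
    """Generate the full fixture bundle (optionally writing it to disk)."""
    rng = np.random.default_rng(config.seed)

    # --- genomes and chain ---------------------------------------------
    chains: list[ChainAlignment] = []
    source_sizes: dict[str, int] = {}
    for i, (t_name, t_size) in enumerate(config.target_chrom_sizes.items()):
        s_name = f"m{t_name}"
        chain = _make_chain(rng, t_name, t_size, s_name, config, chain_id=str(i + 1))
        chains.append(chain)
        source_sizes[s_name] = chain.s_size

    annotation, meta = _place_genes(rng, config)
    cancer_ids = set(meta["cancer_pc"]) | set(meta["cancer_lnc"])
    cancer_spans = [annotation[g].span for g in sorted(cancer_ids)]

    # --- insertion sites in the source genome --------------------------
    weights = {name: np.ones(size) for name, size in source_sizes.items()}
    gene_of_pos: dict[str, np.ndarray] = {
        name: np.full(size, -1, dtype=np.int32) for name, size in source_sizes.items()
    }
    cancer_list = sorted(cancer_ids)
    gene_index = {g: i for i, g in enumerate(cancer_list)}
    for s_name, lo, hi, gid in _source_preimage(chains, cancer_spans):
        weights[s_name][lo:hi] = config.cis_enrichment_fold
        gene_of_pos[s_name][lo:hi] = gene_index[gid]

    cis_records: list[CISRecord] = []
    cis_truth: list[dict] = []
    if config.n_cis:
        positions = _sample_positions(rng, weights, config.n_cis)
        log_lo, log_hi = math.log(config.cis_len_range[0]), math.log(config.cis_len_range[1])
        lens = np.exp(rng.uniform(log_lo, log_hi, size=config.n_cis)).astype(int)
        lens = np.maximum(lens, 1)
        effects = rng.choice(["gain", "loss", "unknown"], size=config.n_cis)
        for i, ((chrom, pos), L) in enumerate(zip(positions, lens)):
            end = min(pos + int(L), source_sizes[chrom])
            if end <= pos:
                pos, end = pos - 1, pos
            name = f"CIS{i:05d}"
            cis_records.append(
                CISRecord(
                    GenomicInterval(chrom, pos, end, name=name),
                    study_id=f"study{1 + i % 5}",
                    predicted_effect=str(effects[i]),
                )
            )
            gi = int(gene_of_pos[chrom][pos])
            cis_truth.append(
                {
                    "name": name,
                    "in_cancer_gene": gi >= 0,
                    "gene_id": cancer_list[gi] if gi >= 0 else None,
                }
            )

    # --- SNPs in the target genome --------------------------------------
    t_weights = {name: np.ones(size) for name, size in config.target_chrom_sizes.items()}
    for g in meta["cancer_lnc"]:
        for e in annotation[g].exons():
            t_weights[e.chrom][e.start:e.end] = config.snp_enrichment_fold
    snp_rows: list[tuple[str, int, str]] = []
    for chrom, pos in _sample_positions(rng, t_weights, config.n_snps):
        snp_rows.append((chrom, pos + 1, str(rng.choice(CANCER_TRAITS))))
    for chrom, pos in _sample_positions(
        rng, {n: np.ones(s) for n, s in config.target_chrom_sizes.items()},
        config.n_noncancer_snps,
    ):
        snp_rows.append((chrom, pos + 1, str(rng.choice(NON_CANCER_TRAITS))))
    order = rng.permutation(len(snp_rows))
    snps = pd.DataFrame(
        [snp_rows[i] for i in order], columns=["chrom", "pos", "trait"]
    )

    # --- unannotated transcripts ------------------------------------------
    # stand-ins for cancer-associated transcripts absent from the gene
    # annotation; placed uniformly, so intergenic insertion sites should hit
    # them no more often than chance
    unannotated: list[GenomicInterval] = []
    if config.n_unannotated:
        uw = {n: np.ones(s) for n, s in config.target_chrom_sizes.items()}
        upos = _sample_positions(rng, uw, config.n_unannotated)
        ulens = rng.integers(*config.unannotated_len_range, size=config.n_unannotated)
        for i, ((chrom, pos), L) in enumerate(zip(upos, ulens)):
            end = min(pos + int(L), config.target_chrom_sizes[chrom])
            if end <= pos:
                pos, end = pos - 1, pos
            unannotated.append(GenomicInterval(chrom, pos, end, name=f"UTX{i:04d}"))

    # --- CNVs ------------------------------------------------------------
    cnv_rows = []
    t_names = list(config.target_chrom_sizes)
    t_sizes = np.array([config.target_chrom_sizes[c] for c in t_names], dtype=float)
    for i in range(config.n_cnvs):
        if meta["cancer_lnc"] and rng.random() < config.cnv_cancer_fraction:
            gid = str(rng.choice(meta["cancer_lnc"]))
            g = annotation[gid]
            start = max(0, g.start - int(rng.integers(0, 500)))
            length = max(200, int(g.span.length * rng.uniform(0.3, 1.2)))
            end = min(start + length, config.target_chrom_sizes[g.chrom])
            chrom = g.chrom
        else:
            gid = "."
            chrom = t_names[int(rng.choice(len(t_names), p=t_sizes / t_sizes.sum()))]
            length = int(rng.integers(1000, 10001))
            start = int(rng.integers(0, config.target_chrom_sizes[chrom] - length))
            end = start + length
        if rng.random() < config.cnv_sig_fraction:
            sig = round(float(rng.uniform(0, 0.05)), 6)
        else:
            sig = round(float(rng.uniform(0.05, 1.0)), 6)
        cnv_rows.append((gid, chrom, start, end, sig))
    cnvs = pd.DataFrame(cnv_rows, columns=["gene_id", "chrom", "start", "end", "significance"])

    # --- expression ------------------------------------------------------
    expr_rows = []
    for g in annotation:
        if g.biotype == "other":
            continue
        mu = config.expr_mu_pc if g.biotype == "protein_coding" else config.expr_mu_lnc
        # cancer genes sit an order of magnitude higher; a minority of other
        # genes share the high component, as highly expressed non-census
        # genes do in real data
        if g.gene_id in cancer_ids or rng.random() < config.expr_high_fraction:
            mu += config.expr_cancer_shift
        fpkm = round(float(10 ** rng.normal(mu, config.expr_sigma)), 4)
        expr_rows.append((g.gene_id, fpkm))
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "mean_fpkm"])

    # --- differential expression ----------------------------------------
    types = [f"CT{i:02d}" for i in range(config.n_cancer_types)]
    de_rows = []
    de_truth: dict[str, dict] = {}
    for g in annotation:
        if g.biotype == "other":
            continue
        label = meta["labels"].get(g.gene_id, "none")
        is_cancer = g.gene_id in cancer_ids
        p_de = config.de_prob_cancer if is_cancer else config.de_prob_null
        is_de = bool(rng.random() < p_de)
        if label == "og":
            sign = 1 if rng.random() < config.de_sign_concordance else -1
        elif label == "ts":
            sign = -1 if rng.random() < config.de_sign_concordance else 1
        else:
            sign = 1 if rng.random() < 0.5 else -1
        de_types: list[str] = []
        if is_de:
            k = int(rng.integers(1, 4))
            de_types = sorted(rng.choice(types, size=k, replace=False).tolist())
        for ct in types:
            if ct in de_types:
                lfc = sign * (config.de_effect_lfc + float(rng.normal(0, 0.3)))
                fdr = float(rng.uniform(1e-5, 0.6 * config.de_fdr_alpha))
            else:
                lfc = float(rng.normal(0, 0.3))
                fdr = float(rng.uniform(0, 1))
            de_rows.append((g.gene_id, ct, round(lfc, 4), round(fdr, 6)))
        de_truth[g.gene_id] = {"de": is_de, "sign": sign if is_de else 0}
    de = pd.DataFrame(de_rows, columns=["gene_id", "cancer_type", "log2_fc", "fdr"])

    # --- evidence tables -------------------------------------------------
    labels = meta["labels"]
    clnc = meta["cancer_lnc"]
    n_lit = int(round(config.literature_fraction * len(clnc)))
    n_cri = int(round(config.crispri_fraction * len(clnc)))
    lit_genes = sorted(rng.choice(clnc, size=n_lit, replace=False).tolist())
    cri_genes = sorted(rng.choice(clnc, size=n_cri, replace=False).tolist())
    hit_genes = sorted(
        {t["gene_id"] for t in cis_truth if t["gene_id"] in set(clnc)}
    )

    def _types() -> tuple[str, ...]:
        k = int(rng.integers(1, 4))
        return tuple(sorted(rng.choice(CANCER_TYPE_VOCAB, size=k, replace=False).tolist()))

    evidence = {
        "literature": [
            EvidenceRecord(g, "literature", labels.get(g, "unknown"), _types(),
                           str(rng.choice(EVIDENCE_LEVELS[:2])))
            for g in lit_genes
        ],
        "mutagenesis": [
            EvidenceRecord(g, "mutagenesis", "unknown", _types(), "mutagenesis screen")
            for g in hit_genes
        ],
        "crispri": [
            EvidenceRecord(
                g, "crispri",
                labels[g] if labels.get(g) in ("og", "ts")
                else ("og" if rng.random() < 0.5 else "ts"),
                _types(), "CRISPRi proliferation screen",
            )
            for g in cri_genes
        ],
    }

    truth = {
        "config": asdict(config),
        "cancer_pc": meta["cancer_pc"],
        "cancer_lnc": meta["cancer_lnc"],
        "labels": labels,
        "planted_cis_fold": config.cis_enrichment_fold,
        "planted_snp_fold": config.snp_enrichment_fold,
        "cis": cis_truth,
        "de": de_truth,
        "n_cis_in_cancer_genes": sum(1 for t in cis_truth if t["in_cancer_gene"]),
    }

    bundle = Bundle(
        source_chrom_sizes=source_sizes,
        target_chrom_sizes=dict(config.target_chrom_sizes),
        chains=chains,
        annotation=annotation,
        cis_records=cis_records,
        snps=snps,
        cnvs=cnvs,
        expression=expression,
        de=de,
        evidence=evidence,
        truth=truth,
        unannotated=unannotated,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def validate_bundle(bundle: Bundle) -> None:
    """Self-check: the truth file and the emitted tables must agree."""
    for c in bundle.chains:
        c.validate()
    ann_ids = set(bundle.annotation.genes)
    lnc = bundle.annotation.ids_by_biotype("lncRNA")
    pc = bundle.annotation.ids_by_biotype("protein_coding")
    assert set(bundle.truth["cancer_lnc"]) <= lnc
    assert set(bundle.truth["cancer_pc"]) <= pc
    assert set(bundle.expression["gene_id"]) <= ann_ids
    assert set(bundle.de["gene_id"]) <= ann_ids
    assert len(bundle.cis_records) == len(bundle.truth["cis"])
    for cis in bundle.cis_records:
        assert cis.interval.end <= bundle.source_chrom_sizes[cis.interval.chrom]
    for g in bundle.annotation:
        span = g.span
        assert span.end <= bundle.target_chrom_sizes[span.chrom]
        for e in g.exons():
            assert span.start <= e.start < e.end <= span.end
    for records in bundle.evidence.values():
        for r in records:
            assert r.gene_id in lnc
    for iv in bundle.unannotated:
        assert iv.end <= bundle.target_chrom_sizes[iv.chrom]


# ---------------------------------------------------------------------------
# Census-scale evidence fixture
# ---------------------------------------------------------------------------


@dataclass
class CensusFixtureConfig:
    """Source structure of the census-scale evidence fixture.

    Sizes and overlaps default to the real study's composition: a
    literature set of 375 genes (261 oncogenes, 92 tumour suppressors, 22
    with both labels), a mutagenesis screen recovering 123 lncRNAs of which
    21 overlap the literature, and 21 validated CRISPRi hits of which 4 are
    in the literature set, 2 among mutagenesis-only genes, and 15 novel (12
    labelled og, 3 ts by growth phenotype).
    """

    seed: int = 0
    n_literature: int = 375
    lit_og: int = 261
    lit_ts: int = 92
    lit_both: int = 22
    n_mutagenesis: int = 123
    mut_lit_overlap: int = 21
    n_crispri: int = 21
    cri_lit_overlap: int = 4
    cri_mut_overlap: int = 2
    cri_novel_og: int = 12
    cri_novel_ts: int = 3


def make_census_evidence(
    cfg: CensusFixtureConfig = CensusFixtureConfig(),
) -> tuple[list[EvidenceRecord], list[EvidenceRecord], list[EvidenceRecord], dict[str, str]]:
    """Evidence tables with the study-scale source structure, plus a
    biotype map declaring every referenced gene a lncRNA."""
    rng = np.random.default_rng(cfg.seed)
    lit_ids = [f"CLNC{i:04d}" for i in range(cfg.n_literature)]
    n_mut_novel = cfg.n_mutagenesis - cfg.mut_lit_overlap
    mut_novel = [f"MLNC{i:04d}" for i in range(n_mut_novel)]
    n_cri_novel = cfg.cri_novel_og + cfg.cri_novel_ts
    cri_novel = [f"XLNC{i:04d}" for i in range(n_cri_novel)]

    perm = rng.permutation(lit_ids).tolist()
    lit_labels = {g: "og" for g in perm[:cfg.lit_og]}
    lit_labels.update({g: "ts" for g in perm[cfg.lit_og:cfg.lit_og + cfg.lit_ts]})
    lit_labels.update({g: "both" for g in perm[cfg.lit_og + cfg.lit_ts:]})

    mut_from_lit = sorted(rng.choice(lit_ids, size=cfg.mut_lit_overlap, replace=False).tolist())
    mut_ids = mut_from_lit + mut_novel

    lit_og_pool = sorted(g for g, l in lit_labels.items() if l == "og" and g not in mut_from_lit)
    cri_from_lit = sorted(rng.choice(lit_og_pool, size=cfg.cri_lit_overlap, replace=False).tolist())
    cri_from_mut = sorted(rng.choice(mut_novel, size=cfg.cri_mut_overlap, replace=False).tolist())
    cri_labels = {g: lit_labels[g] for g in cri_from_lit}
    cri_labels.update({g: "og" for g in cri_from_mut})
    cri_labels.update({g: "og" for g in cri_novel[:cfg.cri_novel_og]})
    cri_labels.update({g: "ts" for g in cri_novel[cfg.cri_novel_og:]})

    def _types() -> tuple[str, ...]:
        k = int(rng.integers(1, 4))
        return tuple(sorted(rng.choice(CANCER_TYPE_VOCAB, size=k, replace=False).tolist()))

    literature = [
        EvidenceRecord(g, "literature", lit_labels[g], _types(),
                       str(rng.choice(EVIDENCE_LEVELS)))
        for g in sorted(lit_ids)
    ]
    mutagenesis = [
        EvidenceRecord(g, "mutagenesis", "unknown", _types(), "mutagenesis screen")
        for g in sorted(mut_ids)
    ]
    crispri = [
        EvidenceRecord(g, "crispri", cri_labels[g], _types(), "CRISPRi proliferation screen")
        for g in sorted(cri_labels)
    ]
    all_ids = set(lit_ids) | set(mut_ids) | set(cri_labels)
    biotype_map = {g: "lncRNA" for g in sorted(all_ids)}
    return literature, mutagenesis, crispri, biotype_map


# ---------------------------------------------------------------------------
# Minimal hand-checkable fixture
# ---------------------------------------------------------------------------


def make_minimal_fixture(out_dir: str | Path | None = None) -> Bundle:
    """A tiny bundle whose every downstream number is hand-derivable.

    Two target chromosomes (hA 10 kb, hB 8 kb) with identity-like chains
    (the hB chain covers only [0, 4000)), one protein-coding and five lncRNA
    genes, and 8 CIS. Expected downstream numbers are recorded in
    ``truth['expected']``:

    * 7 CIS lift (CIS8 lies outside the hB chain span);
    * categories: 2 pc (CIS1; CIS2 overlaps the pc gene and a lncRNA and
      takes pc precedence), 4 lncRNA, 1 intergenic;
    * distinct genes hit: 1 pc, 4 lncRNA;
    * census: literature {G2, G3, G4} + mutagenesis {G3, G6} + CRISPRi
      {G5, G6} = 5 entries, novel counts 3/1/1; the pc gene G1 listed in
      the literature table is dropped as "not lncRNA".
    """
    target_sizes = {"hA": 10_000, "hB": 8_000}
    source_sizes = {"mA": 10_000, "mB": 8_000}
    chains = [
        ChainAlignment(1000, "mA", 10_000, "+", 0, 10_000,
                       "hA", 10_000, "+", 0, 10_000, "1", [(10_000, 0, 0)]),
        ChainAlignment(900, "mB", 8_000, "+", 0, 4_000,
                       "hB", 8_000, "+", 0, 4_000, "2", [(4_000, 0, 0)]),
    ]
    for c in chains:
        c.validate()

    def gene(gid, bt, chrom, start, end, exons=None):
        exons = exons or [(start, end)]
        tx = TranscriptModel(gid + ".1", [GenomicInterval(chrom, s, e, name=gid + ".1")
                                          for s, e in exons])
        raw = {"protein_coding": "protein_coding", "lncRNA": "lncRNA"}[bt]
        return GeneModel(gid, bt, chrom, start, end, gene_name=gid, strand="+",
                         raw_biotype=raw, transcripts=[tx])

    annotation = Annotation([
        gene("G1", "protein_coding", "hA", 1000, 2000),
        gene("G2", "lncRNA", "hA", 1500, 2500, exons=[(1500, 1800), (2200, 2500)]),
        gene("G3", "lncRNA", "hA", 3000, 4000),
        gene("G4", "lncRNA", "hA", 6000, 7000),
        gene("G5", "lncRNA", "hA", 7500, 7800),
        gene("G6", "lncRNA", "hB", 1000, 2000),
    ])

    cis_defs = [
        ("mA", 1200, 1210), ("mA", 1600, 1610), ("mA", 2200, 2300),
        ("mA", 3500, 3501), ("mA", 5100, 5110), ("mA", 6500, 6600),
        ("mB", 1500, 1600), ("mB", 5000, 5010),
    ]
    cis_records = [
        CISRecord(GenomicInterval(c, s, e, name=f"CIS{i+1}"), study_id=f"study{i+1}")
        for i, (c, s, e) in enumerate(cis_defs)
    ]

    evidence = {
        "literature": [
            EvidenceRecord("G2", "literature", "og", ("BRCA",), "in vitro"),
            EvidenceRecord("G3", "literature", "ts", ("LUAD", "BRCA"), "in vivo"),
            EvidenceRecord("G4", "literature", "og", ("GBM",), "in vitro"),
            EvidenceRecord("G1", "literature", "og", ("BRCA",), "in vitro"),  # dropped: pc
        ],
        "mutagenesis": [
            EvidenceRecord("G3", "mutagenesis", "unknown", ("COAD",), "mutagenesis screen"),
            EvidenceRecord("G6", "mutagenesis", "unknown", (), "mutagenesis screen"),
        ],
        "crispri": [
            EvidenceRecord("G5", "crispri", "og", ("PRAD",), "CRISPRi proliferation screen"),
            EvidenceRecord("G6", "crispri", "ts", (), "CRISPRi proliferation screen"),
        ],
    }

    expression = pd.DataFrame(
        {"gene_id": ["G1", "G2", "G3", "G4", "G5", "G6"],
         "mean_fpkm": [5.0, 12.0, 3.0, 8.0, 1.0, 20.0]}
    )
    de = pd.DataFrame(
        [("G2", "BRCA", 2.5, 0.001), ("G3", "LUAD", -1.8, 0.02),
         ("G4", "GBM", 1.2, 0.03), ("G5", "PRAD", 0.4, 0.5),
         ("G6", "BRCA", -2.2, 0.004)],
        columns=["gene_id", "cancer_type", "log2_fc", "fdr"],
    )
    snps = pd.DataFrame(
        [("hA", 1700, "Breast cancer"), ("hA", 2300, "Lung carcinoma"),
         ("hA", 3500, "Height"), ("hB", 1500, "Melanoma risk")],
        columns=["chrom", "pos", "trait"],
    )
    cnvs = pd.DataFrame(
        [("G2", "hA", 1400, 2600, 0.01), (".", "hA", 8000, 9000, 0.5)],
        columns=["gene_id", "chrom", "start", "end", "significance"],
    )
    truth = {
        "expected": {
            "n_cis": 8,
            "n_mapped": 7,
            "n_unmapped": 1,
            "category_counts": {"pc": 2, "lncRNA": 4, "intergenic": 1},
            "genes_per_category": {"pc": 1, "lncRNA": 4},
            "census_union": 5,
            "novel_counts": {"literature": 3, "mutagenesis": 1, "crispri": 1},
            "census_dropped": [["G1", "not lncRNA"]],
        }
    }
    bundle = Bundle(
        source_chrom_sizes=source_sizes,
        target_chrom_sizes=target_sizes,
        chains=chains,
        annotation=annotation,
        cis_records=cis_records,
        snps=snps,
        cnvs=cnvs,
        expression=expression,
        de=de,
        evidence=evidence,
        truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
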