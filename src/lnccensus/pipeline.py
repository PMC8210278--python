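"""End-to-end run: simulate -> liftover -> assign -> enrich -> match -> census.

Each stage persists its intermediate as TSV and the run finishes with a
JSON summary. All randomness flows from one top-level seed, split
deterministically per stage, so a rerun with the same configuration is
identical. Any stage failure aborts the run with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .census import census_to_frame, evidence_from_frame, function_counts, integrate_sources
from .enrichment import (
    de_classify,
    de_direction_concordance,
    enrichment_table,
    hcis_density,
    snp_density,
)
from . import enrichment as _enrichment
from .genomic_io import (
    read_bed,
    read_chain,
    read_chrom_sizes,
    read_cnv_table,
    read_de_table,
    read_evidence_table,
    read_expression_table,
    read_gtf,
    read_trait_snps,
)
from .intervals import IntervalIndex, shuffle_null_overlap
from .liftover import (
    CATEGORY_INTERGENIC,
    LiftoverParams,
    assign_hcis,
    liftover_cis,
    summarize_assignments,
    write_assignments,
)
from .matching import match_distribution
from .simulate import SimulationConfig, cis_from_bed, simulate

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_match: float = 0.1
    min_blocks: float = 0.1
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    cnv_sig_threshold: float = 0.05
    n_iter: int = 1000
    n_bins: int = 20
    length_mode: str = "span"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_all(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated bundle; return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2 ** 31)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "parameters": dataclasses.asdict(config)}

    # -- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        sim_cfg = SimulationConfig(**{"seed": int(seeds[0]), **config.simulation})
        simulate(sim_cfg, out_dir=out / "inputs")
        return out / "inputs"

    inputs = _simulate()
    summary["inputs_dir"] = str(inputs)
    run_from_files(inputs, out, config, summary, seeds)
    with open(out / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def run_from_files(
    inputs: Path, out: Path, config: RunConfig, summary: dict, seeds
) -> dict:
    """Stages downstream of input generation, reading the on-disk bundle."""

    @_stage("load_inputs")
    def _load():
        source_sizes = read_chrom_sizes(inputs / "source.chrom.sizes")
        target_sizes = read_chrom_sizes(inputs / "target.chrom.sizes")
        chains = read_chain(inputs / "alignment.chain")
        annotation = read_gtf(inputs / "annotation.gtf")
        cis = cis_from_bed(read_bed(inputs / "cis.bed"))
        return source_sizes, target_sizes, chains, annotation, cis

    source_sizes, target_sizes, chains, annotation, cis = _load()

    @_stage("liftover")
    def _lift():
        params = LiftoverParams(config.min_match, config.min_blocks)
        mapped, report, _failed = liftover_cis(cis, chains, params)
        return mapped, report

    mapped, lift_report = _lift()
    summary["liftover"] = {
        "n_input": lift_report.n_input,
        "n_mapped": lift_report.n_mapped,
        "unmapped_by_reason": lift_report.unmapped_by_reason,
    }

    @_stage("assign")
    def _assign():
        assignments = assign_hcis(mapped, annotation)
        write_assignments(assignments, out / "assignments.tsv")
        return assignments

    assignments = _assign()
    asg_summary = summarize_assignments(assignments)
    summary["assignment"] = {
        "hcis_per_category": asg_summary.hcis_per_category,
        "genes_per_category": asg_summary.genes_per_category,
    }

    @_stage("census")
    def _census():
        ev = {
            s: evidence_from_frame(
                read_evidence_table(inputs / f"evidence_{s}.tsv", s), s
            )
            for s in ("literature", "mutagenesis", "crispri")
        }
        entries, report = integrate_sources(
            ev["literature"], ev["mutagenesis"], ev["crispri"], annotation
        )
        census_to_frame(entries).to_csv(out / "census.tsv", sep="\t", index=False)
        return entries, report

    entries, census_report = _census()
    summary["census"] = {
        "union_size": census_report.union_size,
        "per_source_totals": census_report.per_source_totals,
        "novel_counts": census_report.novel_counts,
        "function_counts": function_counts(entries),
        "n_dropped": len(census_report.dropped),
    }
    census_ids = {e.gene_id for e in entries}

    @_stage("match")
    def _match():
        expr = read_expression_table(inputs / "expression.tsv")
        lnc = annotation.ids_by_biotype("lncRNA")
        expr = expr[expr["gene_id"].isin(lnc)]
        target = expr[expr["gene_id"].isin(census_ids)]
        candidates = expr[~expr["gene_id"].isin(census_ids)]
        matched = match_distribution(
            target, candidates, n_bins=config.n_bins, rng_seed=int(seeds[1])
        )
        matched.write_tsv(out / "matched_controls.tsv")
        return matched

    matched = _match()
    summary["matching"] = {
        "n_target": len(matched.target_ids),
        "n_control": len(matched.control_ids),
        "ks_distance": matched.ks_distance,
        "ks_distance_unmatched": matched.ks_distance_unmatched,
    }

    @_stage("enrich")
    def _enrich():
        results = []
        dens = hcis_density(
            assignments, census_ids, annotation, target_sizes,
            length_mode=config.length_mode, comparison="hcis_density:census_vs_intergenic",
        )
        results.append(dens)
        snps = read_trait_snps(inputs / "snps.tsv", chrom_sizes=target_sizes)
        snp_sets = {"census": census_ids, "matched": set(matched.control_ids)}
        _per_set, snp_pairs = snp_density(snps, snp_sets, annotation)
        results.extend(snp_pairs.values())
        cnvs = read_cnv_table(inputs / "cnvs.tsv")
        _rates, cnv_pairs = _enrichment.cnv_overlap_rate(
            cnvs, snp_sets, annotation, sig_threshold=config.cnv_sig_threshold
        )
        results.extend(cnv_pairs.values())
        enrichment_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        de = read_de_table(inputs / "de.tsv")
        flags = de_classify(de, fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut)
        labels = {e.gene_id: e.function for e in entries if e.function in ("og", "ts")}
        conc = de_direction_concordance(flags, labels, matched.control_ids)
        return results, conc, flags

    results, concordance, de_flags = _enrich()
    summary["enrichment"] = {r.comparison: {"fold": r.fold, "p": r.p_value} for r in results}
    summary["de_concordance"] = {
        cls: (
            {"p": c.p_value, "fold": c.fold}
            if c.p_value is not None else {"skipped": c.skipped_reason}
        )
        for cls, c in concordance.items()
    }

    @_stage("shuffle_null")
    def _null():
        # do intergenic insertion sites hit unannotated transcripts more
        # often than randomly placed intervals would?
        unannotated_path = inputs / "unannotated.bed"
        intergenic = [
            a.hcis for a in assignments if a.category == CATEGORY_INTERGENIC
        ]
        if not intergenic or not unannotated_path.exists():
            return None
        targets = IntervalIndex(read_bed(unannotated_path))
        res = shuffle_null_overlap(
            intergenic, targets, target_sizes,
            n_iter=config.n_iter, rng_seed=int(seeds[2]),
        )
        res.write_null_counts(out / "null_counts.tsv")
        return res

    null_res = _null()
    if null_res is not None:
        summary["shuffle_null"] = {
            "observed": null_res.observed_overlap_count,
            "observed_targets_hit": null_res.observed_targets_hit,
            "empirical_p": null_res.empirical_p,
            "n_iterations": null_res.n_iterations,
        }
    return summary
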