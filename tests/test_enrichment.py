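import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from lnccensus.enrichment import (
    TwoByTwo,
    de_classify,
    de_direction_concordance,
    density_enrichment,
    exact_test_one_sided,
    hcis_density,
    mean_conservation,
    snp_density,
    cnv_overlap_rate,
)
from lnccensus.genomic_io import Annotation, GeneModel, GenomicInterval, TranscriptModel
from lnccensus.liftover import assign_hcis, liftover_cis
from oracles import bitmap_overlap_nt, hypergeom_tail_enum, mean_score_per_base


def gene(gid, biotype, chrom, start, end, exons=None):
    exons = exons or [(start, end)]
    tx = TranscriptModel(gid + ".1", [GenomicInterval(chrom, s, e) for s, e in exons])
    return GeneModel(gid, biotype, chrom, start, end, transcripts=[tx])


# ------------------------------------------------------------- exact test


def test_exact_test_extreme_table():
    # all 5 positives in the set: p = 1 / C(10,5) = 1/252
    p = exact_test_one_sided(TwoByTwo(5, 0, 0, 5))
    assert p == pytest.approx(1 / 252, rel=1e-12)


def test_exact_test_at_minimum_of_support_is_one():
    assert exact_test_one_sided(TwoByTwo(0, 5, 5, 5)) == 1.0


def test_exact_test_rejects_zero_margin():
    with pytest.raises(ValueError):
        exact_test_one_sided(TwoByTwo(0, 0, 3, 4))


@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
       st.sampled_from(["greater", "less"]))
@settings(max_examples=300, deadline=None)
def test_exact_test_matches_enumeration(a, b, c, d, direction):
    t = TwoByTwo(a, b, c, d)
    if min(t.margins) <= 0:
        return
    assert exact_test_one_sided(t, direction) == pytest.approx(
        hypergeom_tail_enum(a, b, c, d, direction), abs=1e-12
    )


def test_exact_test_agrees_with_scipy_fisher():
    rng = np.random.default_rng(2)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
        t = TwoByTwo(a, b, c, d)
        if min(t.margins) <= 0:
            continue
        ours = exact_test_one_sided(t, "greater")
        ref = fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_exact_test_stable_at_nt_scale_margins():
    p = exact_test_one_sided(TwoByTwo(500, 1_000_000, 300, 2_000_000))
    assert 0 < p < 1e-10  # strong enrichment, no under/overflow


# ------------------------------------------------------ density arithmetic


def test_density_arithmetic_and_fold():
    r = density_enrichment(2, 1000, 10, 10_000)
    assert r.set_density == pytest.approx(0.002)
    assert r.fold == pytest.approx(2.0)
    r2 = density_enrichment(5, 1000, 50, 10_000)
    assert r2.fold == pytest.approx(1.0)
    r3 = density_enrichment(5, 1000, 0, 10_000)
    assert math.isinf(r3.fold)


def test_density_invariant_to_span_splitting():
    """Splitting a gene span into adjacent sub-intervals must not change
    the merged nt accounting (projection correctness)."""
    ann_whole = Annotation([gene("L1", "lncRNA", "c", 100, 700)])
    ann_split = Annotation([gene("L1", "lncRNA", "c", 100, 700,
                                 exons=[(100, 400), (400, 700)])])
    from lnccensus.intervals import project_exons
    assert project_exons([ann_whole["L1"]])[1] == project_exons([ann_split["L1"]])[1]


def test_hcis_density_requires_known_genes(default_bundle):
    mapped, _, _ = liftover_cis(default_bundle.cis_records, default_bundle.chains)
    assignments = assign_hcis(mapped, default_bundle.annotation)
    with pytest.raises(ValueError):
        hcis_density(assignments, set(), default_bundle.annotation,
                     default_bundle.target_chrom_sizes)
    with pytest.raises(ValueError):
        hcis_density(assignments, {"NOPE"}, default_bundle.annotation,
                     default_bundle.target_chrom_sizes)


def test_hcis_density_recovers_planted_enrichment(default_bundle):
    mapped, _, _ = liftover_cis(default_bundle.cis_records, default_bundle.chains)
    assignments = assign_hcis(mapped, default_bundle.annotation)
    res = hcis_density(
        assignments, set(default_bundle.truth["cancer_lnc"]),
        default_bundle.annotation, default_bundle.target_chrom_sizes,
    )
    assert 7 <= res.fold <= 13  # planted 10x
    assert res.p_value < 1e-10


# ------------------------------------------------------------ SNP density


def test_snp_density_arithmetic():
    ann = Annotation([
        gene("A", "lncRNA", "c", 0, 1000),
        gene("B", "lncRNA", "c", 2000, 4000),
    ])
    snps = [GenomicInterval("c", p, p + 1) for p in (10, 20, 30, 40, 2500)]
    per_set, pairs = snp_density(snps, {"setA": {"A"}, "setB": {"B"}}, ann)
    assert per_set["setA"].density == pytest.approx(4 / 1000)
    assert per_set["setB"].density == pytest.approx(1 / 2000)
    assert pairs[("setA", "setB")].fold == pytest.approx(8.0)


def test_snp_density_identical_sets_fold_one():
    ann = Annotation([gene("A", "lncRNA", "c", 0, 1000)])
    snps = [GenomicInterval("c", p, p + 1) for p in (10, 20)]
    per_set, pairs = snp_density(snps, {"x": {"A"}, "y": {"A"}}, ann)
    r = pairs[("x", "y")]
    assert r.fold == pytest.approx(1.0)
    assert r.p_value > 0.5  # symmetric counts cannot look enriched


def test_snp_density_rejects_zero_exonic_nt():
    ann = Annotation([gene("A", "lncRNA", "c", 0, 1000)])
    ann["A"].transcripts[0].exons = []
    with pytest.raises(ValueError):
        snp_density([], {"x": {"A"}, "y": {"A"}}, ann)


def test_snp_density_recovers_planted_fold(default_bundle):
    from lnccensus.genomic_io import CANCER_TRAIT_KEYWORDS
    kws = [k.lower() for k in CANCER_TRAIT_KEYWORDS]
    snps = [
        GenomicInterval(r.chrom, r.pos - 1, r.pos)
        for r in default_bundle.snps.itertuples()
        if any(k in r.trait.lower() for k in kws)
    ]
    lnc = default_bundle.annotation.ids_by_biotype("lncRNA")
    cancer = set(default_bundle.truth["cancer_lnc"])
    _, pairs = snp_density(snps, {"cancer": cancer, "other": lnc - cancer},
                           default_bundle.annotation)
    assert 3 <= pairs[("cancer", "other")].fold <= 5  # planted 4x


# ------------------------------------------------------------ CNV overlap


def test_cnv_full_coverage_and_no_significant():
    ann = Annotation([gene("A", "lncRNA", "c", 100, 200)])
    cnvs = pd.DataFrame(
        [("A", "c", 50, 300, 0.01), ("A", "c", 0, 500, 0.9)],
        columns=["gene_id", "chrom", "start", "end", "significance"],
    )
    per_set, _ = cnv_overlap_rate(cnvs, {"x": {"A"}, "y": {"A"}}, ann)
    assert per_set["x"].density == pytest.approx(1.0)  # whole span covered
    none_sig = cnvs[cnvs.significance > 0.5]
    per_set2, _ = cnv_overlap_rate(none_sig, {"x": {"A"}, "y": {"A"}}, ann)
    assert per_set2["x"].density == 0.0


def test_cnv_overlap_matches_bitmap_oracle():
    rng = np.random.default_rng(8)
    genes = [gene(f"G{i}", "lncRNA", "c1", int(s), int(s) + 200)
             for i, s in enumerate(range(0, 5000, 500))]
    ann = Annotation(genes)
    rows = []
    for i in range(30):
        s = int(rng.integers(0, 4800))
        rows.append((".", "c1", s, s + int(rng.integers(50, 400)), float(rng.uniform(0, 0.1))))
    cnvs = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "significance"])
    per_set, _ = cnv_overlap_rate(cnvs, {"all": {g.gene_id for g in genes},
                                         "none": {"G0"}}, ann)
    sizes = {"c1": 6000}
    spans = [g.span for g in genes]
    sig_iv = [GenomicInterval(r.chrom, r.start, r.end)
              for r in cnvs.itertuples() if r.significance <= 0.05]
    assert per_set["all"].hits == bitmap_overlap_nt(spans, sig_iv, sizes)


# ---------------------------------------------------------------------- DE


def test_de_classify_threshold_boundaries():
    de = pd.DataFrame(
        [
            ("up", "T1", 1.5, 0.01),
            ("sub", "T1", 0.9, 0.001),   # |lfc| at/below the cut: not flagged
            ("edge", "T1", 1.0, 0.001),  # strict inequality on lfc
            ("fdr_edge", "T1", 3.0, 0.05),  # strict inequality on fdr
            ("two", "T1", -2.0, 0.04),
            ("two", "T2", 3.0, 0.2),
        ],
        columns=["gene_id", "cancer_type", "log2_fc", "fdr"],
    )
    out = de_classify(de)
    assert out.loc["up", "flagged"] and out.loc["up", "sign"] == 1
    assert not out.loc["sub", "flagged"]
    assert not out.loc["edge", "flagged"]
    assert not out.loc["fdr_edge", "flagged"]
    # only the passing record counts; its sign is negative
    assert out.loc["two", "flagged"] and out.loc["two", "sign"] == -1


@given(st.floats(0.01, 0.2), st.floats(0.5, 2.0))
@settings(max_examples=40, deadline=None)
def test_de_classify_is_monotone_in_thresholds(fdr_cut, lfc_cut):
    rng = np.random.default_rng(12)
    de = pd.DataFrame(
        {
            "gene_id": [f"g{i % 20}" for i in range(200)],
            "cancer_type": [f"T{i % 5}" for i in range(200)],
            "log2_fc": rng.normal(0, 1.5, 200),
            "fdr": rng.uniform(0, 1, 200),
        }
    )
    strict = de_classify(de, fdr_cut=fdr_cut, lfc_cut=lfc_cut)
    relaxed = de_classify(de, fdr_cut=fdr_cut * 1.5, lfc_cut=lfc_cut * 0.5)
    assert (relaxed["flagged"] | ~strict["flagged"]).all()


def _flags(genes_signs):
    df = pd.DataFrame(
        {"flagged": [s != 0 for _, s in genes_signs],
         "sign": [s for _, s in genes_signs]},
        index=pd.Index([g for g, _ in genes_signs], name="gene_id"),
    )
    return df


def test_concordance_all_up_oncogenes_vs_balanced_controls():
    # 6 oncogenes all upregulated vs 12 balanced controls: p just under 0.05
    rows = [(f"og{i}", 1) for i in range(6)]
    rows += [(f"c{i}", 1 if i < 6 else -1) for i in range(12)]
    flags = _flags(rows)
    labels = {f"og{i}": "og" for i in range(6)}
    res = de_direction_concordance(flags, labels, [f"c{i}" for i in range(12)])
    assert res["og"].p_value == pytest.approx(
        hypergeom_tail_enum(6, 0, 6, 6), abs=1e-12
    )
    assert res["og"].p_value < 0.05


def test_concordance_identical_proportions_fold_one():
    rows = [(f"og{i}", 1 if i < 5 else -1) for i in range(10)]
    rows += [(f"c{i}", 1 if i < 5 else -1) for i in range(10)]
    flags = _flags(rows)
    labels = {f"og{i}": "og" for i in range(10)}
    res = de_direction_concordance(flags, labels, [f"c{i}" for i in range(10)])
    assert res["og"].fold == pytest.approx(1.0)


def test_concordance_recovers_planted_directions(default_bundle):
    """At the generator defaults (oncogenes planted up, tumour suppressors
    planted down) both direction tests come out significant against the
    expression-matched controls."""
    from lnccensus.matching import match_distribution

    lnc = default_bundle.annotation.ids_by_biotype("lncRNA")
    expr = default_bundle.expression[default_bundle.expression["gene_id"].isin(lnc)]
    cancer = set(default_bundle.truth["cancer_lnc"])
    target = expr[expr["gene_id"].isin(cancer)]
    candidates = expr[~expr["gene_id"].isin(cancer)]
    matched = match_distribution(target, candidates, rng_seed=11)
    flags = de_classify(default_bundle.de)
    labels = {g: l for g, l in default_bundle.truth["labels"].items()
              if l in ("og", "ts")}
    res = de_direction_concordance(flags, labels, matched.control_ids)
    assert res["og"].p_value < 0.05 and res["og"].fold > 1
    assert res["ts"].p_value < 0.05 and res["ts"].fold > 1


def test_concordance_empty_class_is_skipped():
    flags = _flags([("a", 1), ("c0", -1)])
    res = de_direction_concordance(flags, {"a": "og"}, ["c0"])
    assert res["ts"].p_value is None and res["ts"].skipped_reason


# ------------------------------------------------------------ conservation


def test_mean_conservation_uniform_and_mixed_tracks():
    track = [(GenomicInterval("c", 0, 1000), 0.5)]
    sets = {"s": [GenomicInterval("c", 10, 60), GenomicInterval("c", 100, 200)]}
    out = mean_conservation(track, sets)
    assert out["s"].mean_score == pytest.approx(0.5)
    track2 = [(GenomicInterval("c", 0, 10), 0.0), (GenomicInterval("c", 10, 20), 1.0)]
    out2 = mean_conservation(track2, {"s": [GenomicInterval("c", 0, 20)]})
    assert out2["s"].mean_score == pytest.approx(0.5)


def test_mean_conservation_uncovered_bases_score_zero():
    track = [(GenomicInterval("c", 0, 10), 1.0)]
    out = mean_conservation(track, {"s": [GenomicInterval("c", 0, 20)]})
    assert out["s"].mean_score == pytest.approx(0.5)
    assert out["s"].covered_fraction == pytest.approx(0.5)


def test_mean_conservation_matches_per_base_oracle():
    rng = np.random.default_rng(4)
    sizes = {"c1": 500}
    track, pos = [], 0
    while pos < 500:
        run = int(rng.integers(5, 40))
        track.append((GenomicInterval("c1", pos, min(pos + run, 500)),
                      float(np.round(rng.uniform(0, 1), 4))))
        pos += run + int(rng.integers(0, 10))
    ivs = [GenomicInterval("c1", int(s), int(s) + int(l))
           for s, l in zip(rng.integers(0, 450, 12), rng.integers(5, 50, 12))]
    ivs = [iv for iv in ivs if iv.end <= 500]
    out = mean_conservation(track, {"s": ivs})
    assert out["s"].mean_score == pytest.approx(
        mean_score_per_base(ivs, track, sizes), abs=1e-12
    )


def test_mean_conservation_rejects_empty_set():
    with pytest.raises(ValueError):
        mean_conservation([], {"s": []})
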