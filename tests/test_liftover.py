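import numpy as np

from lnccensus.genomic_io import Annotation, ChainAlignment, GenomicInterval
from lnccensus.liftover import (
    CISRecord,
    LiftoverParams,
    Unmapped,
    assign_hcis,
    liftover_cis,
    liftover_interval,
    summarize_assignments,
)


def chain(blocks, s_span, t_span, t_strand="+", s_name="m", t_name="h",
          s_size=100_000, t_size=100_000, score=100.0, cid="1"):
    c = ChainAlignment(score, s_name, s_size, "+", *s_span,
                       t_name, t_size, t_strand, *t_span, cid, blocks)
    c.validate()
    return c


IDENTITY = chain([(10_000, 0, 0)], (0, 10_000), (0, 10_000))


def iv(start, end, chrom="m"):
    return GenomicInterval(chrom, start, end)


def test_identity_chain_is_identity_map():
    out = liftover_interval(iv(123, 456), [IDENTITY])
    assert (out.chrom, out.start, out.end) == ("h", 123, 456)


def test_min_match_threshold():
    # only 5 of 100 bases fall in the chain's single block: 5% < 10%
    c = chain([(5, 0, 0)], (0, 5), (0, 5))
    out = liftover_interval(iv(0, 100), [c], LiftoverParams(0.1, 0.1))
    assert isinstance(out, Unmapped) and out.reason == "min_match"
    # the same interval passes with min_match at 5%
    ok = liftover_interval(iv(0, 100), [c], LiftoverParams(0.05, 0.05))
    assert (ok.start, ok.end) == (0, 5)


def test_target_gap_spans_are_bridged():
    # blocks (50, ds=0, dt=10)(50): contiguous source, 10 nt target gap
    c = chain([(50, 0, 10), (50, 0, 0)], (0, 100), (0, 110))
    out = liftover_interval(iv(0, 100), [c])
    assert (out.start, out.end) == (0, 110)


def test_source_gap_drops_unaligned_bases():
    # blocks (50, ds=10, dt=0)(50): bases 50..60 on the source are unaligned
    c = chain([(50, 10, 0), (50, 0, 0)], (0, 110), (0, 100))
    out = liftover_interval(iv(40, 70), [c])
    # bases 40..50 -> 40..50; bases 60..70 -> 50..60
    assert (out.start, out.end) == (40, 60)
    gap_only = liftover_interval(iv(52, 58), [c])
    assert isinstance(gap_only, Unmapped) and gap_only.reason == "empty_projection"


def test_reverse_strand_chain_flips_target_coordinates():
    c = chain([(100, 0, 0)], (0, 100), (0, 100), t_strand="-", t_size=1000)
    out = liftover_interval(iv(0, 10), [c])
    assert (out.start, out.end) == (990, 1000)


def test_no_chain_reason():
    out = liftover_interval(iv(50_000, 50_100), [IDENTITY])
    assert isinstance(out, Unmapped) and out.reason == "no_chain"


def test_best_scoring_chain_wins():
    low = chain([(10_000, 0, 0)], (0, 10_000), (0, 10_000), score=1.0, cid="low")
    high = chain([(10_000, 0, 0)], (0, 10_000), (20_000, 30_000), score=9.0, cid="high")
    out = liftover_interval(iv(100, 200), [low, high])
    assert (out.start, out.end) == (20_100, 20_200)


def test_liftover_is_monotone_within_a_chain():
    rng = np.random.default_rng(0)
    c = chain([(300, 20, 0), (200, 0, 50), (500, 0, 0)], (0, 1020), (0, 1050))
    starts = np.sort(rng.integers(0, 900, 30))
    mapped = []
    for s in starts:
        out = liftover_interval(iv(int(s), int(s) + 20), [c], LiftoverParams(0.05, 0.05))
        if not isinstance(out, Unmapped):
            mapped.append(out.start)
    assert mapped == sorted(mapped)


def test_liftover_cis_report_counts_unmapped_fraction():
    # chain covers the first 80% of the source; 2 of 10 CIS lie beyond it
    c = chain([(800, 0, 0)], (0, 800), (0, 800), s_size=1000)
    starts = [i * 70 for i in range(8)] + [850, 920]  # last two beyond coverage
    cis = [CISRecord(iv(s, s + 10), study_id=f"s{i}") for i, s in enumerate(starts)]
    mapped, report, failed = liftover_cis(cis, [c])
    assert report.n_input == 10 and report.n_mapped == 8
    assert report.unmapped_by_reason == {"no_chain": 2}
    # output order follows input order
    assert [m[0].study_id for m in mapped] == [f"s{i}" for i in range(8)]


def test_empty_chain_set_reports_all_unmapped():
    cis = [CISRecord(iv(0, 10), study_id="a"), CISRecord(iv(20, 30), study_id="b")]
    mapped, report, failed = liftover_cis(cis, [])
    assert mapped == [] and report.unmapped_by_reason == {"no_chain": 2}


# ------------------------------------------------------------- assignment


def test_pc_precedence_and_all_genes_reported(minimal_bundle):
    mapped, _, _ = liftover_cis(minimal_bundle.cis_records, minimal_bundle.chains)
    assignments = assign_hcis(mapped, minimal_bundle.annotation)
    by_name = {a.source_cis.interval.name: a for a in assignments}
    # overlaps both the pc gene G1 and lncRNA G2 -> assigned to pc only
    assert by_name["CIS2"].category == "pc" and by_name["CIS2"].gene_ids == ["G1"]
    assert by_name["CIS3"].category == "lncRNA" and by_name["CIS3"].gene_ids == ["G2"]
    assert by_name["CIS5"].category == "intergenic" and by_name["CIS5"].gene_ids == []


def test_multiple_lncrnas_all_reported():
    ann = Annotation([
        _gene("L1", "lncRNA", "h", 100, 300),
        _gene("L2", "lncRNA", "h", 250, 500),
    ])
    cis = CISRecord(GenomicInterval("h", 260, 290, name="x"), study_id="x")
    [a] = assign_hcis([(cis, cis.interval)], ann)
    assert a.category == "lncRNA" and a.gene_ids == ["L1", "L2"]


def test_other_biotype_is_transparent():
    ann = Annotation([_gene("S1", "other", "h", 100, 300)])
    cis = CISRecord(GenomicInterval("h", 150, 160, name="x"), study_id="x")
    [a] = assign_hcis([(cis, cis.interval)], ann)
    assert a.category == "intergenic" and a.gene_ids == []


def test_assignment_is_partition_and_order_independent(default_bundle):
    mapped, _, _ = liftover_cis(default_bundle.cis_records, default_bundle.chains)
    assignments = assign_hcis(mapped, default_bundle.annotation)
    s = summarize_assignments(assignments)
    assert sum(s.hcis_per_category.values()) == len(mapped)
    # permuting annotation input never changes categories
    rng = np.random.default_rng(1)
    genes = list(default_bundle.annotation)
    shuffled = Annotation([genes[i] for i in rng.permutation(len(genes))])
    assignments2 = assign_hcis(mapped, shuffled)
    assert [(a.category, a.gene_ids) for a in assignments] == [
        (a.category, a.gene_ids) for a in assignments2
    ]


def test_summarize_counts():
    ann = Annotation([_gene("L1", "lncRNA", "h", 0, 1000)])
    pairs = [
        (CISRecord(GenomicInterval("h", i * 10, i * 10 + 5, name=f"c{i}"), study_id=f"c{i}"),
         GenomicInterval("h", i * 10, i * 10 + 5))
        for i in range(3)
    ]
    s = summarize_assignments(assign_hcis(pairs, ann))
    assert s.hcis_per_category["lncRNA"] == 3
    assert s.hcis_per_gene == {"L1": 3}
    assert s.genes_per_category["lncRNA"] == 1
    empty = summarize_assignments([])
    assert sum(empty.hcis_per_category.values()) == 0


def _gene(gid, biotype, chrom, start, end):
    from lnccensus.genomic_io import GeneModel, TranscriptModel
    tx = TranscriptModel(gid + ".1", [GenomicInterval(chrom, start, end)])
    return GeneModel(gid, biotype, chrom, start, end, transcripts=[tx])
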