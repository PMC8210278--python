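import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnccensus.genomic_io import (
    FormatError,
    GenomicInterval,
    IdMapping,
    load_biotype_map,
    map_ids,
    read_bed,
    read_chain,
    read_gtf,
    read_trait_snps,
    write_bed,
    write_chain,
    write_gtf,
)


# ---------------------------------------------------------------------- BED


def test_read_bed_maps_fields_directly(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\tcis1\nchr2\t0\t5\nchr1\t100\t200\tx\t7\t-\n")
    ivs = read_bed(p)
    assert [iv.as_key() for iv in ivs] == [("chr1", 10, 20), ("chr2", 0, 5), ("chr1", 100, 200)]
    assert ivs[0].name == "cis1" and ivs[1].name is None
    assert ivs[2].strand == "-" and ivs[2].score == "7"


def test_read_bed_rejects_inverted_and_short_lines(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t20\t10\n")
    with pytest.raises(FormatError, match="line 1"):
        read_bed(p)
    p.write_text("chr1\t5\n")
    with pytest.raises(FormatError, match="line 1"):
        read_bed(p)


def test_bed_round_trip_is_byte_identical(tmp_path):
    text = "chr1\t10\t20\tcis1\nchr2\t0\t5\nchr1\t100\t200\tx\t7\t-\n"
    p = tmp_path / "a.bed"
    p.write_text(text)
    out = tmp_path / "b.bed"
    write_bed(read_bed(p), out)
    assert out.read_text() == text


def test_read_bed_accepts_gzip(tmp_path):
    p = tmp_path / "a.bed.gz"
    with gzip.open(p, "wt") as fh:
        fh.write("chr1\t1\t2\n")
    assert read_bed(p)[0].as_key() == ("chr1", 1, 2)


# ---------------------------------------------------------------------- GTF

TOY_GTF = """\
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding";
chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.1";
chr1\tsrc\texon\t101\t110\t.\t+\t.\tgene_id "g1"; transcript_id "g1.1";
chr1\tsrc\texon\t121\t130\t.\t+\t.\tgene_id "g1"; transcript_id "g1.1";
chr1\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "g2"; gene_type "lincRNA";
chr1\tsrc\ttranscript\t301\t400\t.\t-\t.\tgene_id "g2"; gene_type "lincRNA"; transcript_id "g2.1";
chr1\tsrc\texon\t301\t400\t.\t-\t.\tgene_id "g2"; transcript_id "g2.1";
chr1\tsrc\tCDS\t101\t110\t.\t+\t0\tgene_id "g1"; transcript_id "g1.1";
"""


def test_read_gtf_converts_coordinates_and_collapses_biotypes(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(TOY_GTF)
    ann = read_gtf(p)
    g1 = ann["g1"]
    assert (g1.start, g1.end) == (100, 200)  # 1-based closed -> 0-based half-open
    assert g1.biotype == "protein_coding"
    assert ann["g2"].biotype == "lncRNA"  # lincRNA collapses to the lncRNA class
    # exons stay separate at read time, no merging
    assert [(e.start, e.end) for e in g1.exons()] == [(100, 110), (120, 130)]


def test_read_gtf_rejects_orphan_exon(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text('chr1\ts\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    with pytest.raises(FormatError, match="exon without parent transcript"):
        read_gtf(p)


def test_gtf_round_trip_restores_coordinates(tmp_path, default_bundle):
    out = tmp_path / "roundtrip.gtf"
    write_gtf(default_bundle.annotation, out)
    back = read_gtf(out)
    assert set(back.genes) == set(default_bundle.annotation.genes)
    for gid, g in default_bundle.annotation.genes.items():
        b = back[gid]
        assert (b.start, b.end, b.biotype) == (g.start, g.end, g.biotype)
        assert [(e.start, e.end) for e in b.exons()] == [(e.start, e.end) for e in g.exons()]


def test_biotype_map_is_configurable(tmp_path):
    custom = tmp_path / "bt.yaml"
    custom.write_text("protein_coding: [protein_coding]\nlncRNA: [weirdRNA]\n")
    m = load_biotype_map(custom)
    assert m["weirdRNA"] == "lncRNA"
    assert "lincRNA" not in m


# -------------------------------------------------------------------- chain


def test_read_chain_identity_block(tmp_path):
    p = tmp_path / "a.chain"
    p.write_text("chain 1000 mA 1000 + 0 1000 hA 1000 + 0 1000 1\n1000\n\n")
    chains = read_chain(p)
    assert len(chains) == 1
    assert chains[0].blocks == [(1000, 0, 0)]


def test_read_chain_block_arithmetic(tmp_path):
    # blocks (100, dt=10, dq=0)(50): source span 160, target span 150
    p = tmp_path / "a.chain"
    p.write_text("chain 5 mA 1000 + 0 160 hA 1000 + 0 150 1\n100 10 0\n50\n\n")
    c = read_chain(p)[0]
    assert c.s_end - c.s_start == 160
    assert c.t_end - c.t_start == 150


def test_read_chain_rejects_bad_arithmetic_and_missing_terminal(tmp_path):
    p = tmp_path / "bad.chain"
    p.write_text("chain 5 mA 1000 + 0 160 hA 1000 + 0 150 7\n100 10 0\n40\n\n")
    with pytest.raises(FormatError, match="chain 7"):
        read_chain(p)
    p.write_text("chain 5 mA 1000 + 0 160 hA 1000 + 0 150 7\n100 10 0\n")
    with pytest.raises(FormatError, match="terminal"):
        read_chain(p)


def test_chains_sorted_by_score_and_round_trip(tmp_path):
    p = tmp_path / "two.chain"
    p.write_text(
        "chain 10 mA 1000 + 0 100 hA 1000 + 0 100 1\n100\n\n"
        "chain 99 mB 1000 + 0 50 hB 1000 + 0 50 2\n50\n\n"
    )
    chains = read_chain(p)
    assert [c.chain_id for c in chains] == ["2", "1"]
    out = tmp_path / "rt.chain"
    write_chain(chains, out)
    assert [c.chain_id for c in read_chain(out)] == ["2", "1"]


# ------------------------------------------------------------------ ID maps


def test_map_ids_examples():
    m = IdMapping([("E1", "G1")])
    assert map_ids(["E1", "E2"], m) == (["G1"], ["E2"])
    m2 = IdMapping([("E1", "G1"), ("E1", "G2")])
    assert map_ids(["E1"], m2) == (["G1", "G2"], [])
    assert map_ids([], m2) == ([], [])


def test_id_mapping_rejects_empty_ids():
    with pytest.raises(ValueError):
        IdMapping([("", "G1")])


# ---------------------------------------------------------------- SNP table


def test_read_trait_snps_filters_and_converts(tmp_path):
    p = tmp_path / "snps.tsv"
    p.write_text(
        "chrom\tpos\ttrait\n"
        "chr1\t100\tBreast cancer\n"
        "chr1\t200\tHeight\n"
        "chrP\t5\tMelanoma\n"
    )
    snps = read_trait_snps(p, chrom_sizes={"chr1": 1000})
    assert [s.as_key() for s in snps] == [("chr1", 99, 100)]  # 1-based -> [99,100)
    # without a sizes table, patch-scaffold rows are kept
    snps = read_trait_snps(p)
    assert len(snps) == 2


def test_read_trait_snps_rejects_non_numeric_position(tmp_path):
    p = tmp_path / "snps.tsv"
    p.write_text("chr1\t100\tcancer\nchr1\toops\tcancer\n")
    with pytest.raises(FormatError, match="line 2"):
        read_trait_snps(p)


# ------------------------------------------------------------ interval type


@given(st.integers(0, 10_000), st.integers(1, 500))
@settings(max_examples=50, deadline=None)
def test_interval_invariants(start, length):
    iv = GenomicInterval("c", start, start + length)
    assert iv.length == length


@pytest.mark.parametrize("start,end", [(5, 5), (10, 2), (-1, 5)])
def test_invalid_intervals_rejected(start, end):
    with pytest.raises(ValueError):
        GenomicInterval("c", start, end)
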