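from __future__ import annotations

import pytest
from Bio.Seq import Seq

from hapalocompare.cluster_io import (ClusterIOError, ClusterRecord,
                                      GeneFeature, read_genbank, read_gff3,
                                      reverse_cluster, summarize,
                                      write_genbank, write_gff3,
                                      write_summary_tsv)

from conftest import toy_cluster


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


def _handwritten_genbank(tmp_path):
    """A GenBank file not produced by this package's writer.

    Three CDSs (two plus, one minus); the minus-strand CDS at 101..202
    has no /translation, so the parser must translate the reverse
    complement itself.
    """
    toy = toy_cluster()
    text = f"""LOCUS       toyhand                  240 bp    DNA     linear   BCT 01-JAN-2014
DEFINITION  toy hapalindole-like cluster.
ACCESSION   toyhand
VERSION     toyhand.1
SOURCE      Fischerella test
  ORGANISM  Fischerella test
FEATURES             Location/Qualifiers
     source          1..240
                     /organism="Fischerella test"
     CDS             11..22
                     /gene="hpiT1"
                     /translation="MKT"
     CDS             complement(101..202)
                     /gene="hpiO1"
                     /product="oxygenase"
     CDS             221..232
                     /gene="hpiC1"
                     /translation="MWY"
ORIGIN
{_origin_block(toy.sequence.lower())}
//
"""
    path = tmp_path / "hand.gbk"
    path.write_text(text)
    return path


def test_handwritten_genbank_parses_three_genes_in_start_order(tmp_path):
    rec = read_genbank(_handwritten_genbank(tmp_path))
    assert len(rec.genes) == 3
    assert [g.start for g in rec.genes] == [11, 101, 221]
    assert [g.strand for g in rec.genes] == ["+", "-", "+"]
    assert rec.organism == "Fischerella test"


def test_minus_strand_cds_translated_from_reverse_complement(tmp_path):
    # 102 nt CDS, hand-computed: ATG + 32x GCT + TAA -> M + 32x A
    rec = read_genbank(_handwritten_genbank(tmp_path))
    g2 = rec.genes[1]
    assert g2.strand == "-"
    assert g2.protein == "M" + "A" * 32


def test_genbank_roundtrip_preserves_features(tmp_path, toy):
    path = tmp_path / "rt.gbk"
    write_genbank(toy, path)
    back = read_genbank(path)
    assert [(g.start, g.end, g.strand, g.label, g.protein) for g in back.genes] == [
        (g.start, g.end, g.strand, g.label, g.protein) for g in toy.genes
    ]
    assert back.sequence.upper() == toy.sequence.upper()


def test_gff3_roundtrip_and_cross_parser_equality(tmp_path, toy):
    gff, fasta = tmp_path / "t.gff3", tmp_path / "t.fasta"
    write_gff3(toy, gff, fasta)
    via_gff = read_gff3(gff, fasta)
    gbk = tmp_path / "t.gbk"
    write_genbank(toy, gbk)
    via_gbk = read_genbank(gbk)
    key = lambda r: [(g.start, g.end, g.strand, g.protein) for g in r.genes]
    assert key(via_gff) == key(via_gbk) == key(toy)
    # round-trip identity through write_gff3
    gff2, fasta2 = tmp_path / "u.gff3", tmp_path / "u.fasta"
    write_gff3(via_gff, gff2, fasta2)
    assert key(read_gff3(gff2, fasta2)) == key(toy)


def test_gff3_minus_strand_translation_matches_genbank(tmp_path, toy):
    gff, fasta = tmp_path / "t.gff3", tmp_path / "t.fasta"
    write_gff3(toy, gff, fasta)
    # drop translations so the reader must translate from sequence
    lines = [
        ";".join(p for p in line.split(";") if not p.startswith("translation="))
        for line in gff.read_text().splitlines()
    ]
    gff.write_text("\n".join(lines) + "\n")
    rec = read_gff3(gff, fasta)
    assert rec.genes[1].protein == "M" + "A" * 32


def test_gff3_seqid_mismatch_is_error(tmp_path, toy):
    gff, fasta = tmp_path / "t.gff3", tmp_path / "t.fasta"
    write_gff3(toy, gff, fasta)
    gff.write_text(gff.read_text().replace("toy1", "other"))
    with pytest.raises(ClusterIOError, match="seqid"):
        read_gff3(gff, fasta)


def test_gff3_without_cds_gives_empty_cluster(tmp_path, toy, caplog):
    gff, fasta = tmp_path / "t.gff3", tmp_path / "t.fasta"
    write_gff3(ClusterRecord(cluster_id="toy1", sequence=toy.sequence),
               gff, fasta)
    rec = read_gff3(gff, fasta)
    assert rec.genes == []


def test_malformed_genbank_raises(tmp_path):
    bad = tmp_path / "bad.gbk"
    bad.write_text("FEATURES nonsense without locus\n")
    with pytest.raises(ClusterIOError):
        read_genbank(bad)


def test_summarize_arithmetic_and_roundings(toy):
    rec = ClusterRecord(cluster_id="x", sequence="A" * 40200,
                        genes=[GeneFeature(f"g{i}", "", 1 + 3 * i, 3 + 3 * i, "+")
                               for i in range(30)])
    s = summarize(rec)
    assert (s.length_kb, s.n_genes) == (40.2, 30)
    assert summarize(toy).n_genes == len(toy.genes)


def test_summarize_requires_sequence():
    with pytest.raises(ValueError):
        summarize(ClusterRecord(cluster_id="x"))


def test_summary_tsv_layout(tmp_path, toy):
    out = tmp_path / "summary.tsv"
    write_summary_tsv([toy], out)
    header, row = out.read_text().splitlines()
    assert header.split("\t") == ["cluster_id", "organism", "length_kb", "n_genes"]
    assert row.split("\t")[0] == "toy1"


def test_feature_invariants_enforced():
    with pytest.raises(ValueError):
        GeneFeature("g", "", 0, 5, "+")
    with pytest.raises(ValueError):
        GeneFeature("g", "", 10, 5, "+")
    with pytest.raises(ValueError):
        GeneFeature("g", "", 1, 5, "*")
    with pytest.raises(ValueError):
        GeneFeature("g", "", 1, 5, "+", protein="MKJ")  # J not amino acid


def test_reverse_cluster_is_involution_and_flips_strands(toy):
    rev = reverse_cluster(toy)
    assert [g.strand for g in rev.genes] == ["-", "+", "-"]
    back = reverse_cluster(rev)
    assert [(g.start, g.end, g.strand) for g in back.genes] == [
        (g.start, g.end, g.strand) for g in toy.genes
    ]
    assert back.sequence == toy.sequence
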