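"""Read, write and summarize annotated biosynthetic gene cluster records.

A cluster record is one contiguous genomic region (typically 25-60 kb in
the hapalindole/ambiguine/welwitindolinone systems) with its ordered
protein-coding gene features.  GenBank flat files and GFF3+FASTA pairs are
supported on both the read and write side; coordinates are 1-based
inclusive throughout (the GenBank convention; GFF3 shares it, so no shift
is applied at that boundary).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO, BiopythonWarning
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: NCBI translation table for bacterial/plastid CDSs.
BACTERIAL_TABLE = 11


class ClusterIOError(ValueError):
    """Raised on malformed cluster input files."""


@dataclass(frozen=True)
class GeneFeature:
    """One protein-coding gene inside a cluster.

    Coordinates are 1-based inclusive nucleotide positions on the cluster
    sequence; ``strand`` is ``'+'`` or ``'-'``; ``protein`` is the amino
    acid translation without a trailing stop.
    """

    feature_id: str
    label: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(self.protein.upper()) - AA_LETTERS
        if bad:
            raise ValueError(f"non-amino-acid letters in protein: {sorted(bad)}")


@dataclass
class ClusterRecord:
    """An annotated gene cluster: sequence plus ordered gene features."""

    cluster_id: str
    organism: str = ""
    sequence: str = ""
    genes: list[GeneFeature] = field(default_factory=list)
    source_accession: str = ""

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        if self.sequence:
            n = len(self.sequence)
            for g in self.genes:
                if g.end > n:
                    raise ValueError(
                        f"feature {g.feature_id} ends at {g.end} beyond "
                        f"sequence length {n}"
                    )

    def proteins(self) -> dict[str, str]:
        """Map feature id -> protein sequence for all genes with a translation."""
        return {g.feature_id: g.protein for g in self.genes if g.protein}


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster size summary: length in kb (1 decimal) and CDS count."""

    cluster_id: str
    length_kb: float
    n_genes: int


def _translate_cds(sequence: str, start: int, end: int, strand: str) -> str:
    """Translate a CDS span of the cluster sequence (bacterial code).

    Internal stop codons warn rather than raise (draft-genome tolerance);
    ambiguous codons become X.  The trailing stop, if present, is dropped.
    """
    sub = Seq(sequence[start - 1 : end])
    if strand == "-":
        sub = sub.reverse_complement()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        prot = str(sub.translate(table=BACTERIAL_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        logger.warning("internal stop codon in CDS %d..%d (%s)", start, end, strand)
        prot = prot.replace("*", "X")
    return prot


def _feature_to_gene(feat: SeqFeature, sequence: str, index: int) -> GeneFeature:
    quals = feat.qualifiers
    label = (quals.get("gene") or quals.get("locus_tag") or [""])[0]
    product = (quals.get("product") or [""])[0]
    start = int(feat.location.start) + 1  # biopython is 0-based half-open
    end = int(feat.location.end)
    strand = "-" if feat.location.strand == -1 else "+"
    translation = (quals.get("translation") or [""])[0]
    if not translation:
        if not sequence:
            raise ClusterIOError(
                f"CDS at {start}..{end} has no /translation and the record "
                "has no sequence to translate from"
            )
        translation = _translate_cds(sequence, start, end, strand)
    feature_id = (quals.get("protein_id") or [label or f"cds{index}"])[0]
    return GeneFeature(
        feature_id=feature_id,
        label=label,
        start=start,
        end=end,
        strand=strand,
        product=product,
        protein=translation.upper(),
    )


def _record_to_cluster(rec: SeqRecord) -> ClusterRecord:
    seq = str(rec.seq) if rec.seq is not None and len(rec.seq) else ""
    # An undefined sequence (features-only record) raises on str(); treat as empty.
    try:
        seq.encode()
    except Exception:  # pragma: no cover
        seq = ""
    genes = [
        _feature_to_gene(f, seq, i)
        for i, f in enumerate(rec.features)
        if f.type == "CDS"
    ]
    organism = rec.annotations.get("organism", "") or (
        rec.annotations.get("source", "")
    )
    return ClusterRecord(
        cluster_id=rec.id or rec.name,
        organism=organism,
        sequence=seq,
        genes=genes,
        source_accession=rec.id or "",
    )


def read_genbank(path) -> ClusterRecord:
    """Parse the first record of a GenBank flat file into a ClusterRecord.

    CDS features become :class:`GeneFeature`; the ``/translation``
    qualifier is used when present, otherwise the CDS is translated with
    the standard bacterial code.  Gene labels come from ``/gene``, falling
    back to ``/locus_tag``.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ClusterIOError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ClusterIOError(f"no GenBank records in {path}")
    return _record_to_cluster(records[0])


def write_genbank(cluster: ClusterRecord, path) -> None:
    """Write a ClusterRecord as a single-record GenBank flat file."""
    seq = Seq(cluster.sequence) if cluster.sequence else Seq("N")
    rec = SeqRecord(
        seq,
        id=cluster.cluster_id,
        name=cluster.cluster_id[:16].replace(" ", "_") or "cluster",
        description=cluster.organism,
        annotations={"molecule_type": "DNA", "organism": cluster.organism},
    )
    for g in cluster.genes:
        loc = SimpleLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
        quals = {
            "gene": [g.label] if g.label else [],
            "protein_id": [g.feature_id],
            "product": [g.product] if g.product else [],
            "translation": [g.protein] if g.protein else [],
        }
        rec.features.append(
            SeqFeature(loc, type="CDS", qualifiers={k: v for k, v in quals.items() if v})
        )
    SeqIO.write([rec], str(path), "genbank")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(gff_path, fasta_path) -> ClusterRecord:
    """Parse a GFF3 CDS table plus its FASTA sequence into a ClusterRecord.

    Produces the same record as :func:`read_genbank` on an equivalent
    locus.  Only single-segment CDS lines with phase 0 (or '.') are
    accepted: the clusters handled here are bacterial, intron-free loci.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ClusterIOError(f"no FASTA records in {fasta_path}")

    genes: list[GeneFeature] = []
    seqid_seen = None
    organism = ""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ClusterIOError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, phase, attrs = parts
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise ClusterIOError(
                    f"{gff_path}:{lineno}: seqid {seqid!r} not in FASTA "
                    f"({sorted(seqs)})"
                )
            if seqid_seen is None:
                seqid_seen = seqid
            elif seqid != seqid_seen:
                raise ClusterIOError(
                    f"{gff_path}:{lineno}: multiple seqids in one cluster file"
                )
            if phase not in {"0", "."}:
                raise ClusterIOError(
                    f"{gff_path}:{lineno}: CDS with non-zero phase {phase!r} "
                    "not supported for intron-free loci"
                )
            a = _parse_gff3_attributes(attrs)
            s, e = int(start), int(end)
            protein = a.get("translation", "")
            if not protein:
                protein = _translate_cds(seqs[seqid], s, e, strand)
            genes.append(
                GeneFeature(
                    feature_id=a.get("ID", f"cds{len(genes)}"),
                    label=a.get("gene", a.get("Name", "")),
                    start=s,
                    end=e,
                    strand=strand,
                    product=a.get("product", ""),
                    protein=protein.upper(),
                )
            )
    if seqid_seen is None:
        seqid_seen = next(iter(seqs))
        logger.warning("no CDS features in %s; empty cluster", gff_path)
    return ClusterRecord(
        cluster_id=seqid_seen,
        organism=organism,
        sequence=seqs[seqid_seen],
        genes=genes,
        source_accession=seqid_seen,
    )


def write_gff3(cluster: ClusterRecord, gff_path, fasta_path) -> None:
    """Write a ClusterRecord as a GFF3 CDS table plus FASTA sequence."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        if cluster.sequence:
            fh.write(
                f"##sequence-region {cluster.cluster_id} 1 {len(cluster.sequence)}\n"
            )
        for g in cluster.genes:
            attrs = [f"ID={g.feature_id}"]
            if g.label:
                attrs.append(f"gene={g.label}")
            if g.product:
                attrs.append(f"product={g.product}")
            if g.protein:
                attrs.append(f"translation={g.protein}")
            fh.write(
                "\t".join(
                    [
                        cluster.cluster_id,
                        "hapalocompare",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    rec = SeqRecord(
        Seq(cluster.sequence or ""), id=cluster.cluster_id, description=""
    )
    SeqIO.write([rec], str(fasta_path), "fasta")


def write_protein_fasta(cluster: ClusterRecord, path) -> None:
    """Write all gene translations of a cluster as protein FASTA."""
    records = [
        SeqRecord(Seq(g.protein), id=f"{cluster.cluster_id}|{g.feature_id}",
                  description=g.product)
        for g in cluster.genes
        if g.protein
    ]
    SeqIO.write(records, str(path), "fasta")


def summarize(cluster: ClusterRecord) -> ClusterSummary:
    """Cluster length in kb (1 decimal, round-half-even) and CDS count."""
    if not cluster.sequence:
        raise ValueError(f"cluster {cluster.cluster_id} has no sequence")
    return ClusterSummary(
        cluster_id=cluster.cluster_id,
        length_kb=round(len(cluster.sequence) / 1000, 1),
        n_genes=len(cluster.genes),
    )


def write_summary_tsv(clusters: list[ClusterRecord], path) -> None:
    """Emit a cluster-size summary table (TSV)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\torganism\tlength_kb\tn_genes\n")
        for c in clusters:
            s = summarize(c)
            fh.write(f"{c.cluster_id}\t{c.organism}\t{s.length_kb}\t{s.n_genes}\n")


def reverse_cluster(cluster: ClusterRecord) -> ClusterRecord:
    """Reverse-complement a cluster: coordinates and strands flipped."""
    n = len(cluster.sequence)
    if n == 0:
        n = max((g.end for g in cluster.genes), default=0)
    seq = str(Seq(cluster.sequence).reverse_complement()) if cluster.sequence else ""
    genes = [
        replace(
            g,
            start=n - g.end + 1,
            end=n - g.start + 1,
            strand="-" if g.strand == "+" else "+",
        )
        for g in cluster.genes
    ]
    return ClusterRecord(
        cluster_id=cluster.cluster_id,
        organism=cluster.organism,
        sequence=seq,
        genes=genes,
        source_accession=cluster.source_accession,
    )
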