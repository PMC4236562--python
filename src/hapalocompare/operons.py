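"""Transcript (operon) prediction from gene orientation.

Bacterial operons are approximated as maximal runs of consecutive
same-strand genes along the cluster: a strand switch starts a new
predicted transcript.  An optional intergenic-distance cutoff additionally
breaks runs at large gaps, as conventional operon callers do; the default
is orientation-only segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster_io import ClusterRecord


@dataclass(frozen=True)
class TranscriptPrediction:
    """A predicted co-transcribed block of consecutive same-strand genes."""

    transcript_id: str
    strand: str
    gene_labels: tuple[str, ...]
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("transcript start > end")


def predict_transcripts(
    cluster: ClusterRecord, max_intergenic_nt: int | None = None
) -> list[TranscriptPrediction]:
    """Segment the gene list into maximal same-strand runs, 5'→3'.

    When ``max_intergenic_nt`` is given, a run also breaks wherever the
    gap between consecutive genes exceeds it.  Output order follows the
    cluster coordinate order, so concatenating the transcripts reproduces
    the gene order exactly.
    """
    if not cluster.genes:
        raise ValueError(f"cluster {cluster.cluster_id} has no genes")
    runs: list[list] = [[cluster.genes[0]]]
    for prev, gene in zip(cluster.genes, cluster.genes[1:]):
        gap = gene.start - prev.end - 1
        breaks = gene.strand != prev.strand or (
            max_intergenic_nt is not None and gap > max_intergenic_nt
        )
        if breaks:
            runs.append([gene])
        else:
            runs[-1].append(gene)
    return [
        TranscriptPrediction(
            transcript_id=f"{cluster.cluster_id}.t{k}",
            strand=run[0].strand,
            gene_labels=tuple(g.label or g.feature_id for g in run),
            start=min(g.start for g in run),
            end=max(g.end for g in run),
        )
        for k, run in enumerate(runs, 1)
    ]


def write_transcripts_bed(
    transcripts: list[TranscriptPrediction], path, chrom: str
) -> None:
    """Write predictions as BED (0-based half-open) with gene lists in col 7."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(
                f"{chrom}\t{t.start - 1}\t{t.end}\t{t.transcript_id}\t"
                f"{len(t.gene_labels)}\t{t.strand}\t{','.join(t.gene_labels)}\n"
            )
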