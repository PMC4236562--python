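"""End-to-end comparative analysis of a set of gene clusters.

Stages run in a fixed order — IO, all-vs-all alignment, homolog family
assignment and naming, operon prediction, motif scanning, class
prediction, and (when an alignment is supplied) 16S phylogeny with
bootstrap — and the results are written as a report bundle of TSV/JSON/
newick files whose metadata records every threshold and seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import PROTEIN_SCHEME
from .classify import (DEFAULT_REQUIRED_CORE, ClassificationResult, classify,
                       presence_absence_matrix, write_presence_absence_tsv)
from .cluster_io import ClusterRecord, read_genbank, read_gff3, write_summary_tsv
from .families import (HomologFamily, assign_families, core_families,
                       identity_matrix, name_families, sort_key_for_label)
from .motifs import builtin_motifs, scan_all, write_hits_tsv
from .operons import predict_transcripts, write_transcripts_bed
from .phylogeny import (bootstrap_support, root_and_test_monophyly,
                        slice_alignment, write_newick)

logger = logging.getLogger(__name__)

_CANONICAL_RE = re.compile(r"^(?:hpi|amb|wel)?((?:orf|[A-Z])\d*|H)$")


@dataclass
class ReportBundle:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    clusters: list[ClusterRecord]
    families: list[HomologFamily] = field(default_factory=list)
    core: set[str] = field(default_factory=set)
    classifications: list[ClassificationResult] = field(default_factory=list)
    monophyletic: bool | None = None
    files: dict[str, Path] = field(default_factory=dict)


def catalog_from_labels(clusters: list[ClusterRecord]) -> dict[str, str]:
    """Canonical-label catalog inferred from gene names.

    A gene labelled ``welP1`` / ``hpiT4`` / ``ambO3`` yields canonical
    label ``P1`` / ``T4`` / ``O3``; the first protein seen per canonical
    label becomes the exemplar.
    """
    catalog: dict[str, str] = {}
    for cluster in clusters:
        for gene in cluster.genes:
            m = _CANONICAL_RE.match(gene.label or "")
            if m and gene.protein:
                canonical = m.group(1)
                catalog.setdefault(canonical, gene.feature_id)
    return catalog


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def _read_clusters(entries) -> list[ClusterRecord]:
    clusters = []
    for entry in entries:
        if isinstance(entry, str):
            clusters.append(read_genbank(entry))
        else:
            clusters.append(read_gff3(entry["gff"], entry["fasta"]))
    return clusters


def run_pipeline(config: dict | str | Path, out_dir) -> ReportBundle:
    """Run every analysis stage and write the report bundle.

    ``config`` is a mapping (or path to a YAML file) with keys:
    ``clusters`` (list of GenBank paths or ``{gff, fasta}`` pairs),
    optional ``msa_16s`` (FASTA of aligned 16S sequences), and the knobs
    ``identity_threshold`` (default 90), ``bootstrap_replicates``
    (default 100), ``msa_slice`` (default 929), ``seed`` (default 0),
    ``outgroup`` and ``clade_taxa`` (for the monophyly question).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    threshold = float(config.get("identity_threshold", 90))
    n_boot = int(config.get("bootstrap_replicates", 100))
    slice_len = int(config.get("msa_slice", 929))
    seed = int(config.get("seed", 0))

    bundle = ReportBundle(out_dir=out, clusters=_read_clusters(config["clusters"]))
    clusters = bundle.clusters
    if not clusters:
        raise ValueError("pipeline stage io: no clusters supplied")

    write_summary_tsv(clusters, out / "cluster_summary.tsv")
    bundle.files["summary"] = out / "cluster_summary.tsv"

    proteins: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    products: dict[str, str] = {}
    for c in clusters:
        for g in c.genes:
            if not g.protein:
                continue
            if g.feature_id in proteins:
                raise ValueError(
                    f"pipeline stage alignment: duplicate protein id "
                    f"{g.feature_id!r} in cluster {c.cluster_id}"
                )
            proteins[g.feature_id] = g.protein
            cluster_of[g.feature_id] = c.cluster_id
            products[g.feature_id] = g.product

    labels_by_cluster: dict[str, set[str]] = {c.cluster_id: set() for c in clusters}
    if len(clusters) >= 2:
        m = identity_matrix(proteins, PROTEIN_SCHEME)
        fams = assign_families(m, threshold_pct=threshold, cluster_of=cluster_of)
        catalog = config.get("catalog") or catalog_from_labels(clusters)
        fams = name_families(fams, catalog, m, products=products,
                             threshold_pct=threshold)
        fams.sort(key=lambda f: sort_key_for_label(f.family_label))
        bundle.families = fams
        bundle.core = core_families(
            fams, [c.cluster_id for c in clusters],
            required_fraction=float(config.get("core_fraction", 1.0)),
        )
        with open(out / "families.tsv", "w") as fh:
            fh.write("family\tn_members\tmin_identity\tmean_identity\tmembers\n")
            for f in fams:
                fh.write(
                    f"{f.family_label}\t{len(f.members)}\t{f.min_identity_pct}\t"
                    f"{f.mean_identity_pct}\t"
                    + ";".join(f"{cid}:{pid}" for cid, pid in f.members) + "\n"
                )
        bundle.files["families"] = out / "families.tsv"
        pa = presence_absence_matrix([c.cluster_id for c in clusters], fams)
        write_presence_absence_tsv(pa, out / "presence_absence.tsv")
        bundle.files["presence_absence"] = out / "presence_absence.tsv"
        for f in fams:
            for cid, _ in f.members:
                labels_by_cluster[cid].add(f.family_label)
    else:
        logger.info("single cluster: family assignment and naming skipped")

    bed_lines = []
    for c in clusters:
        for t in predict_transcripts(c):
            bed_lines.append(
                f"{c.cluster_id}\t{t.start - 1}\t{t.end}\t{t.transcript_id}\t"
                f"{len(t.gene_labels)}\t{t.strand}\t{','.join(t.gene_labels)}"
            )
    (out / "transcripts.bed").write_text("\n".join(bed_lines) + "\n")
    bundle.files["transcripts"] = out / "transcripts.bed"

    patterns = builtin_motifs(config.get("extra_motifs"))
    hits = scan_all(proteins, patterns)
    write_hits_tsv(hits, out / "motif_hits.tsv")
    bundle.files["motifs"] = out / "motif_hits.tsv"

    if len(clusters) >= 2:
        results = [
            classify(
                c.cluster_id,
                labels_by_cluster[c.cluster_id],
                core_reference=frozenset(
                    config.get("required_core", DEFAULT_REQUIRED_CORE)
                ),
            )
            for c in clusters
        ]
        bundle.classifications = results
        payload = {
            r.cluster_id: {
                "class": r.predicted_class,
                "evidence": [list(e) for e in r.evidence],
                "flags": sorted(r.flags),
                "missing_core": list(r.missing_core),
            }
            for r in results
        }
        (out / "classifications.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        bundle.files["classifications"] = out / "classifications.json"
    else:
        logger.info("single cluster: classification skipped")

    if config.get("msa_16s"):
        from Bio import SeqIO

        msa = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(config["msa_16s"]), "fasta")}
        width = len(next(iter(msa.values())))
        if width > slice_len:
            msa = slice_alignment(msa, slice_len)
        tree = bootstrap_support(msa, n_replicates=n_boot, seed=seed)
        write_newick(tree, out / "tree_16s.nwk")
        bundle.files["tree"] = out / "tree_16s.nwk"
        if config.get("outgroup") and config.get("clade_taxa"):
            bundle.monophyletic = root_and_test_monophyly(
                tree, set(config["clade_taxa"]), config["outgroup"]
            )

    metadata = {
        "version": __version__,
        "identity_threshold": threshold,
        "bootstrap_replicates": n_boot,
        "msa_slice": slice_len,
        "seed": seed,
        "identity_definition": "matches / alignment columns (gaps included)",
        "distance_model": "JC69, pairwise deletion",
        "n_clusters": len(clusters),
        "monophyletic": bundle.monophyletic,
        "core_families": sorted(bundle.core, key=sort_key_for_label),
    }
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    bundle.files["metadata"] = out / "run_metadata.json"
    return bundle
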