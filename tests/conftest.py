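from __future__ import annotations

import sys
from pathlib import Path

import pytest
from Bio.Seq import Seq

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hapalocompare.cluster_io import ClusterRecord, GeneFeature, write_genbank
from hapalocompare.pipeline import run_pipeline
from hapalocompare.synthetic import (study_preset_16s_newick,
                                     study_preset_config, simulate_16s_msa,
                                     simulate_cluster_set)

MIMIC_SEED = 11
BOOT_SEED = 7


def toy_cluster() -> ClusterRecord:
    """Three-gene cluster with a minus-strand CDS and full sequence.

    Gene g2 (minus strand, 101..202) encodes M + 32xA: the coding strand
    is ATG + 32xGCT + TAA, embedded reverse-complemented.
    """
    coding_g2 = "ATG" + "GCT" * 32 + "TAA"
    rc_g2 = str(Seq(coding_g2).reverse_complement())
    coding_g1 = "ATGAAAACTTAA"  # MKT
    coding_g3 = "ATGTGGTATTAA"  # MWY
    seq = (
        "A" * 10 + coding_g1               # g1 at 11..22, + strand
        + "C" * 78 + rc_g2                 # g2 at 101..202, - strand
        + "G" * 18 + coding_g3             # g3 at 221..232, + strand
        + "T" * 8
    )
    genes = [
        GeneFeature("g1", "hpiT1", 11, 22, "+", "tryptophan synthase", "MKT"),
        GeneFeature("g2", "hpiO1", 101, 202, "-", "oxygenase",
                    "M" + "A" * 32),
        GeneFeature("g3", "hpiC1", 221, 232, "+", "kinase", "MWY"),
    ]
    return ClusterRecord(
        cluster_id="toy1", organism="Fischerella test", sequence=seq,
        genes=genes, source_accession="synthetic",
    )


@pytest.fixture
def toy():
    return toy_cluster()


@pytest.fixture(scope="session")
def mimic():
    """The nine-cluster synthetic study preset with its ground truth."""
    cfg = study_preset_config(MIMIC_SEED)
    records, truth = simulate_cluster_set(cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def mimic_dir(tmp_path_factory, mimic):
    """The preset written to disk as GenBank + GFF3/FASTA files."""
    _, _, cfg = mimic
    out = tmp_path_factory.mktemp("mimic_clusters")
    simulate_cluster_set(cfg, out_dir=out)
    return out


@pytest.fixture(scope="session")
def mimic_msa(tmp_path_factory):
    """Simulated 16S alignment (1000 columns) for the preset taxa."""
    msa, _ = simulate_16s_msa(study_preset_16s_newick(), msa_length=1000,
                              seed=MIMIC_SEED)
    out = tmp_path_factory.mktemp("msa") / "sixteen_s.fasta"
    with open(out, "w") as fh:
        for taxon, seq in msa.items():
            fh.write(f">{taxon}\n{seq}\n")
    return out


def mimic_pipeline_config(mimic_dir: Path, mimic_msa: Path, mimic) -> dict:
    records, _, _ = mimic
    cluster_ids = [r.cluster_id for r in records]
    return {
        "clusters": [str(mimic_dir / f"{cid}.gbk") for cid in cluster_ids],
        "msa_16s": str(mimic_msa),
        "identity_threshold": 90,
        "bootstrap_replicates": 100,
        "msa_slice": 929,
        "seed": BOOT_SEED,
        "outgroup": "OUTGROUP",
        "clade_taxa": cluster_ids,
    }


@pytest.fixture(scope="session")
def mimic_bundle(tmp_path_factory, mimic_dir, mimic_msa, mimic):
    """One full pipeline run on the preset."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = mimic_pipeline_config(mimic_dir, mimic_msa, mimic)
    return run_pipeline(cfg, out)


@pytest.fixture
def toy_genbank(tmp_path, toy):
    path = tmp_path / "toy1.gbk"
    write_genbank(toy, path)
    return path
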