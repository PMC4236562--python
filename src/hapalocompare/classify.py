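"""Rule-based cluster classification: hpi, amb or wel.

The three cluster classes are distinguished by gene complement rather than
by any single phylogenetic signal:

* ``amb`` — carries the second aromatic prenyltransferase P3, unique to
  the ambiguine cluster (precedence 1);
* ``wel`` — carries any welwitindolinone marker: the methyltransferases
  M1-M3, regulator R3, exporter E4, oxygenases O11-O19, or DUF genes
  U7/U8 (precedence 2);
* ``hpi`` — the default: the shared core without class markers.

A cluster missing members of the conserved required core (isonitrile,
prenyl, isoprenoid, tryptophan genes) is flagged putatively
non-functional, mirroring the interpretation of truncated clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .families import HomologFamily, sort_key_for_label

logger = logging.getLogger(__name__)

#: Families specific to wel clusters.
WEL_MARKERS = frozenset(
    {"M1", "M2", "M3", "R3", "E4", "U7", "U8"}
    | {f"O{i}" for i in range(11, 20)}
)

#: Family required for an amb call.
AMB_MARKER = "P3"

#: Conserved core whose absence flags a cluster putatively non-functional.
DEFAULT_REQUIRED_CORE = frozenset(
    {"I1", "I3", "P1", "P2"}
    | {f"D{i}" for i in range(1, 5)}
    | {f"T{i}" for i in range(1, 6)}
    | {f"C{i}" for i in range(1, 4)}
)


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted class with the marker evidence and functionality flags."""

    cluster_id: str
    predicted_class: str
    evidence: tuple[tuple[str, str], ...]
    flags: frozenset[str]
    missing_core: tuple[str, ...]


def classify(
    cluster_id: str,
    family_labels: set[str],
    core_reference: frozenset[str] | set[str] = DEFAULT_REQUIRED_CORE,
    wel_markers: frozenset[str] | set[str] = WEL_MARKERS,
) -> ClassificationResult:
    """Predict the product class of a cluster from its family complement.

    Precedence: P3 present → amb; any wel marker present → wel; otherwise
    hpi.  amb outranks wel (P3 is unique to amb and no known cluster
    carries both marker sets; a dual-marker input yields amb plus a
    warning).  Order-independent and deterministic in the label set.
    """
    if not family_labels:
        raise ValueError(f"cluster {cluster_id}: empty family label set")
    labels = set(family_labels)
    wel_evidence = sorted(labels & set(wel_markers), key=sort_key_for_label)
    evidence: list[tuple[str, str]] = []
    if AMB_MARKER in labels:
        predicted = "amb"
        evidence.append((AMB_MARKER, "amb_marker_P3"))
        if wel_evidence:
            logger.warning(
                "cluster %s carries both P3 and wel markers %s; amb takes "
                "precedence", cluster_id, wel_evidence,
            )
    elif wel_evidence:
        predicted = "wel"
        evidence.extend((lab, "wel_marker") for lab in wel_evidence)
    else:
        predicted = "hpi"
    missing = sorted(set(core_reference) - labels, key=sort_key_for_label)
    flags = frozenset({"putatively_nonfunctional"} if missing else set())
    return ClassificationResult(
        cluster_id=cluster_id,
        predicted_class=predicted,
        evidence=tuple(evidence),
        flags=flags,
        missing_core=tuple(missing),
    )


def presence_absence_matrix(
    cluster_ids: list[str], families: list[HomologFamily]
) -> pd.DataFrame:
    """Binary family × cluster matrix (1 = present), table-ordered rows."""
    if not cluster_ids:
        raise ValueError("empty cluster list")
    rows = {}
    for fam in families:
        present = {cid for cid, _ in fam.members}
        rows[fam.family_label] = [int(c in present) for c in cluster_ids]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cluster_ids)
    return df.loc[sorted(df.index, key=sort_key_for_label)]


def write_presence_absence_tsv(df: pd.DataFrame, path) -> None:
    """Serialize the matrix as TSV with '-' marking absence."""
    out = df.replace({0: "-", 1: "1"})
    out.to_csv(path, sep="\t", index_label="family")
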