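"""Homolog family assignment across gene clusters.

Proteins from different clusters are grouped into labelled homolog
families by the >90%-identity rule: an all-vs-all global-alignment
identity matrix is thresholded (strictly greater than the threshold) and
single-linkage connected components become families.  Families are then
named against a reference catalog of canonical exemplars (T1-5, C1-3,
D1-4, I1-3, P1-3, M1-3, R1-3, E1-4, O1-19, U1-8, H, orf1-9), and core
families — those present in (a required fraction of) all clusters — are
reported with min/mean identity summaries.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .alignment import PROTEIN_SCHEME, ScoringScheme, needleman_wunsch

#: Sentinel for identity summaries of singleton families.
NA = "n/a"


@dataclass
class IdentityMatrix:
    """Symmetric all-vs-all percent-identity matrix over labelled proteins."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class HomologFamily:
    """A set of proteins connected by pairwise identity above threshold."""

    family_label: str
    members: list[tuple[str, str]]  # (cluster_id, protein_id)
    min_identity_pct: float | str = NA
    mean_identity_pct: float | str = NA
    product: str = ""

    def member_ids(self) -> list[str]:
        return [pid for _, pid in self.members]


def identity_matrix(
    proteins: dict[str, str], scheme: ScoringScheme = PROTEIN_SCHEME
) -> IdentityMatrix:
    """All-vs-all global-alignment percent identities.

    ``proteins`` maps protein id -> amino-acid sequence.  Each unordered
    pair is aligned once; the matrix is symmetric by construction with a
    diagonal of 100.
    """
    labels = list(proteins)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate protein ids")
    if not labels:
        raise ValueError("need at least one protein")
    n = len(labels)
    m = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        pid = needleman_wunsch(proteins[labels[i]], proteins[labels[j]], scheme).identity_pct
        m[i, j] = m[j, i] = pid
    return IdentityMatrix(labels=labels, values=m)


def assign_families(
    m: IdentityMatrix,
    threshold_pct: float = 90.0,
    cluster_of: dict[str, str] | None = None,
) -> list[HomologFamily]:
    """Single-linkage families: connected components of the >threshold graph.

    The threshold is strict (identity must exceed it), so a pair at
    exactly 90.0 does *not* join.  Families are ordered by their smallest
    member index; singletons are allowed.  ``cluster_of`` maps protein id
    -> cluster id for provenance (defaults to empty strings).
    """
    if not (0 < threshold_pct <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {threshold_pct}")
    cluster_of = cluster_of or {}
    g = nx.Graph()
    g.add_nodes_from(range(len(m.labels)))
    n = len(m.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if m.values[i, j] > threshold_pct:
                g.add_edge(i, j)
    components = sorted(nx.connected_components(g), key=min)
    families = []
    for k, comp in enumerate(components, 1):
        idx = sorted(comp)
        members = [(cluster_of.get(m.labels[i], ""), m.labels[i]) for i in idx]
        fam = HomologFamily(family_label=f"F{k}", members=members)
        mn_mean = family_identity_summary(fam, m)
        fam.min_identity_pct, fam.mean_identity_pct = mn_mean
        families.append(fam)
    return families


def family_identity_summary(
    family: HomologFamily, m: IdentityMatrix
) -> tuple[float | str, float | str]:
    """(min, mean) pairwise identity over family members, 1 decimal.

    Singleton families have no pairs; the sentinel ``"n/a"`` is returned
    for both values.
    """
    ids = family.member_ids()
    if len(ids) < 2:
        return NA, NA
    pairs = [m.get(a, b) for a, b in itertools.combinations(ids, 2)]
    return round(min(pairs), 1), round(float(np.mean(pairs)), 1)


_CATEGORY_RE = re.compile(r"^(orf|[A-Z])(\d*)$")

#: Canonical label categories, keyed by prefix.
CATEGORIES = {
    "T": "tryptophan biosynthesis",
    "C": "other enzyme",
    "D": "IPP/DMAPP biosynthesis",
    "I": "isonitrile biosynthesis",
    "P": "prenyltransferase",
    "M": "methyltransferase",
    "R": "regulation",
    "E": "transporter",
    "O": "oxygenase",
    "U": "unknown (DUF)",
    "H": "halogenase",
    "orf": "open reading frame",
}


def _category_for_product(product: str) -> str:
    p = product.lower()
    for prefix, keyword in [
        ("O", "oxygenase"), ("O", "oxidoreductase"), ("O", "monooxygenase"),
        ("M", "methyltransferase"), ("P", "prenyltransferase"),
        ("T", "tryptophan"), ("D", "synthase"), ("R", "regulator"),
        ("E", "transporter"), ("H", "halogenase"), ("U", "unknown"),
    ]:
        if keyword in p:
            return prefix
    return "orf"


def name_families(
    families: list[HomologFamily],
    reference_catalog: dict[str, str],
    m: IdentityMatrix,
    products: dict[str, str] | None = None,
    threshold_pct: float = 90.0,
) -> list[HomologFamily]:
    """Label families against a catalog of canonical exemplar proteins.

    ``reference_catalog`` maps canonical labels (e.g. ``"P1"``) to
    exemplar protein ids present in the identity matrix.  Each family is
    labelled by its best-matching exemplar (highest identity above the
    threshold; ties broken by the lexicographically smallest label).
    Unmatched families receive fresh sequential labels with a category
    prefix inferred from the product annotation (e.g. ``"Onew1"``).
    Two families claiming one canonical label is a conflict error.
    """
    products = products or {}
    named: list[HomologFamily] = []
    used: dict[str, str] = {}
    fresh_counters: dict[str, int] = {}
    for fam in families:
        best_label, best_pid = "", -1.0
        for label, exemplar_id in sorted(reference_catalog.items()):
            if exemplar_id not in m.labels:
                continue
            top = max(m.get(exemplar_id, pid) for pid in fam.member_ids())
            if top > threshold_pct and (
                top > best_pid or (top == best_pid and label < best_label)
            ):
                best_label, best_pid = label, top
        if best_label:
            if best_label in used:
                raise ValueError(
                    f"families {used[best_label]!r} and members "
                    f"{fam.member_ids()} both map to canonical label "
                    f"{best_label!r}"
                )
            used[best_label] = ",".join(fam.member_ids())
            label = best_label
        else:
            prod = next(
                (products[pid] for pid in fam.member_ids() if products.get(pid)), ""
            )
            prefix = _category_for_product(prod)
            fresh_counters[prefix] = fresh_counters.get(prefix, 0) + 1
            label = f"{prefix}new{fresh_counters[prefix]}"
        named.append(replace(fam, family_label=label,
                             product=products.get(fam.member_ids()[0], "")))
    return named


def core_families(
    families: list[HomologFamily],
    cluster_ids: list[str],
    required_fraction: float = 1.0,
) -> set[str]:
    """Labels of families present in at least ``required_fraction`` of clusters."""
    if len(cluster_ids) < 2:
        raise ValueError("core families need >= 2 clusters")
    need = required_fraction * len(cluster_ids)
    out = set()
    for fam in families:
        present = {cid for cid, _ in fam.members if cid in cluster_ids}
        if len(present) >= need:
            out.add(fam.family_label)
    return out


def sort_key_for_label(label: str) -> tuple:
    """Deterministic table order: category prefix, then number, then text."""
    match = _CATEGORY_RE.match(label)
    order = list(CATEGORIES)
    if match and match.group(1) in CATEGORIES:
        prefix, num = match.group(1), match.group(2)
        return (order.index(prefix), int(num) if num else 0, label)
    return (len(order), 0, label)
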