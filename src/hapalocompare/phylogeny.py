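"""Distance-based phylogenetics: JC69 distances, neighbour-joining,
bootstrap support, outgroup rooting and monophyly testing.

The 16S rDNA analysis takes an alignment slice (929 columns by default),
computes Jukes-Cantor distances with pairwise deletion, builds a
Saitou-Nei neighbour-joining tree, annotates its internal edges with
bootstrap percentages from column-resampled replicates, roots on a
distant outgroup and asks whether the cluster-bearing taxa form a clade.
The same machinery runs on protein alignments with p-distances (used for
the prenyltransferase tree).

Trees are :class:`dendropy.Tree` objects (newick-serializable); the NJ
agglomeration itself is implemented here with a deterministic
smallest-index tie-break and negative branch lengths clamped to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

MSA = dict[str, str]  # taxon -> aligned (gapped) sequence

_NUC = set("ACGT")
_GAPLIKE = set("-.NX?")


class SaturationError(ValueError):
    """Raised when a pair's mismatch fraction exceeds the JC69 domain."""


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(m).all() or m.min() < 0:
            raise ValueError("distances must be finite and non-negative")
        self.d = m


def _check_msa(msa: MSA) -> None:
    if len(msa) < 2:
        raise ValueError("alignment needs >= 2 rows")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")


def slice_alignment(msa: MSA, length: int, start: int = 1) -> MSA:
    """Retain ``length`` columns from 1-based column ``start``."""
    _check_msa(msa)
    width = len(next(iter(msa.values())))
    if length <= 0:
        raise ValueError(f"slice length must be positive, got {length}")
    if start < 1 or start - 1 + length > width:
        raise ValueError(
            f"slice [{start}, {start + length - 1}] outside alignment of "
            f"width {width}"
        )
    return {t: s[start - 1 : start - 1 + length] for t, s in msa.items()}


def _pair_mismatch_fraction(a: str, b: str, valid: set) -> float | None:
    n = matches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in valid and y in valid:
            n += 1
            matches += x == y
    if n == 0:
        return None
    return 1.0 - matches / n


def jc69_distance(msa: MSA) -> DistanceMatrix:
    """Jukes-Cantor distances with pairwise deletion.

    Columns where either row carries a gap or ambiguous base are dropped
    per pair; d = -(3/4) ln(1 - 4p/3).  A pair with p >= 0.75 is outside
    the model's domain and raises :class:`SaturationError` naming the
    taxa.
    """
    _check_msa(msa)
    taxa = list(msa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pair_mismatch_fraction(msa[taxa[i]], msa[taxa[j]], _NUC)
            if p is None:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            if p >= 0.75:
                raise SaturationError(
                    f"pair ({taxa[i]}, {taxa[j]}) saturated: p = {p:.3f} >= 0.75"
                )
            d[i, j] = d[j, i] = -0.75 * math.log(1 - 4 * p / 3)
    return DistanceMatrix(taxa=taxa, d=d)


def p_distance(msa: MSA, alphabet: str = "protein") -> DistanceMatrix:
    """Raw mismatch-fraction distances with pairwise deletion.

    The protein-tree alternative to JC69 (used for the prenyltransferase
    alignment); for nucleotides it is the uncorrected p-distance.
    """
    _check_msa(msa)
    valid = set("ACDEFGHIKLMNPQRSTVWY") if alphabet == "protein" else _NUC
    taxa = list(msa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pair_mismatch_fraction(msa[taxa[i]], msa[taxa[j]], valid)
            if p is None:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=taxa, d=d)


def _clamped(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative branch length %.6f clamped to 0 (%s)",
                       length, context)
        return 0.0
    return length


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; returns an unrooted dendropy tree.

    The Q-matrix minimum is selected with a deterministic tie-break (the
    lexicographically smallest active index pair); negative branch
    lengths are clamped to zero with a warning.  Exact on additive
    distance matrices.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError(f"neighbour joining needs >= 3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(D.taxa)
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(t)) for i, t in enumerate(D.taxa)
    }
    d = {(i, j): float(D.d[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        li = dist(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist(i, j) - li
        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes[i].edge.length = _clamped(li, f"join {i},{j}")
        nodes[j].edge.length = _clamped(lj, f"join {i},{j}")
        for k in active:
            if k in (i, j):
                continue
            d[(min(next_id, k), max(next_id, k))] = (
                dist(i, k) + dist(j, k) - dist(i, j)
            ) / 2
        nodes[next_id] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # three-point closure: central node with exact branch lengths
    a, b, c = active
    root = dendropy.Node()
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = _clamped(lk, "three-point closure")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset) -> set[frozenset]:
    """Internal-edge bipartitions, each canonicalized to the side without
    the alphabetically first taxon."""
    ref = min(all_taxa)
    bips: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= len(all_taxa) - 2:
            side = below if ref not in below else all_taxa - below
            bips.add(side)
    return bips


def tree_distance_oracle(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree (additive matrix)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    n = len(taxa)
    d = np.zeros((n, n))
    by_label = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                by_label[taxa[i]], by_label[taxa[j]]
            )
    return DistanceMatrix(taxa=taxa, d=d)


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "jc69",
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap edge supports.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate is re-distanced and re-joined, and every internal edge of
    the full-data tree is annotated (node label and ``support``
    attribute) with the percentage of replicate trees containing the same
    bipartition.  Replicates with a saturated pair are skipped with a
    warning and the denominator adjusts.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    _check_msa(msa)
    distance = jc69_distance if model == "jc69" else p_distance
    full_tree = neighbor_joining(distance(msa))
    taxa = list(msa)
    all_taxa = frozenset(taxa)
    width = len(next(iter(msa.values())))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    valid = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        resampled = {t: "".join(msa[t][c] for c in cols) for t in taxa}
        try:
            rep_tree = neighbor_joining(distance(resampled))
        except SaturationError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        valid += 1
        for bip in _bipartitions(rep_tree, all_taxa):
            counts[bip] = counts.get(bip, 0) + 1
    if valid == 0:
        raise SaturationError("all bootstrap replicates saturated")
    for node in full_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (2 <= len(below) <= len(all_taxa) - 2):
            continue
        side = below if min(all_taxa) not in below else all_taxa - below
        pct = 100.0 * counts.get(side, 0) / valid
        node.label = f"{pct:.0f}"
        node.support = pct
    return full_tree


def clade_support(tree: dendropy.Tree, taxa_subset: set[str]) -> float | None:
    """Bootstrap support of the edge separating ``taxa_subset`` from the
    rest, or None when no such edge exists in the tree."""
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    target = frozenset(taxa_subset)
    side = target if min(all_taxa) not in target else all_taxa - target
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        canonical = below if min(all_taxa) not in below else all_taxa - below
        if canonical == side:
            return getattr(node, "support", None)
    return None


def root_and_test_monophyly(
    tree: dendropy.Tree, taxa_subset: set[str], outgroup_taxon: str
) -> bool:
    """Root on the outgroup edge; is ``taxa_subset`` exactly some clade?

    The input tree is not modified.
    """
    if not taxa_subset:
        raise ValueError("taxa_subset is empty")
    labels = {t.label for t in tree.taxon_namespace}
    unknown = (set(taxa_subset) | {outgroup_taxon}) - labels
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if outgroup_taxon in taxa_subset:
        raise ValueError("taxa_subset must exclude the outgroup")
    rooted = tree.clone(depth=1)
    og = rooted.find_node_with_taxon_label(outgroup_taxon)
    rooted.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = rooted.mrca(taxon_labels=list(taxa_subset))
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == set(taxa_subset)


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".6f",
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
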