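from __future__ import annotations

import math

import dendropy
import numpy as np
import pytest

from hapalocompare.phylogeny import (DistanceMatrix, SaturationError,
                                     bootstrap_support, clade_support,
                                     jc69_distance, neighbor_joining,
                                     p_distance, read_newick,
                                     root_and_test_monophyly, slice_alignment,
                                     tree_distance_oracle, write_newick)

from oracles import random_tuple_tree, tuple_tree_distances


def msa_of(**rows):
    return dict(rows)


def test_slice_alignment_basics():
    msa = {"a": "ACGT" * 250, "b": "ACGT" * 250}
    sliced = slice_alignment(msa, 929)
    assert all(len(s) == 929 for s in sliced.values())
    assert slice_alignment(msa, 1000) == msa
    with pytest.raises(ValueError):
        slice_alignment(msa, 0)
    with pytest.raises(ValueError):
        slice_alignment(msa, 1001)
    offset = slice_alignment(msa, 4, start=3)
    assert offset["a"] == "GTAC"


def test_jc69_zero_distance_for_identical_rows():
    d = jc69_distance({"a": "ACGTACGT", "b": "ACGTACGT"})
    assert d.d[0, 1] == 0.0


def test_jc69_closed_form_at_p_0_1():
    # 10 mismatches over 100 columns: d = -(3/4) ln(1 - 4*0.1/3)
    a = "A" * 100
    b = "C" * 10 + "A" * 90
    d = jc69_distance({"a": a, "b": b})
    assert d.d[0, 1] == pytest.approx(0.107326, abs=1e-6)


def test_jc69_pairwise_deletion_ignores_gap_columns():
    d = jc69_distance({"a": "ACGT--NA", "b": "ACGTAC-A"})
    # only columns 1-4 and 8 comparable, all matches
    assert d.d[0, 1] == 0.0


def test_jc69_saturation_error_names_taxa():
    a = "A" * 100
    b = "C" * 80 + "A" * 20
    with pytest.raises(SaturationError, match="taxA.*taxB"):
        jc69_distance({"taxA": a, "taxB": b})


def test_jc69_monotone_in_p():
    def dist(k):
        a = "A" * 100
        b = "C" * k + "A" * (100 - k)
        return jc69_distance({"a": a, "b": b}).d[0, 1]

    values = [dist(k) for k in range(0, 70, 5)]
    assert all(x < y for x, y in zip(values, values[1:]))


def test_p_distance_protein():
    d = p_distance({"a": "MKTA", "b": "MKTV"}, alphabet="protein")
    assert d.d[0, 1] == pytest.approx(0.25)


def test_three_taxon_branch_lengths_solve_three_point_equations():
    taxa = ["a", "b", "c"]
    D = DistanceMatrix(taxa, np.array([[0, 0.3, 0.5], [0.3, 0, 0.4],
                                       [0.5, 0.4, 0]]))
    tree = neighbor_joining(D)
    lengths = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
@pytest.mark.parametrize("trial", range(8))
def test_nj_exact_on_additive_matrices(n_taxa, trial):
    rng = np.random.default_rng(500 + 13 * n_taxa + trial)
    labels = [f"t{i}" for i in range(n_taxa)]
    tree = random_tuple_tree(labels, rng)
    pairs = tuple_tree_distances(tree)
    d = np.zeros((n_taxa, n_taxa))
    for (x, y), v in pairs.items():
        i, j = labels.index(x), labels.index(y)
        d[i, j] = d[j, i] = v
    nj = neighbor_joining(DistanceMatrix(labels, d))
    recovered = tree_distance_oracle(nj)
    for (x, y), v in pairs.items():
        i, j = recovered.taxa.index(x), recovered.taxa.index(y)
        assert recovered.d[i, j] == pytest.approx(v, abs=1e-9)


def test_nj_clamps_negative_lengths(caplog):
    # a decidedly non-additive matrix can produce negative estimates
    d = np.array([
        [0.0, 0.1, 0.6, 0.6],
        [0.1, 0.0, 0.6, 0.6],
        [0.6, 0.6, 0.0, 0.01],
        [0.6, 0.6, 0.01, 0.0],
    ])
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], d))
    assert all(
        (n.edge.length or 0) >= 0
        for n in tree.preorder_node_iter() if n.parent_node
    )


def test_bootstrap_deterministic_under_seed(mimic_msa_small):
    t1 = bootstrap_support(mimic_msa_small, n_replicates=30, seed=5)
    t2 = bootstrap_support(mimic_msa_small, n_replicates=30, seed=5)
    s1 = {n.label for n in t1.preorder_node_iter() if n.label}
    s2 = {n.label for n in t2.preorder_node_iter() if n.label}
    assert s1 == s2


def test_bootstrap_supports_bounded_and_strong_split_found(mimic_msa_small):
    tree = bootstrap_support(mimic_msa_small, n_replicates=50, seed=2)
    supports = [
        n.support for n in tree.preorder_node_iter()
        if getattr(n, "support", None) is not None
    ]
    assert supports and all(0 <= s <= 100 for s in supports)
    group = {t for t in mimic_msa_small if t.startswith("W")}
    assert clade_support(tree, group) >= 95


def test_bootstrap_rejects_nonpositive_replicates(mimic_msa_small):
    with pytest.raises(ValueError):
        bootstrap_support(mimic_msa_small, n_replicates=0, seed=1)


@pytest.fixture(scope="module")
def mimic_msa_small():
    from hapalocompare.synthetic import simulate_16s_msa

    newick = ("(((W1:0.02,W2:0.02):0.04,(W3:0.03,W4:0.02):0.03):0.08,"
              "(X1:0.05,X2:0.06):0.05,OUT:0.35);")
    msa, _ = simulate_16s_msa(newick, msa_length=800, seed=9)
    return msa


def test_monophyly_on_known_topology():
    tree = dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1,D:1):1,out:3);", schema="newick"
    )
    assert root_and_test_monophyly(tree, {"A", "B"}, "out") is True
    assert root_and_test_monophyly(tree, {"A", "C"}, "out") is False
    assert root_and_test_monophyly(tree, {"A", "B", "C", "D"}, "out") is True
    with pytest.raises(ValueError, match="unknown"):
        root_and_test_monophyly(tree, {"A", "Z"}, "out")
    with pytest.raises(ValueError):
        root_and_test_monophyly(tree, {"A", "out"}, "out")
    with pytest.raises(ValueError):
        root_and_test_monophyly(tree, set(), "out")


def test_newick_roundtrip_topology_lengths_supports(tmp_path, mimic_msa_small):
    tree = bootstrap_support(mimic_msa_small, n_replicates=20, seed=3)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    d1 = tree_distance_oracle(tree)
    d2 = tree_distance_oracle(back)
    assert d1.taxa == d2.taxa
    assert np.allclose(d1.d, d2.d, atol=1e-6)
    labels_in = sorted(n.label for n in tree.preorder_node_iter()
                       if n.label and not n.is_leaf())
    labels_out = sorted(n.label for n in back.preorder_node_iter()
                        if n.label and not n.is_leaf())
    assert labels_in == labels_out


def test_distance_matrix_invariants():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, -1.0], [-1.0, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0]]))
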