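import itertools
import random

import dendropy
import pytest

from mitocomp import (Alignment, build_supermatrix, distance_matrix,
                      is_monophyletic, nj_tree, write_partitions, write_phylip)
from mitocomp.phylo import FrameError


def _codon_aln(names, n_codons, seed):
    rng = random.Random(seed)
    rows = ["".join(rng.choice("ACGT") for _ in range(3 * n_codons))
            for _ in names]
    return Alignment(list(names), rows, is_codon=True)


def test_supermatrix_variant_column_arithmetic():
    g1 = _codon_aln(["a", "b"], 2, 1)   # 6 columns
    g2 = _codon_aln(["a", "b"], 3, 2)   # 9 columns
    sup = build_supermatrix({"COX1": g1, "ND2": g2}, "P123")
    assert sup.n_cols == 15
    assert set(sup.partitions) == {"COX1", "ND2"}
    sup12 = build_supermatrix({"COX1": g1, "ND2": g2}, "P12")
    assert sup12.n_cols == 10


def test_supermatrix_pads_missing_taxa_with_gaps():
    g1 = _codon_aln(["a", "b"], 4, 3)
    g2 = _codon_aln(["a"], 4, 4)
    sup = build_supermatrix({"COX1": g1, "ND2": g2}, "P123")
    # genes concatenate in canonical order (ND2 before COX1)
    assert sup.alignment.row("b").startswith("-" * 12)


def test_p12_variant_requires_codon_alignment():
    notcodon = Alignment(["a", "b"], ["ACGTAC", "ACGTAC"], is_codon=False)
    with pytest.raises(FrameError):
        build_supermatrix({"COX1": notcodon}, "P12")


def test_variant_length_ordering(panel):
    alns = dict(panel.alignments)
    lengths = {v: build_supermatrix(alns, v).n_cols
               for v in ("P123R", "P123", "P12R", "P12")}
    assert lengths["P123R"] >= lengths["P123"]
    assert lengths["P12R"] >= lengths["P12"]
    assert lengths["P123"] > lengths["P12"]


def test_nj_recovers_four_taxon_additive_tree_exactly():
    # tree ((A:2,B:3):1,(C:4,D:5)) → additive distances
    names = ["A", "B", "C", "D"]
    d = [[0, 5, 7, 8],
         [5, 0, 8, 9],
         [7, 8, 0, 9],
         [8, 9, 0, 0]]
    d[3][2] = 9
    tree = nj_tree(names, d)
    ok, _ = is_monophyletic(tree, {"A", "B"})
    assert ok
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0})


def test_nj_three_leaf_star_resolution():
    tree = nj_tree(["A", "B", "C"], [[0, 2, 3], [2, 0, 3], [3, 3, 0]])
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})


def _random_additive(n, seed):
    """Random binary tree with positive lengths; returns (names, dist, tree)."""
    rng = random.Random(seed)
    names = [f"t{i}" for i in range(n)]
    newick_of = dict(enumerate(names))
    nodes = list(range(n))
    nid = n
    while len(nodes) > 2:
        i, j = rng.sample(nodes, 2)
        bi, bj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        newick_of[nid] = f"({newick_of[i]}:{bi:.6f},{newick_of[j]}:{bj:.6f})"
        nodes = [k for k in nodes if k not in (i, j)] + [nid]
        nid += 1
    i, j = nodes
    b = rng.uniform(0.1, 2.0)
    newick = f"({newick_of[i]}:{b:.6f},{newick_of[j]}:0.0);"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dist = [[pdm.distance(taxa[a], taxa[b_]) for b_ in names] for a in names]
    return names, dist, tree


@pytest.mark.parametrize("n", [5, 8, 10])
def test_nj_exact_on_random_additive_matrices(n):
    for seed in range(3):
        names, dist, true_tree = _random_additive(n, 100 * n + seed)
        est = nj_tree(names, dist)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=true_tree.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t2 = dendropy.Tree.get(data=est.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0


def test_nj_matches_independent_implementation():
    """Cross-check against scikit-bio's neighbor joining on an additive
    matrix, where both must recover the same topology."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    names, dist, _ = _random_additive(7, 42)
    ours = nj_tree(names, dist)
    theirs = skbio_nj(DistanceMatrix(dist, names))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=ours.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=str(theirs).replace("root", ""),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_newick_roundtrip_preserves_lengths():
    names, dist, _ = _random_additive(6, 9)
    tree = nj_tree(names, dist)
    text = tree.as_string(schema="newick")
    back = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    a = sorted((l.taxon.label, l.edge.length) for l in tree.leaf_node_iter())
    b = sorted((l.taxon.label, l.edge.length) for l in back.leaf_node_iter())
    for (n1, l1), (n2, l2) in zip(a, b):
        assert n1 == n2 and abs(l1 - l2) < 1e-9


def test_monophyly_simple_cases():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                             schema="newick", preserve_underscores=True)
    assert is_monophyletic(tree, {"A", "B"})[0]
    assert not is_monophyletic(tree, {"A", "C"})[0]
    with pytest.raises(KeyError):
        is_monophyletic(tree, {"A", "Z"})


def test_monophyly_agrees_with_exhaustive_bipartition_enumeration():
    """Against an independent oracle: an unrooted clade is a subset whose
    MRCA (or its complement's MRCA) spans exactly that subset."""
    for seed in (1, 2):
        names, dist, _ = _random_additive(8, 500 + seed)
        tree = nj_tree(names, dist)

        def oracle(subset):
            other = set(names) - subset
            for s in (subset, other):
                mrca = tree.mrca(taxon_labels=sorted(s))
                leafset = {l.taxon.label for l in mrca.leaf_iter()}
                if leafset == s:
                    return True
            return False

        for r in range(2, 7):
            for subset in itertools.combinations(names, r):
                assert is_monophyletic(tree, set(subset))[0] == oracle(set(subset))


def test_exports_are_parseable(tmp_path, panel):
    sup = build_supermatrix(dict(panel.alignments), "P123R")
    phy = tmp_path / "sup.phy"
    parts = tmp_path / "parts.txt"
    write_phylip(sup.alignment, phy)
    write_partitions(sup, parts)
    header = phy.read_text().splitlines()[0].split()
    assert [int(x) for x in header] == [sup.alignment.n_rows, sup.n_cols]
    text = parts.read_text()
    assert "COX1_pos3" in text and "\\3" in text and "rrnL" in text
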