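"""Supermatrix assembly, Saitou–Nei neighbor joining, and monophyly tests.

Maximum-likelihood and Bayesian inference are deliberately delegated to
external tools: this module exports relaxed-Phylip/FASTA supermatrices and
RAxML-style partition files for them, and provides a canonical
neighbor-joining tree (deterministic lexicographic tie-breaking) plus an
unrooted monophyly test as the in-repo analysis surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy

from .divergence import Alignment

PCG_ORDER = ("ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
             "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1")
RRNA_ORDER = ("rrnL", "rrnS")
VARIANTS = ("P123R", "P123", "P12R", "P12")


class FrameError(ValueError):
    pass


@dataclass
class Supermatrix:
    alignment: Alignment
    variant: str
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols


def build_supermatrix(gene_alignments: dict[str, Alignment],
                      variant: str = "P123R") -> Supermatrix:
    """Concatenate gene alignments into one of the four dataset variants.

    P123R = 13 PCGs + 2 rRNAs; P123 = PCGs only; P12R/P12 drop every third
    codon position of the PCG partitions.  Taxa missing from a gene are
    padded with gaps.  Genes are concatenated in a fixed canonical order.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    with_rrna = variant.endswith("R")
    drop_third = variant in ("P12", "P12R")
    genes = [g for g in PCG_ORDER if g in gene_alignments]
    if with_rrna:
        genes += [g for g in RRNA_ORDER if g in gene_alignments]
    if not genes:
        raise ValueError("no usable gene alignments")
    taxa = sorted({n for g in genes for n in gene_alignments[g].names})
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for g in genes:
        aln = gene_alignments[g]
        is_pcg = g in PCG_ORDER
        if is_pcg and drop_third:
            if not aln.is_codon:
                raise FrameError(f"{g}: P12 variants need a codon alignment")
            cols = [i for i in range(aln.n_cols) if i % 3 != 2]
            aln = aln.take_columns(cols)
        width = aln.n_cols
        for t in taxa:
            parts[t].append(aln.row(t) if t in aln.names else "-" * width)
        partitions[g] = (offset, offset + width)
        offset += width
    rows = ["".join(parts[t]) for t in taxa]
    sup = Alignment(taxa, rows, is_codon=False, partitions=partitions)
    return Supermatrix(alignment=sup, variant=variant, partitions=partitions)


def write_phylip(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{aln.n_rows} {aln.n_cols}\n")
        for name, row in zip(aln.names, aln.rows):
            fh.write(f"{name}  {row}\n")


def write_partitions(sup: Supermatrix, path) -> None:
    """RAxML-style partition file; PCG partitions get codon sub-partitions
    (``GENE = start-end\\3``) in P123-style variants."""
    codon_split = sup.variant in ("P123R", "P123")
    with open(path, "w") as fh:
        for gene, (s, e) in sup.partitions.items():
            if gene in PCG_ORDER and codon_split:
                for k in range(3):
                    fh.write(f"DNA, {gene}_pos{k + 1} = {s + 1 + k}-{e}\\3\n")
            else:
                fh.write(f"DNA, {gene} = {s + 1}-{e}\n")


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(names: list[str], dist) -> dendropy.Tree:
    """Canonical Saitou–Nei neighbor joining.

    ``dist`` is a symmetric matrix (sequence of rows) with zero diagonal.
    Ties in the Q criterion break on the lexicographically smallest taxon-name
    pair, making the topology deterministic.  Negative branch-length estimates
    are clamped to zero.  For n < 3 a trivial tree is returned.
    """
    n = len(names)
    d = {frozenset((i, j)): float(dist[i][j])
         for i in range(n) for j in range(i + 1, n)}
    for i in range(n):
        if abs(float(dist[i][i])) > 1e-12:
            raise ValueError("nonzero diagonal")
    for key, v in d.items():
        if v < 0:
            raise ValueError("negative distances")
    newick_of = {i: names[i] for i in range(n)}
    label_of = {i: names[i] for i in range(n)}   # lexicographic tie-break key
    active = list(range(n))
    next_id = n
    if n < 3:
        if n == 1:
            return dendropy.Tree.get(data=f"({names[0]});", schema="newick", preserve_underscores=True)
        blen = d[frozenset((0, 1))] / 2
        return dendropy.Tree.get(
            data=f"({names[0]}:{blen:.10g},{names[1]}:{blen:.10g});",
            schema="newick", preserve_underscores=True)
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[frozenset((i, j))] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[frozenset((i, j))] - r[i] - r[j]
            tie = tuple(sorted((label_of[i], label_of[j])))
            if best is None or (q, tie) < (best[0], best[1]):
                best = (q, tie, i, j)
        _, _, i, j = best
        dij = d[frozenset((i, j))]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        newick_of[u] = (f"({newick_of[i]}:{li:.10g},{newick_of[j]}:{lj:.10g})")
        label_of[u] = min(label_of[i], label_of[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[frozenset((i, k))] + d[frozenset((j, k))] - dij)
            d[frozenset((u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    dij, dik, djk = (d[frozenset((i, j))], d[frozenset((i, k))],
                     d[frozenset((j, k))])
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    newick = (f"({newick_of[i]}:{li:.10g},{newick_of[j]}:{lj:.10g},"
              f"{newick_of[k]}:{lk:.10g});")
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def distance_matrix(aln: Alignment, model: str = "K2P"):
    """Pairwise distance matrix over alignment rows (names, matrix)."""
    from .divergence import pairwise_distance
    n = aln.n_rows
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i][j] = mat[j][i] = pairwise_distance(aln.rows[i], aln.rows[j], model)
    return aln.names, mat


# ---------------------------------------------------------------------------
# Monophyly

def _bipartitions(tree: dendropy.Tree):
    """Leaf-set bipartitions induced by internal edges of an unrooted tree."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 0 < len(side) < len(leaves):
            yield side, leaves - side


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]
                    ) -> tuple[bool, tuple[frozenset, frozenset] | None]:
    """Whether ``taxa`` form a clade of the unrooted tree, i.e. some edge
    bipartition separates exactly ``taxa`` from the rest.  Returns the
    defining bipartition when true.  Singleton and full sets are trivially
    monophyletic."""
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if not taxa <= leaves:
        raise KeyError(f"taxa not in tree: {sorted(set(taxa) - leaves)}")
    target = frozenset(taxa)
    if len(target) in (1, len(leaves)):
        return True, (target, frozenset(leaves) - target)
    for side, other in _bipartitions(tree):
        if side == target or other == target:
            return True, (target, frozenset(leaves) - target)
    return False, None
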