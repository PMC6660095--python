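"""Per-window trees, concordance with a genome tree, and clade recovery.

Window trees are built by neighbor joining from the same missing-data-aware
pairwise genotype distances that drive pi and d_xy; externally inferred
newick trees can be supplied instead.  Concordance between two trees is the
Pearson correlation of their tip-to-tip patristic (cophenetic) distance
matrices, so it is invariant to overall branch-length scale.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from mimland.genomic_io import GenotypeMatrix, WindowSpec
from mimland.window_stats import pairwise_mismatch

__all__ = [
    "nj_tree",
    "window_tree",
    "cophenetic_matrix",
    "concordance_score",
    "clade_recovery",
    "root_on_outgroup",
]


def nj_tree(
    distances: np.ndarray,
    labels: list[str],
    outgroup_tips: list[str] | None = None,
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Negative NJ branch lengths are clamped to zero.  When ``outgroup_tips``
    is given the tree is rooted on that group (see `root_on_outgroup`).
    """
    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=list(labels))
    sk = nj(dm)
    for node in sk.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    sk.write(buf)
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    if outgroup_tips:
        tree = root_on_outgroup(tree, outgroup_tips)
    return tree


def window_tree(
    matrix: GenotypeMatrix,
    window: WindowSpec,
    outgroup_tips: list[str] | None = None,
) -> dendropy.Tree | None:
    """NJ tree over individuals from one window's genotype distances.

    Returns None (with a warning) when fewer than 4 individuals carry data
    or when some pair of individuals shares no genotyped site.
    """
    sl = matrix.site_slice(window.chrom, window.start, window.end)
    dos = matrix.dosage()[sl]
    with_data = np.flatnonzero(np.isfinite(dos).any(axis=0))
    if len(with_data) < 4:
        warnings.warn(f"window {window.label}: fewer than 4 individuals with data")
        return None
    dos = dos[:, with_data]
    m, j = pairwise_mismatch(dos)
    off_diag = ~np.eye(len(with_data), dtype=bool)
    if np.any(j[off_diag] == 0):
        warnings.warn(f"window {window.label}: pair with zero joint sites, skipped")
        return None
    d = m / np.maximum(j, 1)
    np.fill_diagonal(d, 0.0)
    labels = [matrix.individuals[i] for i in with_data]
    og = None
    if outgroup_tips is not None:
        og = [t for t in outgroup_tips if t in labels]
    return nj_tree(d, labels, og or None)


def _leaf_labels(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def root_on_outgroup(tree: dendropy.Tree, outgroup_tips: list[str]) -> dendropy.Tree:
    """Root a tree on the given outgroup tip set.

    If the outgroup is not monophyletic in the unrooted tree, the tree is
    rooted on the edge whose bipartition best agrees with the outgroup
    split (maximal tip-set agreement) and annotated with
    ``outgroup_conflict = True``.
    """
    og = set(outgroup_tips)
    all_tips = _leaf_labels(tree.seed_node)
    if not og <= all_tips:
        raise ValueError(f"outgroup tips absent from tree: {sorted(og - all_tips)}")
    best_node, best_score = None, -1
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = _leaf_labels(node)
        other = all_tips - side
        # agreement of this bipartition with the outgroup split
        score = max(
            len(og & side) - len(side - og),
            len(og & other) - len(other - og),
        )
        if score > best_score:
            best_node, best_score = node, score
    exact = _leaf_labels(best_node) == og or _leaf_labels(best_node) == all_tips - og
    tree.to_outgroup_position(best_node, update_bipartitions=False)
    tree.annotations.add_new("outgroup_conflict", not exact)
    return tree


def cophenetic_matrix(tree: dendropy.Tree, labels: list[str] | None = None):
    """Tip-to-tip patristic distance matrix in a fixed label order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if labels is None:
        labels = sorted(taxa)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[k]])
            out[i, k] = out[k, i] = d
    return out, labels


def concordance_score(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> float:
    """Pearson correlation of the two trees' cophenetic matrices.

    A higher score means a window tree more similar to the genome tree.
    NaN when either matrix has zero variance (e.g. a star tree) or the
    tip sets differ.
    """
    labels_a = sorted(_leaf_labels(tree_a.seed_node))
    labels_b = sorted(_leaf_labels(tree_b.seed_node))
    if labels_a != labels_b:
        raise ValueError("trees have different tip sets")
    ma, _ = cophenetic_matrix(tree_a, labels_a)
    mb, _ = cophenetic_matrix(tree_b, labels_a)
    iu = np.triu_indices(len(labels_a), k=1)
    xa, xb = ma[iu], mb[iu]
    if xa.std() == 0 or xb.std() == 0:
        return np.nan
    return float(np.corrcoef(xa, xb)[0, 1])


def clade_recovery(
    trees: list[dendropy.Tree],
    clade: set[str],
    outgroup_tips: set[str] | None = None,
) -> float:
    """Fraction of trees in which ``clade`` is monophyletic.

    Trees are assumed rooted (e.g. via `root_on_outgroup`).  A singleton
    clade, or one containing outgroup tips, is an error.
    """
    clade = set(clade)
    if len(clade) < 2:
        raise ValueError("clade must contain at least 2 tips")
    if outgroup_tips and clade & set(outgroup_tips):
        raise ValueError("clade must not contain outgroup tips")
    hits = 0
    for tree in trees:
        if not tree.is_rooted:
            tree.is_rooted = True
        tree.encode_bipartitions()
        taxa = [t for t in tree.taxon_namespace if t.label in clade]
        if len(taxa) != len(clade):
            raise ValueError("clade tips absent from a tree")
        mrca = tree.mrca(taxa=taxa)
        if _leaf_labels(mrca) == clade:
            hits += 1
    return hits / len(trees)
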