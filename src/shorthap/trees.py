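"""Neighbor-Joining tree construction with bootstrap bipartition support.

Trees are :class:`dendropy.Tree` objects (unrooted; the seed node is the
final trifurcation), which provides Newick serialization and bipartition
encoding. The agglomeration itself is the classical Saitou–Nei algorithm:
repeatedly join the pair minimizing the Q-criterion, assign branch lengths
with the two-point formulas, and reduce the matrix. Ties on Q are broken by
the lexicographically smallest pair of current node indices, so results are
reproducible. Negative branch lengths are clamped to zero and the clamped
amount logged.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from shorthap.relatedness import DistanceMatrix

logger = logging.getLogger(__name__)


def nj(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei Neighbor-Joining on a symmetric distance matrix."""
    d = np.array(matrix.values, dtype=float)
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("NJ requires at least 3 samples")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")

    taxa = dendropy.TaxonNamespace(matrix.samples)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in matrix.samples:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)

    clamped = 0.0

    def _edge_len(v: float) -> float:
        nonlocal clamped
        if v < 0:
            clamped += -v
            return 0.0
        return float(v)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographic tie-break over (i, j), i < j in current order
        best = None
        qmin = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < qmin - 1e-12:
                    qmin = q[i, j]
                    best = (i, j)
        i, j = best
        gi, gj = active[i], active[j]
        dij = d[gi, gj]
        vi = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        ni, nj_ = nodes[gi], nodes[gj]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = _edge_len(vi)
        nj_.edge.length = _edge_len(vj)
        # reduce: replace node i by parent, drop node j
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        gp = d.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [gp]

    # final trifurcation
    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = tree.seed_node
    for g, v in zip((i, j, k), (vi, vj, vk)):
        root.add_child(nodes[g])
        nodes[g].edge.length = _edge_len(v)
    tree.is_rooted = False
    if clamped > 0:
        logger.info("clamped %.6g of negative NJ branch length to 0", clamped)
    return tree


def bootstrap_support(main: dendropy.Tree,
                      replicates: list[dendropy.Tree]) -> dendropy.Tree:
    """Annotate each internal edge of ``main`` with the percentage of
    replicate trees containing the same leaf bipartition (topology only)."""
    taxa = main.taxon_namespace
    main_leaves = {t.label for t in taxa if t is not None}
    rep_splits = []
    for rep in replicates:
        rep_leaves = {lf.taxon.label for lf in rep.leaf_node_iter()}
        if rep_leaves != main_leaves:
            raise ValueError("replicate tree has a different leaf set")
        rep_splits.append(_split_set(rep, taxa))
    main.encode_bipartitions()
    for node in main.preorder_node_iter():
        if node.is_leaf() or node is main.seed_node:
            continue
        split = _normalize_split(node.edge.bipartition.leafset_bitmask, taxa)
        count = sum(split in s for s in rep_splits)
        node.label = f"{100.0 * count / len(rep_splits):g}"
    return main


def _normalize_split(bitmask: int, taxa: dendropy.TaxonNamespace) -> int:
    full = (1 << len(taxa)) - 1
    comp = bitmask ^ full
    return min(bitmask, comp)


def _split_set(tree: dendropy.Tree, taxa: dendropy.TaxonNamespace) -> set[int]:
    if tree.taxon_namespace is not taxa:
        tree.migrate_taxon_namespace(taxa)
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node is tree.seed_node:
            continue
        out.add(_normalize_split(edge.bipartition.leafset_bitmask, taxa))
    return out


def species_split_support(tree: dendropy.Tree, group: set[str]) -> float | None:
    """Support of the edge whose bipartition separates ``group`` from the
    rest of the leaves, or None if the tree lacks that split."""
    taxa = tree.taxon_namespace
    mask = 0
    for idx, taxon in enumerate(taxa):
        if taxon.label in group:
            mask |= 1 << idx
    target = _normalize_split(mask, taxa)
    tree.encode_bipartitions()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        if _normalize_split(node.edge.bipartition.leafset_bitmask, taxa) == target:
            return float(node.label) if node.label else None
    return None


def write_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths; supports as internal node labels."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    if not text.strip():
        raise ValueError("empty Newick string")
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree
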