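"""Allele-sharing distances and midpoint-rooted neighbour-joining trees.

The between-individual distance is the conventional genotype
(identity-by-state) distance: per site both genotypes are compared and the
number of shared alleles counted (identical homozygotes 2, het vs het 2,
het vs either homozygote 1, opposite homozygotes 0); the distance is
``1 − shared / (2 · sites compared)``, in [0, 1].  Sites where either
sample is missing are skipped.

Neighbour joining follows the standard Q-matrix agglomeration and is exact
on additive matrices.  Ties in the Q minimisation are broken toward the
lowest (row, column) pair in current node order, making the output
deterministic.  Negative branch-length estimates are clamped to zero with
the deficit absorbed by the sibling branch, preserving the pair's summed
length.  Trees are dendropy objects; midpoint rooting places the root
halfway along the longest leaf-to-leaf path.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from .vcf_io import GT_MISSING, VariantTable


def allele_sharing_distance(table: VariantTable, sample_a: str, sample_b: str) -> float:
    """1 − IBS allele-sharing proportion between two samples."""
    ga, gb = table.gt(sample_a), table.gt(sample_b)
    ok = (ga != GT_MISSING) & (gb != GT_MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no comparable sites between {sample_a!r} and {sample_b!r}")
    shared = 2 - np.abs(ga[ok].astype(np.int64) - gb[ok].astype(np.int64))
    return float(1.0 - shared.sum() / (2.0 * n))


def distance_matrix(table: VariantTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise allele-sharing distances and per-pair compared-site counts."""
    samples = table.samples
    gm = table.gt_matrix().astype(np.int64)
    k = len(samples)
    dist = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        counts[i, i] = int((gm[:, i] != GT_MISSING).sum())
        for j in range(i + 1, k):
            ok = (gm[:, i] != GT_MISSING) & (gm[:, j] != GT_MISSING)
            n = int(ok.sum())
            if n == 0:
                raise ValueError(f"no comparable sites between {samples[i]!r} and {samples[j]!r}")
            shared = (2 - np.abs(gm[ok, i] - gm[ok, j])).sum()
            dist[i, j] = dist[j, i] = 1.0 - shared / (2.0 * n)
            counts[i, j] = counts[j, i] = n
    return (
        pd.DataFrame(dist, index=samples, columns=samples),
        pd.DataFrame(counts, index=samples, columns=samples),
    )


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbour-joining tree from a symmetric labelled distance matrix.

    Deterministic (lowest-index tie-break); exact on additive matrices.
    Returns an unrooted dendropy tree (trifurcating seed node).
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    if list(dist.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    ns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=ns.get_taxon(lab)) for lab in labels]
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) on ties: argmin scans row-major
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:  # clamp, deficit absorbed by sibling
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        # distances from the new node to every other active node
        new_row = np.full(d.shape[0] + 1, np.nan)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=np.nan)
        d[-1, :] = new_row
        d[:, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j = active
    # root at the internal node (the later-created one)
    if len(nodes[j].child_nodes()) == 0:
        i, j = j, i
    nodes[j].add_child(nodes[i])
    nodes[i].edge.length = max(d[i, j], 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[j])
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path."""
    total = sum(e.length or 0.0 for e in tree.edges())
    if total <= 0:
        warnings.warn("tree has zero total branch length; rooting at an arbitrary internal node")
        tree.is_rooted = True
        return tree
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-leaf path lengths, by taxon label."""
    out = {}
    for leaf in tree.leaf_node_iter():
        dist = 0.0
        node = leaf
        while node.parent_node is not None:
            dist += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = dist
    return out


def has_clade(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True when ``labels`` form a clade (a bipartition of the unrooted tree)."""
    all_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not labels <= all_labels:
        raise ValueError("labels not all present in tree")
    complement = all_labels - labels
    tree.encode_bipartitions()
    for edge in tree.edges():
        side = {
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        }
        if side == labels or side == complement:
            return True
    return False
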