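"""Host-phylogeny utilities.

Patristic distances and the Brownian-motion covariance matrix among host
species, the two quantities the mixed-model and feedback analyses consume.
Trees are handled as :class:`dendropy.Tree` objects read from Newick; tip
labels are canonicalised so that underscores and spaces are interchangeable
(the Phylomatic/Newick convention).
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "canonical_label",
    "patristic_distances",
    "phylo_covariance",
]


def canonical_label(name: str) -> str:
    """Canonical species label: trimmed, spaces folded to underscores."""
    return name.strip().replace(" ", "_")


def read_newick(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string.

    The tree is forced rooted at the basal node (the study's trees are
    consumed as rooted); underscores in labels are preserved verbatim.
    """
    data = source
    if "(" not in source:  # a path, not a Newick string
        with open(source) as fh:
            data = fh.read()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = canonical_label(leaf.taxon.label)
    return tree


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise sum of branch lengths along tip-to-tip paths.

    Returns a symmetric DataFrame indexed by tip label with a zero diagonal.
    """
    _check_branch_lengths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def phylo_covariance(tree: dendropy.Tree, scale: str = "mean_diag") -> pd.DataFrame:
    """Brownian-motion covariance among tips.

    C[i, j] is the shared path length from the root to the most recent
    common ancestor of tips i and j; C[i, i] is the root-to-tip depth.
    With ``scale="mean_diag"`` (default) the matrix is rescaled so the mean
    diagonal entry is 1, making the phylogenetic variance component of the
    mixed model comparable across trees; ``scale="none"`` returns raw path
    lengths.
    """
    if not tree.is_rooted:
        raise ValueError(
            "phylo_covariance requires a rooted tree; midpoint-root upstream"
        )
    _check_branch_lengths(tree)
    labels = sorted(tip_labels(tree))
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    # Single preorder pass: depth of each node from the root; the MRCA of
    # any two tips drawn from different child subtrees of a node is that
    # node, so its depth fills the corresponding off-diagonal block.
    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    leafset: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = [idx[node.taxon.label]]
            C[idx[node.taxon.label], idx[node.taxon.label]] = depth[node]
        else:
            children = [leafset[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            leafset[node] = [i for ch in children for i in ch]

    if scale == "mean_diag":
        m = np.diag(C).mean()
        if m <= 0:
            raise ValueError("tree has zero total depth")
        C = C / m
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    return pd.DataFrame(C, index=labels, columns=labels)


def tree_to_newick(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return buf.getvalue().strip()
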