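"""Phylogenetic trees and pairwise patristic distances.

Distances are reported in the branch-length units of the input tree (for a
16S tree, substitutions per site) and are root-independent: the patristic
distance between two leaves is the sum of branch lengths along the unique
path connecting them.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd

__all__ = ["parse_newick", "patristic_distances", "read_tree"]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; leaf labels must be unique, all edges measured.

    Internal node labels are tolerated and ignored downstream.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise ValueError("tree contains unlabeled leaves")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise ValueError(f"missing branch length on the edge above {where}")
        if node.edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_tree(path: str) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric leaf-to-leaf path-length matrix with zero diagonal."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    d = np.zeros((len(taxa), len(taxa)))
    for (i, ta), (j, tb) in itertools.combinations(enumerate(taxa), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(ta, tb)
    return pd.DataFrame(d, index=labels, columns=labels)
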