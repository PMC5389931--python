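"""Small shared helpers over dendropy trees.

Trees throughout the package are rooted dendropy Trees with unique leaf labels
and non-negative branch lengths. Missing branch lengths are treated as 0.
"""

from __future__ import annotations

from typing import Iterable

import dendropy


def read_newick(source: str, from_path: bool = True) -> dendropy.Tree:
    """Load a rooted tree from Newick (path or literal string)."""
    kwargs = {"path" if from_path else "data": source}
    tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", unquoted_underscores=True)


def leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label or ""


def leaf_labels(tree_or_node) -> list[str]:
    if isinstance(tree_or_node, dendropy.Tree):
        it = tree_or_node.leaf_node_iter()
    else:
        it = tree_or_node.leaf_iter()
    return [leaf_label(n) for n in it]


def edge_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def validate_tree(tree: dendropy.Tree) -> None:
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes[:5]}")
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and edge_length(node) < 0:
            raise ValueError("negative branch length")


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance of every node from the root, along branch lengths."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + edge_length(node)
    return depths


def ancestors(node: dendropy.Node) -> list[dendropy.Node]:
    out = [node]
    while node.parent_node is not None:
        node = node.parent_node
        out.append(node)
    return out


def lca(u: dendropy.Node, v: dendropy.Node) -> dendropy.Node:
    seen = set(id(a) for a in ancestors(u))
    for a in ancestors(v):
        if id(a) in seen:
            return a
    raise ValueError("nodes are not in the same tree")


def patristic_distance(u: dendropy.Node, v: dendropy.Node,
                       depths: dict[dendropy.Node, float]) -> float:
    return depths[u] + depths[v] - 2.0 * depths[lca(u, v)]


def brute_force_leaf_distances(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """All pairwise leaf patristic distances by explicit path sums (test oracle)."""
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    out: dict[frozenset[str], float] = {}
    for i, u in enumerate(leaves):
        for v in leaves[i + 1:]:
            out[frozenset((leaf_label(u), leaf_label(v)))] = patristic_distance(
                u, v, depths)
    return out


def preorder_index(tree: dendropy.Tree) -> dict[dendropy.Node, int]:
    return {node: i for i, node in enumerate(tree.preorder_node_iter())}


def iter_leaf_sets(nodes: Iterable[dendropy.Node]) -> list[frozenset[str]]:
    return [frozenset(leaf_labels(n)) for n in nodes]
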