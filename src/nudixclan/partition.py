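"""Patristic-distance tree partitioning for divide-and-conquer alignment.

Very large protein families cannot be aligned in one shot; a practical route
is to cut the guide tree into clades of manageable size, align each clade
separately, and merge the sub-alignments on a shared core. The cutting rule
here descends from Prosperi-style patristic clustering: a clade qualifies as
a cluster when its mean pairwise leaf distance falls below a low percentile
of the whole-tree pairwise-distance distribution.

Two refinements make this workable at scale:

* per-clade mean pairwise distances are computed exactly in one linear
  post-order pass via the (leaf count, leaf-path-sum) recurrence, so no
  O(n^2) distance matrix is ever formed;
* the whole-tree distribution is represented as the pair-count-weighted
  multiset of per-node cross-pair means (every leaf pair contributes once,
  at its lowest common ancestor), from which the percentile threshold is
  taken with linear interpolation.

Size bounds are then enforced: oversized clades are split at their root,
undersized ones merged into their nearest neighbouring clade when possible,
and otherwise pooled into a single leftover group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .trees import (
    edge_length,
    leaf_label,
    leaf_labels,
    lca,
    node_depths,
    preorder_index,
)

LEFTOVER_GROUP = "UNCLUSTERED_POOL"


@dataclass(frozen=True)
class NodeStats:
    """Per-node leaf-distance summaries from the post-order recurrence.

    ``leaf_path_sum`` is the summed distance from the node to each descendant
    leaf; ``cross_pair_count``/``cross_pair_mean`` describe the leaf pairs
    whose lowest common ancestor is this node.
    """

    n_leaves: int
    leaf_path_sum: float
    cross_pair_count: int
    cross_pair_mean: float


@dataclass(frozen=True)
class PartitionConfig:
    percentile: float = 0.05
    min_size: int = 400
    max_size: int = 4000

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must lie in (0, 1)")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")


@dataclass
class Partition:
    """Disjoint leaf-set clades within size bounds, plus a leftover pool."""

    clades: list[frozenset[str]]
    leftover: frozenset[str]

    def validate(self, all_leaves: frozenset[str], config: PartitionConfig) -> None:
        covered: set[str] = set()
        for clade in self.clades:
            if covered & clade:
                raise AssertionError("clades are not disjoint")
            covered |= clade
            if not config.min_size <= len(clade) <= config.max_size:
                raise AssertionError("clade size out of bounds")
        if covered & self.leftover:
            raise AssertionError("leftover overlaps clades")
        if covered | self.leftover != all_leaves:
            raise AssertionError("partition does not cover the leaf set")


def compute_node_stats(tree: dendropy.Tree) -> dict[dendropy.Node, NodeStats]:
    """Exact per-node mean cross-pair patristic distance, in one post-order pass.

    For a node with children c_i carrying (n_i, S_i) — leaf count and summed
    leaf distance to c_i — the distances from leaves under c_i up to this node
    sum to A_i = S_i + n_i * len(edge to c_i). Pairs joined at this node
    contribute sum_{i<j} (n_j A_i + n_i A_j) over n_i n_j pairs.
    """
    stats: dict[dendropy.Node, NodeStats] = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            stats[node] = NodeStats(1, 0.0, 0, 0.0)
            continue
        ns, As = [], []
        for child in children:
            cs = stats[child]
            ns.append(cs.n_leaves)
            As.append(cs.leaf_path_sum + cs.n_leaves * edge_length(child))
        n_total = sum(ns)
        path_sum = sum(As)
        # cross terms via prefix accumulation: O(#children)
        pair_count = 0
        dist_sum = 0.0
        acc_n, acc_A = 0, 0.0
        for n_i, A_i in zip(ns, As):
            pair_count += acc_n * n_i
            dist_sum += acc_n * A_i + acc_A * n_i
            acc_n += n_i
            acc_A += A_i
        mean = dist_sum / pair_count if pair_count else 0.0
        stats[node] = NodeStats(n_total, path_sum, pair_count, mean)
    return stats


def whole_tree_threshold(stats: dict[dendropy.Node, NodeStats],
                         percentile: float) -> float:
    """Weighted percentile of the approximate whole-tree distance distribution.

    The distribution is the multiset in which each internal node's cross-pair
    mean appears once per leaf pair joined at that node. The p-th percentile
    is defined to agree exactly with numpy's linear-interpolation percentile
    of the expanded flat list, but is computed from cumulative pair counts
    without expansion.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must lie in (0, 1]")
    weighted = sorted(
        (s.cross_pair_mean, s.cross_pair_count)
        for s in stats.values() if s.cross_pair_count > 0
    )
    total = sum(c for _, c in weighted)
    if total == 0:
        raise ValueError("tree must have at least two leaves")
    # virtual index into the expanded sorted list of length `total`
    pos = percentile * (total - 1)
    lo_idx = int(pos)
    frac = pos - lo_idx

    def value_at(k: int) -> float:
        cum = 0
        for mean, count in weighted:
            cum += count
            if k < cum:
                return mean
        return weighted[-1][0]

    lo = value_at(lo_idx)
    if frac == 0.0:
        return lo
    hi = value_at(lo_idx + 1)
    return lo + frac * (hi - lo)


def initial_clusters(tree: dendropy.Tree, threshold: float,
                     stats: dict[dendropy.Node, NodeStats] | None = None,
                     ) -> list[dendropy.Node]:
    """Maximal (root-most) clades whose mean cross-pair distance < threshold.

    Pre-order descent that does not enter a qualifying clade; leaves on their
    own never qualify (they contain no pairs).
    """
    if stats is None:
        stats = compute_node_stats(tree)
    clusters: list[dendropy.Node] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        s = stats[node]
        if s.cross_pair_count > 0 and s.cross_pair_mean < threshold:
            clusters.append(node)
            continue
        stack.extend(reversed(node.child_nodes()))
    return clusters


@dataclass
class _Clade:
    node: dendropy.Node          # representative node (LCA of the leaves)
    leaves: frozenset[str]
    members: list[dendropy.Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.node]

    @property
    def size(self) -> int:
        return len(self.leaves)

    @property
    def min_leaf(self) -> str:
        return min(self.leaves)


def enforce_size_bounds(tree: dendropy.Tree, clusters: list[dendropy.Node],
                        config: PartitionConfig) -> Partition:
    """Split oversized clades at their root, merge undersized ones, pool the rest.

    Oversized clades are replaced by their children, recursively, until every
    piece fits under ``max_size`` (a polytomy splits into all children at
    once). Each undersized clade is then merged with its adjacent clade — the
    nearest other clade by patristic distance between representative nodes,
    preferring siblings, with ties broken by smaller size then smallest leaf
    label — provided the merge stays within ``max_size``; otherwise its
    leaves join the leftover pool.
    """
    depths = node_depths(tree)
    order = preorder_index(tree)

    # 1. split oversized clades
    pieces: list[dendropy.Node] = []
    stack = list(clusters)
    while stack:
        node = stack.pop()
        if len(node.leaf_nodes()) > config.max_size:
            children = node.child_nodes()
            if not children:
                raise AssertionError("leaf exceeds max_size")
            stack.extend(children)
        else:
            pieces.append(node)
    pieces.sort(key=lambda n: order[n])
    clades = [_Clade(n, frozenset(leaf_labels(n))) for n in pieces]

    # 2. merge undersized clades with their adjacent clade
    leftover: set[str] = set()
    while True:
        small = [c for c in clades if c.size < config.min_size]
        if not small:
            break
        clade = min(small, key=lambda c: (c.size, c.min_leaf))
        clades.remove(clade)
        if not clades:
            leftover |= clade.leaves
            continue

        def rank(other: _Clade) -> tuple:
            dist = (depths[clade.node] + depths[other.node]
                    - 2.0 * depths[lca(clade.node, other.node)])
            sibling = clade.node.parent_node is other.node.parent_node
            return (dist, not sibling, other.size, other.min_leaf)

        adjacent = min(clades, key=rank)
        if clade.size + adjacent.size <= config.max_size:
            adjacent.leaves = adjacent.leaves | clade.leaves
            adjacent.members = adjacent.members + clade.members
            adjacent.node = lca(adjacent.node, clade.node)
        else:
            leftover |= clade.leaves

    clades.sort(key=lambda c: min(order[m] for m in c.members))
    return Partition([c.leaves for c in clades], frozenset(leftover))


def partition_tree(tree: dendropy.Tree,
                   config: PartitionConfig | None = None) -> Partition:
    """Full pipeline: node stats, threshold, initial clusters, size bounds.

    Deterministic for a fixed input. Leaves never assigned to a clade — from
    unclustered regions of the tree or from unmergeable small clades — are
    reported as one pooled leftover group. A tree smaller than ``min_size``
    goes entirely to the pool.
    """
    config = config or PartitionConfig()
    all_leaves = frozenset(leaf_labels(tree))
    if len(all_leaves) < max(config.min_size, 2):
        return Partition([], all_leaves)
    stats = compute_node_stats(tree)
    threshold = whole_tree_threshold(stats, config.percentile)
    clusters = initial_clusters(tree, threshold, stats)
    partition = enforce_size_bounds(tree, clusters, config)
    partition.leftover = frozenset(all_leaves - set().union(*partition.clades)
                                   if partition.clades else all_leaves)
    partition.validate(all_leaves, config)
    return partition


def partition_to_frames(partition: Partition,
                        stats_by_leafset: dict[frozenset[str], float] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leaf-to-group assignment table plus per-group summary table."""
    assign_rows, summary_rows = [], []
    for i, clade in enumerate(partition.clades):
        gid = f"G{i + 1:03d}"
        for leaf in sorted(clade):
            assign_rows.append((leaf, gid))
        mean = (stats_by_leafset or {}).get(clade, float("nan"))
        summary_rows.append((gid, len(clade), mean))
    for leaf in sorted(partition.leftover):
        assign_rows.append((leaf, LEFTOVER_GROUP))
    if partition.leftover:
        summary_rows.append((LEFTOVER_GROUP, len(partition.leftover), float("nan")))
    assignments = pd.DataFrame(assign_rows, columns=["leaf_label", "group_id"])
    summary = pd.DataFrame(summary_rows,
                           columns=["group_id", "n_leaves", "mean_within_distance"])
    return assignments, summary
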