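"""Function-on-phylogeny analysis: rooting, coherent clades, polyphyly.

Given a tree of protein domains and per-leaf annotations (domain of life plus
functions with confidence scores), this module asks the questions that drive
ancestral-function inference: which maximal clades are functionally coherent
(their characterized members share a function), do those clades span more
than one domain of life (making the function a candidate for presence in the
last universal common ancestor), and in how many independent clades does a
function appear (monophyly vs homoplasy or repeated loss)?

A leaf counts as characterized when at least one of its functions reaches the
confidence threshold (default 0.2, the point below which annotations are
treated as unlikely to reflect physiological activity; 0.5 is a stricter
"reliable" preset). Viral leaves stay in the clades but are excluded from
domain-of-life counting, since viruses cut across the cellular domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

from .trees import edge_length, leaf_label, validate_tree

logger = logging.getLogger(__name__)

DOMAINS_OF_LIFE = ("bacteria", "archaea", "eukaryota", "virus")
CELLULAR_DOMAINS = frozenset({"bacteria", "archaea", "eukaryota"})


@dataclass
class LeafAnnotation:
    """Per-leaf metadata: domain of life and scored functions.

    ``functions`` maps function_id to confidence in [0, 1]; a leaf with no
    functions is uncharacterized (e.g. present only for phylogenetic
    coverage).
    """

    leaf_id: str
    domain_of_life: str
    functions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise ValueError(f"unknown domain of life {self.domain_of_life!r}")
        for fid, score in self.functions.items():
            if not 0 <= score <= 1:
                raise ValueError(f"confidence for {fid!r} outside [0, 1]")

    def characterized_functions(self, min_confidence: float) -> set[str]:
        return {f for f, s in self.functions.items() if s >= min_confidence}


@dataclass(frozen=True)
class FunctionClade:
    """A maximal functionally coherent clade for one shared function."""

    leaf_ids: tuple[str, ...]
    function_id: str
    n_characterized: int
    n_supporting: int
    domains_present: frozenset[str]
    has_virus: bool
    classification: str  # multi_domain | single_domain

    @property
    def size(self) -> int:
        return len(self.leaf_ids)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new tree; the input is not modified. The diameter path is found
    by the two-sweep farthest-leaf method (exact on trees with non-negative
    branch lengths); ties at each sweep are broken toward the lexicographically
    smallest leaf label, making the result deterministic. After rooting, the
    two deepest root-to-leaf distances are equal to within floating-point
    round-off. A tree whose branch lengths are all zero has no midpoint and
    raises ValueError.
    """
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")

    def distances_from(start: dendropy.Node):
        dist = {start: 0.0}
        parent_of = {start: None}
        stack = [start]
        while stack:
            node = stack.pop()
            neighbours = list(node.child_nodes())
            if node.parent_node is not None:
                neighbours.append(node.parent_node)
            for nb in neighbours:
                if nb in dist:
                    continue
                step = edge_length(nb if nb.parent_node is node else node)
                dist[nb] = dist[node] + step
                parent_of[nb] = node
                stack.append(nb)
        return dist, parent_of

    def farthest_leaf(dist) -> dendropy.Node:
        return sorted(leaves, key=lambda lf: (-dist[lf], leaf_label(lf)))[0]

    start = sorted(leaves, key=leaf_label)[0]
    dist0, _ = distances_from(start)
    u = farthest_leaf(dist0)
    dist_u, parent_of = distances_from(u)
    v = farthest_leaf(dist_u)
    diameter = dist_u[v]
    if diameter <= 0:
        raise ValueError("all branch lengths are zero; midpoint undefined")

    # walk the u->v path to the midpoint
    path = [v]
    while path[-1] is not u:
        path.append(parent_of[path[-1]])
    path.reverse()  # u ... v
    half = diameter / 2.0
    cum = 0.0
    for prev, node in zip(path, path[1:]):
        step = edge_length(node if node.parent_node is prev else prev)
        if cum + step >= half:
            into = half - cum  # distance from `prev` along this tree edge
            child = node if node.parent_node is prev else prev
            # distance from the child end of the edge to the new root
            from_child = (step - into) if child is node else into
            if from_child == 0.0:
                tree.reroot_at_node(child, update_bipartitions=False,
                                    collapse_unrooted_basal_bifurcation=False)
            elif from_child == step and child.parent_node is not None:
                tree.reroot_at_node(child.parent_node, update_bipartitions=False,
                                    collapse_unrooted_basal_bifurcation=False)
            else:
                tree.reroot_at_edge(child.edge,
                                    length1=step - from_child,
                                    length2=from_child,
                                    update_bipartitions=False)
            break
        cum += step
    else:
        raise AssertionError("midpoint not found on diameter path")
    validate_tree(tree)
    return tree


def _check_annotations(tree: dendropy.Tree,
                       annotations: Mapping[str, LeafAnnotation]) -> None:
    tree_leaves = {leaf_label(lf) for lf in tree.leaf_node_iter()}
    missing = sorted(set(annotations) - tree_leaves)
    if missing:
        raise ValueError(f"annotations reference leaves absent from the tree: "
                         f"{missing[:10]}")


@dataclass
class _NodeSummary:
    n_characterized: int
    function_counts: dict[str, int]
    leaf_ids: list[str]


def _summarize(tree: dendropy.Tree, annotations: Mapping[str, LeafAnnotation],
               min_confidence: float) -> dict[dendropy.Node, _NodeSummary]:
    summaries: dict[dendropy.Node, _NodeSummary] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lid = leaf_label(node)
            ann = annotations.get(lid)
            funcs = ann.characterized_functions(min_confidence) if ann else set()
            summaries[node] = _NodeSummary(
                1 if funcs else 0, {f: 1 for f in funcs}, [lid])
            continue
        n_char = 0
        counts: dict[str, int] = {}
        leaf_ids: list[str] = []
        for child in node.child_nodes():
            cs = summaries[child]
            n_char += cs.n_characterized
            leaf_ids.extend(cs.leaf_ids)
            for f, c in cs.function_counts.items():
                counts[f] = counts.get(f, 0) + c
        summaries[node] = _NodeSummary(n_char, counts, leaf_ids)
    return summaries


def _clade_domains(leaf_ids, annotations):
    domains = set()
    has_virus = False
    for lid in leaf_ids:
        ann = annotations.get(lid)
        if ann is None:
            continue
        if ann.domain_of_life == "virus":
            has_virus = True
        else:
            domains.add(ann.domain_of_life)
    return frozenset(domains), has_virus


def find_function_clades(tree: dendropy.Tree,
                         annotations: Mapping[str, LeafAnnotation],
                         min_confidence: float = 0.2,
                         coherence_fraction: float = 1.0) -> list[FunctionClade]:
    """Maximal clades whose characterized leaves share a common function.

    A clade qualifies when it holds >= 2 characterized leaves and some
    function is carried by at least ``coherence_fraction`` of them (1.0 =
    strict agreement). Maximality: qualifying clades nested inside a larger
    qualifying clade are absorbed by it. One FunctionClade is emitted per
    (clade, shared function) pair, with domain-of-life classification over
    the clade's non-viral leaves: ``multi_domain`` when at least two cellular
    domains are present.
    """
    _check_annotations(tree, annotations)
    summaries = _summarize(tree, annotations, min_confidence)
    out: list[FunctionClade] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        s = summaries[node]
        shared = []
        if s.n_characterized >= 2:
            need = coherence_fraction * s.n_characterized - 1e-9
            shared = sorted(f for f, c in s.function_counts.items() if c >= need)
        if shared:
            domains, has_virus = _clade_domains(s.leaf_ids, annotations)
            cls = "multi_domain" if len(domains) >= 2 else "single_domain"
            for f in shared:
                out.append(FunctionClade(
                    tuple(s.leaf_ids), f, s.n_characterized,
                    s.function_counts[f], domains, has_virus, cls))
            continue
        stack.extend(reversed(node.child_nodes()))
    return out


def polyphyly_count(tree: dendropy.Tree,
                    annotations: Mapping[str, LeafAnnotation],
                    function_id: str,
                    min_confidence: float = 0.2,
                    coherence_fraction: float = 1.0) -> int:
    """Number of maximal clades coherently carrying one function.

    1 means the characterized carriers are monophyletic; >= 2 indicates
    independent origins (homoplasy) or repeated loss. Single characterized
    leaves carrying the function count as degenerate clades — a lone carrier
    elsewhere in the tree is evidence against monophyly. A function absent
    at the confidence threshold yields 0 with a warning.
    """
    _check_annotations(tree, annotations)
    summaries = _summarize(tree, annotations, min_confidence)
    root = summaries[tree.seed_node]
    if function_id not in root.function_counts:
        logger.warning("function %r not carried by any characterized leaf",
                       function_id)
        return 0
    count = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        s = summaries[node]
        carriers = s.function_counts.get(function_id, 0)
        if carriers == 0:
            continue
        need = max(coherence_fraction * s.n_characterized - 1e-9, 1.0)
        if carriers >= need:
            count += 1
            continue
        stack.extend(reversed(node.child_nodes()))
    return count


# --- tabular I/O -----------------------------------------------------------

ANNOTATION_COLUMNS = ["leaf_id", "domain_of_life", "function_id", "confidence"]


def read_annotations_tsv(path: str) -> dict[str, LeafAnnotation]:
    """Read a leaf-annotation TSV (one row per leaf-function; empty
    function_id rows declare an uncharacterized leaf's domain)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[str, LeafAnnotation] = {}
    for _, row in df.iterrows():
        lid = row["leaf_id"]
        ann = out.setdefault(lid, LeafAnnotation(lid, row["domain_of_life"]))
        fid = str(row.get("function_id", "")).strip()
        if fid:
            ann.functions[fid] = float(row["confidence"])
    return out


def write_annotations_tsv(annotations: Mapping[str, LeafAnnotation],
                          path: str) -> None:
    rows = []
    for lid in sorted(annotations):
        ann = annotations[lid]
        if not ann.functions:
            rows.append((lid, ann.domain_of_life, "", ""))
        for fid in sorted(ann.functions):
            rows.append((lid, ann.domain_of_life, fid, f"{ann.functions[fid]:.4f}"))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def clades_to_frame(clades: list[FunctionClade]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clades):
        rows.append((f"C{i + 1:03d}", c.function_id, c.n_characterized,
                     c.n_supporting, ",".join(sorted(c.domains_present)),
                     c.classification, int(c.has_virus),
                     ",".join(sorted(c.leaf_ids))))
    return pd.DataFrame(rows, columns=[
        "clade_id", "function_id", "n_characterized", "n_supporting",
        "domains", "classification", "has_virus", "leaves"])
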