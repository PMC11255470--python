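"""Rooted ultrametric tree handling and Faith phylogenetic diversity.

Trees are held as :class:`dendropy.Tree` objects (one taxon namespace per
tree, so per-tree edits such as taxon imputation never leak across trees).
Branch lengths are in millions of years (Ma) throughout. All diversity
quantities follow the Faith (1992) convention: PD of a tip set is the sum
of branch lengths of the subtree induced by those tips, rooted at their
most recent common ancestor (no stem below the MRCA); a singleton set
contributes its pendant (terminal) branch only.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "NewickError",
    "TreeSet",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tip_labels",
    "tip_depths",
    "tree_height",
    "is_ultrametric",
    "check_ultrametric",
    "total_length",
    "pd_subset",
    "terminal_branch_length",
    "root_path_length",
]

#: relative tolerance on tip depths for a tree to count as ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Raised for malformed newick input or structurally invalid trees."""


class TreeSet:
    """An ordered collection of rooted trees sharing analytical intent.

    Typically a posterior-like sample (e.g. rate-smoothed bootstrap trees)
    over the same taxon set; after imputation all member trees carry an
    identical, complete tip-label set.
    """

    def __init__(self, trees: Sequence[dendropy.Tree]):
        trees = list(trees)
        if not trees:
            raise ValueError("TreeSet requires at least one tree")
        self.trees = trees

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> dendropy.Tree:
        return self.trees[i]

    def tip_label_sets(self) -> list[set[str]]:
        return [set(tip_labels(t)) for t in self.trees]

    def common_labels(self) -> set[str]:
        sets = self.tip_label_sets()
        first = sets[0]
        for s in sets[1:]:
            if s != first:
                raise ValueError(
                    "trees do not share a tip-label set; symmetric difference "
                    f"of tree 1 vs offender: {sorted(first ^ s)[:10]}"
                )
        return first

    def as_string(self) -> str:
        return "".join(write_newick(t) for t in self.trees)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_string())


def _validate(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length is None:
            child_tips = [lf.taxon.label for lf in node.leaf_iter()][:3]
            raise NewickError(
                "missing branch length on edge above node subtending tips "
                f"{child_tips}"
            )
        if not (length >= 0.0) or length != length or length == float("inf"):
            raise NewickError(f"non-finite or negative branch length {length!r}")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")


def parse_newick(text: str) -> TreeSet:
    """Parse one or more semicolon-delimited newick statements.

    Each tree gets its own taxon namespace. Labels are preserved verbatim
    (underscores are NOT converted to spaces).
    """
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"newick parse error: {exc}") from exc
    if len(tree_list) == 0:
        raise NewickError("no trees found in input")
    trees = []
    for tree in tree_list:
        tree.migrate_taxon_namespace(
            dendropy.TaxonNamespace(), unify_taxa_by_label=True
        )
        _validate(tree)
        trees.append(tree)
    return TreeSet(trees)


def read_newick(path) -> TreeSet:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _tip_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise KeyError(f"tip label not in tree: {label!r}")


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depths[node]
    return out


def tree_height(tree: dendropy.Tree) -> float:
    """Mean root-to-tip depth (== tip depth for an ultrametric tree)."""
    d = tip_depths(tree)
    return sum(d.values()) / len(d)


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    d = list(tip_depths(tree).values())
    hi = max(d)
    if hi == 0.0:
        return True
    return (hi - min(d)) <= rtol * hi


def check_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> None:
    """Warn (not fail) on ultrametricity violations beyond tolerance.

    Rate-smoothed input trees carry numeric noise, so a violation is a
    data-quality signal rather than a hard error.
    """
    if not is_ultrametric(tree, rtol=rtol):
        d = tip_depths(tree)
        warnings.warn(
            "tree is not ultrametric within relative tolerance "
            f"{rtol:g} (tip depth range {min(d.values()):.6g}.."
            f"{max(d.values()):.6g})",
            stacklevel=2,
        )


def total_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths below the root (crown total, no root stem)."""
    return sum(
        node.edge.length
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )


def terminal_branch_length(tree: dendropy.Tree, tip: str) -> float:
    """Length of the pendant edge of ``tip``."""
    node = _tip_node(tree, tip)
    if node.parent_node is None:  # single-tip tree: the pendant edge is all there is
        return node.edge.length or 0.0
    return node.edge.length


def root_path_length(tree: dendropy.Tree, tip: str) -> float:
    """Sum of branch lengths on the path from ``tip`` to the root."""
    node = _tip_node(tree, tip)
    out = 0.0
    while node.parent_node is not None:
        out += node.edge.length
        node = node.parent_node
    return out


def pd_subset(tree: dendropy.Tree, tips: Iterable[str]) -> float:
    """Faith PD of ``tips``: branch-length sum of the MRCA-rooted induced subtree.

    A singleton set returns that tip's terminal branch length, so e.g. a
    grid cell occupied by one taxon still carries nonzero PD.
    """
    tips = set(tips)
    if not tips:
        raise ValueError("pd_subset requires a non-empty tip set")
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    unknown = sorted(tips - leaf_by_label.keys())
    if unknown:
        raise KeyError(f"tip labels not in tree: {unknown}")
    if len(tips) == 1:
        (label,) = tips
        return terminal_branch_length(tree, label)
    # MRCA = shallowest node on all root paths
    nodes = [leaf_by_label[label] for label in tips]
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])  # root .. leaf
    mrca_idx = 0
    limit = min(len(p) for p in paths)
    for i in range(limit):
        anchor = paths[0][i]
        if all(p[i] is anchor for p in paths):
            mrca_idx = i
        else:
            break
    mrca = paths[0][mrca_idx]
    # union of leaf->MRCA paths, each edge counted once
    seen: set[int] = set()
    out = 0.0
    for node in nodes:
        cur = node
        while cur is not mrca and id(cur) not in seen:
            seen.add(id(cur))
            out += cur.edge.length
            cur = cur.parent_node
    return out
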