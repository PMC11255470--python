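"""Imputation of unsampled taxa onto ultrametric trees.

EDGE-style scoring needs complete species-level trees, but molecular
phylogenies rarely sample every described taxon. Each missing taxon is
therefore grafted, at random, inside a clade designated by the analyst
(e.g. "all unsampled Cape species belong to the Cape clade"):

* the attachment branch is chosen within the clade's crown (MRCA) subtree
  with probability proportional to branch length (optionally uniform over
  branches);
* the attachment height is uniform along the chosen branch;
* the new pendant edge runs from the attachment point to the present, so
  the tree stays ultrametric.

Subspecific taxa sharing a conspecific-group key are kept monophyletic:
the first member attaches to its sampled conspecific's pendant edge (or
anywhere in the clade when none is sampled) and later members attach
within the group's own subtree. Completed group subtrees are closed to
unrelated taxa so the grouping survives subsequent insertions.

Placements are independent across trees of a set; every tree's RNG seed
is derived from a master seed and the tree's index, so a run is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import TreeSet, parse_newick, tree_height, write_newick

__all__ = [
    "CladeAssignment",
    "read_clade_assignments",
    "impute_tree",
    "impute_treeset",
]


@dataclass(frozen=True)
class CladeAssignment:
    """A taxon missing from the trees, the clade it belongs to, and an
    optional conspecific-group key (shared by subspecies of one species)."""

    taxon: str
    clade: str
    group_key: str | None = None


def read_clade_assignments(path) -> list[CladeAssignment]:
    """Read a CSV with columns taxon, clade and optional group_key."""
    df = pd.read_csv(path)
    if not {"taxon", "clade"} <= set(df.columns):
        raise ValueError("clade assignment table needs columns: taxon, clade")
    out = []
    for row in df.itertuples(index=False):
        key = getattr(row, "group_key", None)
        if key is not None and (pd.isna(key) or key == ""):
            key = None
        out.append(CladeAssignment(str(row.taxon), str(row.clade), key))
    return out


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _mrca(tree: dendropy.Tree, nodes: Sequence[dendropy.Node]) -> dendropy.Node:
    if len(nodes) == 1:
        return nodes[0]
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for i in range(min(len(p) for p in paths)):
        anchor = paths[0][i]
        if all(p[i] is anchor for p in paths):
            mrca = anchor
        else:
            break
    return mrca


def _depth(node: dendropy.Node) -> float:
    d = 0.0
    cur = node
    while cur.parent_node is not None:
        d += cur.edge.length or 0.0
        cur = cur.parent_node
    return d


def _subtree_nodes(root: dendropy.Node) -> list[dendropy.Node]:
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.child_nodes())
    return out


def _is_inside(node: dendropy.Node, ancestor: dendropy.Node) -> bool:
    cur = node
    while cur is not None:
        if cur is ancestor:
            return True
        cur = cur.parent_node
    return False


def _candidate_edges(
    clade_root: dendropy.Node,
    locked: list[dendropy.Node],
    allow_root_edge: bool,
) -> list[dendropy.Node]:
    """Attachable edges = edges within the crown subtree of ``clade_root``,
    excluding its stem (unless ``allow_root_edge``) and excluding the
    interior of locked (completed conspecific-group) subtrees. The stem of
    a locked subtree itself remains attachable."""
    out = []
    for node in _subtree_nodes(clade_root):
        if node is clade_root and not allow_root_edge:
            continue
        if node.parent_node is None:
            continue
        inside_locked = any(
            node is not lock and _is_inside(node, lock) for lock in locked
        )
        if inside_locked:
            continue
        out.append(node)
    return out


def _attach(
    tree: dendropy.Tree,
    edge_child: dendropy.Node,
    attach_depth: float,
    label: str,
    height: float,
) -> dendropy.Node:
    """Split the edge above ``edge_child`` at ``attach_depth`` (distance from
    the root) and hang a new tip reaching the present (depth ``height``)."""
    parent = edge_child.parent_node
    child_depth = _depth(edge_child)
    old_len = edge_child.edge.length or 0.0
    new_node = dendropy.Node()
    parent.remove_child(edge_child)
    parent.add_child(new_node)
    new_node.edge.length = max(attach_depth - (child_depth - old_len), 0.0)
    new_node.add_child(edge_child)
    edge_child.edge.length = max(child_depth - attach_depth, 0.0)
    taxon = tree.taxon_namespace.require_taxon(label=label)
    tip = dendropy.Node(taxon=taxon)
    new_node.add_child(tip)
    tip.edge.length = max(height - attach_depth, 0.0)
    return tip


def impute_tree(
    tree: dendropy.Tree,
    assignments: Sequence[CladeAssignment],
    clades: Mapping[str, Sequence[str]],
    seed: int | None = None,
    attachment: str = "length",
) -> dendropy.Tree:
    """Return a copy of ``tree`` with every assigned missing taxon grafted in.

    Parameters
    ----------
    tree
        Rooted ultrametric source tree (left unmodified).
    assignments
        Missing taxa with clade labels and optional conspecific-group keys.
    clades
        Clade name -> anchor tip labels; the clade is the crown subtree of
        the anchors' MRCA on this tree.
    seed
        RNG seed; placements are deterministic given it.
    attachment
        "length" (branch chosen proportional to its length, the default) or
        "uniform" (equal probability per branch).
    """
    if attachment not in ("length", "uniform"):
        raise ValueError(f"unknown attachment rule: {attachment!r}")
    if not assignments:
        return tree
    work = parse_newick(write_newick(tree))[0]
    rng = np.random.default_rng(seed)
    leaves = _leaf_map(work)

    for clade, anchors in clades.items():
        missing = [a for a in anchors if a not in leaves]
        if missing:
            raise KeyError(
                f"clade {clade!r} anchors absent from tree: {sorted(missing)}"
            )

    todo = []
    for a in assignments:
        if a.taxon in leaves:
            import warnings

            warnings.warn(
                f"taxon {a.taxon!r} already in tree; assignment skipped",
                stacklevel=2,
            )
            continue
        if a.clade not in clades:
            raise KeyError(f"assignment of {a.taxon!r} to unknown clade {a.clade!r}")
        todo.append(a)
    if not todo:
        return tree

    height = tree_height(work)

    # group into insertion units: ungrouped taxa alone, conspecific groups whole
    units: list[list[CladeAssignment]] = []
    by_key: dict[str, list[CladeAssignment]] = {}
    for a in todo:
        if a.group_key is None:
            units.append([a])
        else:
            by_key.setdefault(a.group_key, []).append(a)
    units.extend(by_key.values())
    rng.shuffle(units)

    locked: list[dendropy.Node] = []
    for unit in units:
        group_tips: list[dendropy.Node] = []
        key = unit[0].group_key
        if key is not None:
            # a sampled conspecific already on the tree joins the group
            group_tips = [
                leaf
                for label, leaf in _leaf_map(work).items()
                if _conspecific(label, key)
            ]
        for a in unit:
            leaves = _leaf_map(work)
            anchor_nodes = [leaves[x] for x in clades[a.clade]]
            clade_root = _mrca(work, anchor_nodes)
            if group_tips:
                sub_root = _mrca(work, group_tips)
                candidates = _candidate_edges(
                    sub_root, locked=locked, allow_root_edge=True
                )
            else:
                candidates = _candidate_edges(
                    clade_root, locked=locked, allow_root_edge=False
                )
            if not candidates:
                # degenerate single-anchor clade: attach on the anchor's pendant edge
                candidates = anchor_nodes
            lengths = np.array(
                [c.edge.length or 0.0 for c in candidates], dtype=float
            )
            if attachment == "length" and lengths.sum() > 0:
                probs = lengths / lengths.sum()
            else:
                probs = np.full(len(candidates), 1.0 / len(candidates))
            idx = rng.choice(len(candidates), p=probs)
            child = candidates[idx]
            child_depth = _depth(child)
            top = child_depth - (child.edge.length or 0.0)
            attach_depth = rng.uniform(top, child_depth)
            tip = _attach(work, child, attach_depth, a.taxon, height)
            if key is not None:
                group_tips.append(tip)
        if key is not None and len(group_tips) > 1:
            locked.append(_mrca(work, group_tips))
    return work


def _conspecific(label: str, key: str) -> bool:
    """A tip belongs to a conspecific group when the group key equals the
    label or appears as a whitespace/underscore-delimited token in it
    (e.g. key "trimera" matches "E_trimera_ssp_alta")."""
    if label == key:
        return True
    if label.startswith(key) and label[len(key)] in "_ ":
        return True
    tokens = label.replace("_", " ").split()
    return key in tokens


def impute_treeset(
    trees: TreeSet,
    assignments: Sequence[CladeAssignment],
    clades: Mapping[str, Sequence[str]],
    seed: int | None = None,
    attachment: str = "length",
) -> TreeSet:
    """Impute every tree independently (per-tree seed derived from the
    master seed and the tree index) and verify the trees end up sharing
    one complete tip set."""
    out = []
    for i, tree in enumerate(trees):
        sub_seed = None
        if seed is not None:
            sub_seed = np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
        out.append(
            impute_tree(tree, assignments, clades, seed=sub_seed, attachment=attachment)
        )
    result = TreeSet(out)
    result.common_labels()
    return result
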