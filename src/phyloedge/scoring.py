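"""Extinction-risk-weighted diversity: expected PD loss, ED2, EDGE2.

Let ``L_b`` be the length of branch ``b`` and ``tips(b)`` the set of tips
descending from it, each tip ``j`` carrying an independent extinction
probability ``p_j``. A branch is lost only if every tip below it goes
extinct, so

* expected PD loss of a tree:  ``ePDloss = sum_b L_b * prod_{j in tips(b)} p_j``
* evolutionary distinctiveness of tip ``i``:
  ``ED2_i = sum_{b on i's root path} L_b * prod_{j in tips(b), j != i} p_j``
  (the empty product is 1, so the pendant edge always counts in full);
  this is tip ``i``'s expected marginal contribution to surviving PD.
* ``EDGE2_i = p_i * ED2_i`` — the expected PD loss attributable to tip
  ``i`` itself; equivalently the root-path sum over the risk-weighted tree
  with branch lengths ``L'_b = L_b * prod_{j in tips(b)} p_j``.

Both identities are checked against exhaustive enumeration over all
``2^n`` extinction outcomes in the test suite.

Products over many tips are computed in log space with an exact-zero
short-circuit (a complete tree may have ~1000 terms per product).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import pandas as pd

from .extinction import PextIteration
from .trees import parse_newick, total_length, write_newick

__all__ = [
    "IterationScores",
    "expected_pd_loss",
    "ed2_scores",
    "edge2_scores",
    "weight_tree",
    "tbl_percent",
    "score_iteration",
]


def _branch_products(tree: dendropy.Tree, p) -> dict:
    """Per node: (sum of log p over nonzero descendant-tip p's, count of
    zero p's). The survival product for the branch above the node is then
    0 if any zero, else exp(logsum)."""
    agg: dict[int, tuple[float, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            try:
                pi = p[label]
            except KeyError:
                raise KeyError(f"no extinction probability for tip {label!r}")
            if not (0.0 <= pi <= 1.0):
                raise ValueError(f"p out of [0,1] for {label!r}: {pi}")
            agg[id(node)] = (0.0, 1) if pi == 0.0 else (math.log(pi), 0)
        else:
            logsum = 0.0
            zeros = 0
            for child in node.child_nodes():
                ls, z = agg[id(child)]
                logsum += ls
                zeros += z
            agg[id(node)] = (logsum, zeros)
    return agg


def _prod(entry: tuple[float, int]) -> float:
    logsum, zeros = entry
    return 0.0 if zeros > 0 else math.exp(logsum)


def expected_pd_loss(tree: dendropy.Tree, p: PextIteration | dict) -> float:
    """Expected PD loss under independent Bernoulli extinctions (Ma)."""
    agg = _branch_products(tree, p)
    out = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        out += (node.edge.length or 0.0) * _prod(agg[id(node)])
    return out


def ed2_scores(tree: dendropy.Tree, p: PextIteration | dict) -> dict[str, float]:
    """ED2 per tip: expected marginal PD contribution given the other
    tips' extinction probabilities (Ma)."""
    agg = _branch_products(tree, p)
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        pi = p[label]
        score = 0.0
        node = leaf
        while node.parent_node is not None:
            logsum, zeros = agg[id(node)]
            if pi == 0.0:
                zx = zeros - 1
                prod_excl = math.exp(logsum) if zx == 0 else 0.0
            else:
                prod_excl = 0.0 if zeros > 0 else math.exp(logsum - math.log(pi))
            score += (node.edge.length or 0.0) * prod_excl
            node = node.parent_node
        out[label] = score
    return out


def edge2_scores(tree: dendropy.Tree, p: PextIteration | dict) -> dict[str, float]:
    """EDGE2 per tip: ``p_i * ED2_i`` (Ma)."""
    ed2 = ed2_scores(tree, p)
    return {label: p[label] * v for label, v in ed2.items()}


def weight_tree(tree: dendropy.Tree, p: PextIteration | dict) -> dendropy.Tree:
    """Risk-weighted copy of ``tree``: each branch rescaled by the joint
    extinction probability of its descendant tips. The weighted total
    length equals the tree's expected PD loss."""
    out = parse_newick(write_newick(tree))[0]
    agg = _branch_products(out, p)
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        node.edge.length = (node.edge.length or 0.0) * _prod(agg[id(node)])
    return out


def tbl_percent(ed: float, tbl: float) -> float | None:
    """Share (%) of ED attributable to the pendant edge, one decimal;
    None (reported as missing) when ED is zero."""
    if ed == 0.0:
        return None
    return round(100.0 * tbl / ed, 1)


@dataclass
class IterationScores:
    """Per-taxon scores for one (tree, extinction-probability) iteration.

    ``scores`` is indexed by taxon with columns ed2, edge2, tbl, pext
    (all branch-length quantities in Ma).
    """

    iteration: int
    scores: pd.DataFrame
    epd_loss: float
    total_pd: float

    def __post_init__(self):
        if self.epd_loss > self.total_pd * (1 + 1e-9):
            raise ValueError("expected PD loss exceeds total PD")


def score_iteration(
    tree: dendropy.Tree, p: PextIteration, iteration: int | None = None
) -> IterationScores:
    """Compute the full score bundle for one complete tree and one draw of
    extinction probabilities."""
    it = p.iteration if iteration is None else iteration
    ed2 = ed2_scores(tree, p)
    tbl = {
        leaf.taxon.label: leaf.edge.length or 0.0
        for leaf in tree.leaf_node_iter()
    }
    df = pd.DataFrame(
        {
            "ed2": pd.Series(ed2),
            "tbl": pd.Series(tbl),
            "pext": pd.Series({t: p[t] for t in ed2}),
        }
    )
    df["edge2"] = df["pext"] * df["ed2"]
    df = df[["ed2", "edge2", "tbl", "pext"]].sort_index()
    df.index.name = "taxon"
    return IterationScores(
        iteration=it,
        scores=df,
        epd_loss=expected_pd_loss(tree, p),
        total_pd=total_length(tree),
    )
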