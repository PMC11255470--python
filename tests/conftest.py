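"""Shared fixtures and independent tree/score oracles.

The tree builders here construct newick strings directly (random
coalescent-style merges for ultrametric trees, recursive splits for
general trees) so they are independent of the package's own simulators;
the enumeration oracle computes extinction-scenario expectations by
brute force over all 2^n survival outcomes.
"""

from __future__ import annotations

import numpy as np
import pytest


def random_ultrametric_newick(rng: np.random.Generator, n_tips: int,
                              height: float = 10.0) -> str:
    """Random ultrametric tree via successive pair merges at increasing
    node heights (all tips end at height 0)."""
    labels = [f"t{i}" for i in range(n_tips)]
    if n_tips == 1:
        return f"({labels[0]}:{height});"
    heights = np.sort(rng.uniform(0.05 * height, height, size=n_tips - 1))
    heights[-1] = height
    clusters = [(lab, 0.0) for lab in labels]  # (newick fragment, node height)
    for h in heights:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        (na, ha), (nb, hb) = clusters[i], clusters[j]
        merged = (f"({na}:{h - ha:.10f},{nb}:{h - hb:.10f})", float(h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    assert len(clusters) == 1
    return clusters[0][0] + ";"


def random_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random (generally non-ultrametric) rooted binary tree."""
    frags = [f"t{i}:{rng.uniform(0.1, 3.0):.10f}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = rng.choice(len(frags), size=2, replace=False)
        merged = f"({frags[i]},{frags[j]}):{rng.uniform(0.1, 3.0):.10f}"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
    # the root edge length is dropped on the final fragment
    root = frags[0]
    root = root[: root.rfind(":")] if root.rfind(":") > root.rfind(")") else root
    return root + ";"


def tree_arrays(tree):
    """(labels, branch lengths, tips-below-branch indicator) for a parsed
    tree: one row per non-root branch, one column per tip."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    branches = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    lengths = np.array([nd.edge.length or 0.0 for nd in branches])
    desc = np.zeros((len(branches), len(labels)), dtype=bool)
    for b, nd in enumerate(branches):
        for lf in nd.leaf_iter():
            desc[b, index[id(lf)]] = True
    return labels, lengths, desc


def enumeration_expected_loss(lengths: np.ndarray, desc: np.ndarray,
                              p: np.ndarray) -> float:
    """Expected PD loss by exhaustive enumeration of survival outcomes.

    PD retained by a survival pattern counts every branch with at least
    one surviving descendant tip; the loss is total minus its expectation.
    """
    n = desc.shape[1]
    patterns = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    weights = np.prod(np.where(patterns, 1.0 - p, p), axis=1)
    covered = patterns @ desc.T.astype(int) > 0  # (2^n, branches)
    pd_vals = covered @ lengths
    return float(lengths.sum() - weights @ pd_vals)


def enumeration_ed2(lengths: np.ndarray, desc: np.ndarray,
                    p: np.ndarray) -> np.ndarray:
    """ED2 per tip by enumeration: expected PD gained by forcing the tip
    alive versus extinct, over the other tips' 2^(n-1) outcomes."""
    n = desc.shape[1]
    patterns = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    covered = patterns @ desc.T.astype(int) > 0
    pd_vals = covered @ lengths
    out = np.empty(n)
    for i in range(n):
        alive = patterns[:, i]
        others = np.delete(np.arange(n), i)
        w = np.prod(
            np.where(patterns[:, others], 1.0 - p[others], p[others]), axis=1
        )
        # pair each pattern with its i-flipped twin via xor on bit i
        flipped = np.arange(2 ** n) ^ (1 << i)
        gain = pd_vals - pd_vals[flipped]  # meaningful where i is alive
        out[i] = float(np.sum(w[alive] * gain[alive]))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_newick():
    return "((a:1,b:1):1,c:2);"
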