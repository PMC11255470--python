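"""Aggregation across iterations and the EDGE Species / Research lists.

Scoring is replicated once per tree of the posterior-like set, so every
taxon ends up with one ED2/EDGE2/TBL value per iteration. Medians over
iterations are the reported point scores. List membership uses the
above-median rule: in each iteration the across-taxa median EDGE2 is
computed, and a taxon "beats" the iteration when its own EDGE2 is
strictly above that median. A taxon qualifies when it beats at least
``ceil(frac * n_iterations)`` iterations (``frac`` defaults to 0.95, so
95 of 100 iterations qualifies — the threshold is inclusive):

* EDGE Species list — qualifying taxa assessed VU/EN/CR (and, by default,
  EW/EX, since formally described but extinct taxa still carry scores);
* EDGE Research list — qualifying taxa assessed DD or NE, flagging high
  phylogenetic value hidden behind assessment gaps.

Both lists are ordered by median EDGE2, descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extinction import DATA_DEFICIENT, THREATENED
from .scoring import IterationScores, tbl_percent

__all__ = ["aggregate", "build_lists", "PriorityLists"]


def aggregate(
    iters: Sequence[IterationScores],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse per-iteration scores into the per-taxon score table.

    Returns a DataFrame indexed by taxon with columns ``ED.med``,
    ``EDGE.med``, ``TBL.med`` (medians over iterations, Ma), ``TBL%``
    (from the medians, one decimal), ``above_median_total`` (iterations
    whose across-taxa median EDGE2 the taxon strictly exceeds),
    ``overall_rank`` (1 = highest ``EDGE.med``; ties broken by ``ED.med``
    then name) and, when ``categories`` is given, ``RL.cat``.
    """
    if not iters:
        raise ValueError("no iterations to aggregate")
    taxa = set(iters[0].scores.index)
    for it in iters[1:]:
        other = set(it.scores.index)
        if other != taxa:
            raise ValueError(
                "iterations cover different taxon sets; symmetric difference: "
                f"{sorted(taxa ^ other)[:10]}"
            )
    index = iters[0].scores.index
    ed2 = pd.DataFrame({it.iteration: it.scores["ed2"] for it in iters})
    edge2 = pd.DataFrame({it.iteration: it.scores["edge2"] for it in iters})
    tbl = pd.DataFrame({it.iteration: it.scores["tbl"] for it in iters})

    # per-iteration across-taxa median of EDGE2, strict ">" for "above"
    iter_medians = edge2.median(axis=0)
    above = (edge2 > iter_medians).sum(axis=1)

    out = pd.DataFrame(
        {
            "ED.med": ed2.median(axis=1),
            "EDGE.med": edge2.median(axis=1),
            "TBL.med": tbl.median(axis=1),
        },
        index=index,
    )
    out["TBL%"] = [
        np.nan if (v := tbl_percent(e, t)) is None else v
        for e, t in zip(out["ED.med"], out["TBL.med"])
    ]
    out["above_median_total"] = above.astype(int)
    order = out.assign(_name=out.index.astype(str)).sort_values(
        by=["EDGE.med", "ED.med", "_name"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    out["overall_rank"] = pd.Series(
        range(1, len(order) + 1), index=order.index
    )
    if categories is not None:
        missing = sorted(taxa - set(categories))
        if missing:
            raise ValueError(f"taxa without Red List category: {missing[:10]}")
        out["RL.cat"] = [categories[t] for t in out.index]
    out.index.name = "taxon"
    return out


@dataclass(frozen=True)
class PriorityLists:
    """Ranked EDGE Species and EDGE Research lists plus the thresholds used."""

    edge_species: list[str]
    research_list: list[str]
    n_iterations: int
    frac: float
    count_cutoff: int
    threatened: frozenset = field(default_factory=lambda: frozenset(THREATENED))


def build_lists(
    scores: pd.DataFrame,
    n_iterations: int,
    frac: float = 0.95,
    threatened: frozenset | set = THREATENED,
) -> PriorityLists:
    """Apply the above-median rule to the aggregated score table.

    ``scores`` must carry columns ``EDGE.med``, ``above_median_total`` and
    ``RL.cat``. The count cutoff is ``ceil(frac * n_iterations)`` and the
    comparison is inclusive (>=).
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    needed = {"EDGE.med", "above_median_total", "RL.cat"}
    if not needed <= set(scores.columns):
        raise ValueError(f"score table lacks columns {sorted(needed - set(scores.columns))}")
    # guard against binary-float overshoot (0.95 * 100 is slightly above 95)
    cutoff = math.ceil(frac * n_iterations - 1e-9)
    qualifies = scores["above_median_total"] >= cutoff
    ranked = scores.loc[qualifies].sort_values(
        by="EDGE.med", ascending=False, kind="mergesort"
    )
    edge_species = [
        t for t in ranked.index if ranked.at[t, "RL.cat"] in threatened
    ]
    research = [
        t for t in ranked.index if ranked.at[t, "RL.cat"] in DATA_DEFICIENT
    ]
    return PriorityLists(
        edge_species=edge_species,
        research_list=research,
        n_iterations=n_iterations,
        frac=frac,
        count_cutoff=cutoff,
        threatened=frozenset(threatened),
    )
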