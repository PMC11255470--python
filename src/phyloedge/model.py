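"""The `EDGEAnalysis` model and its fitted `EDGEResults`.

`EDGEAnalysis` bundles the inputs of an EDGE2-style prioritisation — a
posterior-like set of rooted ultrametric trees, Red List assessments,
clade assignments for taxa missing from the trees, and (optionally)
occurrence records — and `fit()` runs the whole pipeline:

1. impute missing taxa onto every tree (complete species-level trees);
2. per tree, draw extinction probabilities from the category-keyed
   sampler and compute ED2 / EDGE2 / TBL per taxon, expected PD loss and
   the risk-weighted tree;
3. aggregate medians across iterations, count above-median iterations,
   rank taxa, and build the EDGE Species and EDGE Research lists;

the fitted `EDGEResults` carries the score table, the lists, per-
iteration diagnostics, and computes per-QDS spatial metrics on demand.
Everything is reproducible from (inputs, seed): a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import spatial as _spatial
from .extinction import (
    AssessmentTable,
    PextSamplerConfig,
    sample_pext,
)
from .imputation import CladeAssignment, impute_treeset, read_clade_assignments
from .prioritisation import PriorityLists, aggregate, build_lists
from .scoring import IterationScores, score_iteration, weight_tree
from .trees import TreeSet, check_ultrametric, read_newick

__all__ = ["EDGEAnalysis", "EDGEResults"]


class EDGEAnalysis:
    """Extinction-risk-weighted phylogenetic prioritisation model.

    Parameters
    ----------
    trees
        Posterior-like set of rooted ultrametric trees (branch lengths Ma).
    assessments
        Red List category per taxon; taxa absent from the trees must have
        a clade assignment.
    clade_assignments, clade_map
        Missing-taxon clade labels and clade -> anchor-tip map for the
        imputation stage. May be empty when the trees are already complete.
    occurrences
        Raw occurrence records (taxon, longitude, latitude) for the
        spatial stage; cleaned at fit time.
    synonym_map
        from-name -> accepted-name renames applied during cleaning.
    sampler
        Extinction-probability sampler configuration.
    attachment
        Imputation attachment rule: "length" (default) or "uniform".
    """

    def __init__(
        self,
        trees: TreeSet,
        assessments: AssessmentTable,
        clade_assignments: Sequence[CladeAssignment] = (),
        clade_map: Mapping[str, Sequence[str]] | None = None,
        occurrences: pd.DataFrame | None = None,
        synonym_map: Mapping[str, str] | None = None,
        sampler: PextSamplerConfig | None = None,
        attachment: str = "length",
    ):
        self.trees = trees
        self.assessments = assessments
        self.clade_assignments = list(clade_assignments)
        self.clade_map = dict(clade_map or {})
        self.occurrences = occurrences
        self.synonym_map = dict(synonym_map or {})
        self.sampler = sampler or PextSamplerConfig()
        self.attachment = attachment
        for tree in trees:
            check_ultrametric(tree)
        tree_tips = {l.taxon.label for l in trees[0].leaf_node_iter()}
        assessed = set(assessments.taxa)
        assigned = {a.taxon for a in self.clade_assignments}
        unplaced = sorted(assessed - tree_tips - assigned)
        if unplaced:
            raise ValueError(
                "assessed taxa neither on the trees nor assigned to a clade: "
                f"{unplaced[:10]} (and {max(0, len(unplaced) - 10)} more)"
            )

    @classmethod
    def from_files(
        cls,
        trees,
        assessments,
        clades=None,
        occurrences=None,
        synonyms=None,
        clade_map: Mapping[str, Sequence[str]] | None = None,
        sampler: PextSamplerConfig | None = None,
        attachment: str = "length",
    ) -> "EDGEAnalysis":
        """Build the model from the on-disk text formats (multi-newick
        trees, assessments CSV, clades CSV, occurrences CSV, synonyms CSV)."""
        treeset = read_newick(trees)
        table = AssessmentTable.from_csv(assessments)
        assignments = read_clade_assignments(clades) if clades else []
        occ = _spatial.read_occurrences(occurrences) if occurrences else None
        syn = _spatial.read_synonym_map(synonyms) if synonyms else None
        return cls(
            treeset,
            table,
            clade_assignments=assignments,
            clade_map=clade_map or {},
            occurrences=occ,
            synonym_map=syn,
            sampler=sampler,
            attachment=attachment,
        )

    def fit(
        self,
        seed: int,
        n_iterations: int | None = None,
        threshold: float = 0.95,
    ) -> "EDGEResults":
        """Run imputation, scoring and list building.

        One iteration per tree (the default uses every tree); ``seed``
        drives both imputation and extinction-probability sampling.
        """
        if seed is None:
            raise ValueError("fit requires a seed (reproducibility contract)")
        n_iter = len(self.trees) if n_iterations is None else int(n_iterations)
        if not (1 <= n_iter <= len(self.trees)):
            raise ValueError(
                f"n_iterations must be in 1..{len(self.trees)} (one tree per iteration)"
            )
        subset = TreeSet(list(self.trees)[:n_iter])
        imput_seed = int(np.random.SeedSequence([int(seed), 101]).generate_state(1)[0])
        pext_seed = int(
            np.random.SeedSequence([int(seed), 202]).generate_state(1)[0] % (2**31)
        )
        if self.clade_assignments:
            complete = impute_treeset(
                subset,
                self.clade_assignments,
                self.clade_map,
                seed=imput_seed,
                attachment=self.attachment,
            )
        else:
            complete = subset
            complete.common_labels()

        iterations: list[IterationScores] = []
        weighted = []
        for i, tree in enumerate(complete):
            p = sample_pext(self.assessments, self.sampler, iteration=i, seed=pext_seed)
            iterations.append(score_iteration(tree, p, iteration=i))
            weighted.append(weight_tree(tree, p))
        scores = aggregate(iterations, categories=self.assessments.categories)
        lists = build_lists(scores, n_iterations=n_iter, frac=threshold)
        return EDGEResults(
            model=self,
            seed=int(seed),
            threshold=threshold,
            n_iterations=n_iter,
            complete_trees=complete,
            weighted_trees=TreeSet(weighted),
            iterations=iterations,
            scores=scores,
            lists=lists,
        )


@dataclass
class EDGEResults:
    """Fitted prioritisation: score table, lists, diagnostics."""

    model: EDGEAnalysis
    seed: int
    threshold: float
    n_iterations: int
    complete_trees: TreeSet
    weighted_trees: TreeSet
    iterations: list[IterationScores]
    scores: pd.DataFrame
    lists: PriorityLists
    _cells: pd.DataFrame | None = _field(default=None, repr=False)
    _cleaning_log: _spatial.CleaningLog | None = _field(default=None, repr=False)

    @property
    def total_pd(self) -> float:
        """Median total tree length (Ma) over iterations."""
        return float(np.median([it.total_pd for it in self.iterations]))

    @property
    def expected_pd_loss(self) -> float:
        """Median expected PD loss (Ma) over iterations."""
        return float(np.median([it.epd_loss for it in self.iterations]))

    def iteration_frame(self) -> pd.DataFrame:
        """Long-format per-iteration per-taxon scores (CSV-ready)."""
        frames = []
        for it in self.iterations:
            df = it.scores.reset_index()
            df.insert(0, "iteration", it.iteration)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def edge_table(self) -> pd.DataFrame:
        """EDGE Species list rows in reporting order."""
        return self._list_table(self.lists.edge_species)

    def research_table(self) -> pd.DataFrame:
        """EDGE Research list rows in reporting order."""
        return self._list_table(self.lists.research_list)

    def _list_table(self, taxa: Sequence[str]) -> pd.DataFrame:
        cols = [
            "overall_rank", "above_median_total", "ED.med", "EDGE.med",
            "TBL.med", "TBL%", "RL.cat",
        ]
        out = self.scores.loc[list(taxa), cols].reset_index()
        return out

    def spatial_metrics(self) -> pd.DataFrame:
        """Per-QDS metrics table (computed once, then cached)."""
        if self._cells is not None:
            return self._cells
        occ = self.model.occurrences
        if occ is None:
            raise ValueError("model has no occurrence records")
        cleaned, log = _spatial.clean_occurrences(occ, self.model.synonym_map)
        matrix = _spatial.presence_matrix(cleaned)
        self._cells = _spatial.cell_metrics(
            matrix,
            self.complete_trees,
            self.weighted_trees,
            edge_list=self.lists.edge_species,
        )
        self._cleaning_log = log
        return self._cells

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "EDGE prioritisation results",
            "===========================",
            f"iterations (trees):        {self.n_iterations}",
            f"taxa on complete trees:    {len(self.scores)}",
            f"total PD (median, Ma):     {self.total_pd:.2f}",
            f"expected PD loss (median): {self.expected_pd_loss:.2f} Ma "
            f"({100 * self.expected_pd_loss / self.total_pd:.1f}%)",
            f"above-median cutoff:       >= {self.lists.count_cutoff} of "
            f"{self.n_iterations} iterations",
            f"EDGE species:              {len(self.lists.edge_species)}",
            f"EDGE research list:        {len(self.lists.research_list)}",
        ]
        top = self.edge_table().head(5)
        if len(top):
            lines.append("top EDGE species (EDGE.med, Ma):")
            for _, row in top.iterrows():
                lines.append(f"  {row['taxon']:<30s} {row['EDGE.med']:.4f}")
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write the output bundle (scores, lists, cells, manifest, log)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.reset_index().to_csv(out / "scores.csv", index=False)
        self.edge_table().to_csv(out / "edge_list.csv", index=False)
        self.research_table().to_csv(out / "research_list.csv", index=False)
        stage_log = {
            "n_iterations": self.n_iterations,
            "n_taxa": int(len(self.scores)),
            "n_trees_in": len(self.model.trees),
            "n_imputed": len(self.model.clade_assignments),
            "edge_species": len(self.lists.edge_species),
            "research_list": len(self.lists.research_list),
        }
        if self.model.occurrences is not None:
            cells = self.spatial_metrics()
            cells.to_csv(out / "cells.csv", index=False)
            stage_log["occurrence_cleaning"] = self._cleaning_log.as_dict()
            stage_log["n_cells"] = int(len(cells))
            stage_log["unmatched_occurrence_taxa"] = cells.attrs.get(
                "unmatched_taxa", []
            )
        manifest = {
            "seed": self.seed,
            "threshold": self.threshold,
            "count_cutoff": self.lists.count_cutoff,
            "sampler": {
                "mode": self.model.sampler.mode,
                "beta_a": self.model.sampler.beta_a,
                "beta_b": self.model.sampler.beta_b,
            },
            "attachment": self.model.attachment,
            "stages": stage_log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            for key, val in stage_log.items():
                fh.write(f"{key}: {val}\n")
        return manifest
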