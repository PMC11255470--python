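"""Synthetic study systems for the prioritisation pipeline.

The generator emulates the statistical structure of a large shrub genus
whose diversity is dominated by one young, species-rich radiation (the
Cape clade of the Cape Floristic Region) alongside several older,
species-poor lineages:

* a posterior-like set of rooted ultrametric trees, each assembled by
  grafting independently simulated pure-birth (Yule) clade subtrees onto
  a fixed-age backbone; within-clade topology is re-simulated per tree so
  the set carries phylogenetic uncertainty;
* an assessment table with exact per-category quotas (defaults are the
  genus-wide Red List frequencies: 51 CR, 62 EN, 86 VU, 9 NT, 562 LC,
  4 EX and 274 DD/NE of 1048 taxa), optionally biased so threatened
  categories concentrate in the radiation;
* a configurable fraction of taxa withheld from the trees ("unsampled",
  default 55% sampled) with clade assignments for the imputation stage;
* occurrence records of narrow-range taxa on a one-row QDS landscape,
  radiation taxa concentrated around one cell, with an optional fraction
  of deliberately invalid rows to exercise record cleaning.

Everything is deterministic given the scenario seed; a manifest records
the ground truth (who is sampled, categories, ranges, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .extinction import AssessmentTable, CATEGORIES
from .imputation import CladeAssignment
from .trees import TreeSet, parse_newick, write_newick

__all__ = [
    "CladeSpec",
    "LandscapeSpec",
    "ScenarioConfig",
    "Scenario",
    "yule_tree",
    "simulate_treeset",
    "simulate_assessments",
    "simulate_occurrences",
    "simulate_scenario",
]

#: genus-wide Red List category frequencies used as default quotas
DEFAULT_QUOTAS = {
    "CR": 51, "EN": 62, "VU": 86, "NT": 9, "LC": 562, "EX": 4, "DD": 137, "NE": 137,
}


@dataclass(frozen=True)
class CladeSpec:
    """One clade: taxon count, crown age (Ma) and sampling level."""

    name: str
    crown_age: float
    n_taxa: int
    sampled_fraction: float = 0.55
    birth_model: str = "yule"

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValueError("clade needs at least one taxon")
        if not (0.0 < self.sampled_fraction <= 1.0):
            raise ValueError("sampled_fraction must be in (0, 1]")
        if self.birth_model != "yule":
            raise ValueError(f"unsupported birth model: {self.birth_model!r}")


@dataclass(frozen=True)
class LandscapeSpec:
    """A single row of QDS cells (southern-African domain by default)."""

    n_cells: int = 40
    origin_lon: float = 18.0
    origin_lat: float = -34.25
    range_mean: float = 2.0  # geometric mean range size, in cells
    records_mean: float = 3.0  # mean records per taxon (>= 1 each)
    invalid_fraction: float = 0.0
    radiation_cell: int = 5
    radiation_spread: int = 3  # radiation taxa start within +- this of the hot cell


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: clades, tree count, category quotas, landscape, seed."""

    clades: Sequence[CladeSpec]
    n_trees: int = 100
    root_height: float = 62.0
    quotas: dict = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    threat_bias: float | None = None  # P(a CR/EN/VU slot goes to the radiation clade)
    radiation_clade: str | None = None  # defaults to the largest clade
    n_conspecific_groups: int = 0
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    seed: int = 0

    def __post_init__(self):
        total = sum(c.n_taxa for c in self.clades)
        qtotal = sum(self.quotas.values())
        if total != qtotal:
            raise ValueError(
                f"category quotas sum to {qtotal} but clades hold {total} taxa"
            )
        bad = sorted(set(self.quotas) - set(CATEGORIES))
        if bad:
            raise ValueError(f"unknown categories in quotas: {bad}")

    @property
    def total_taxa(self) -> int:
        return sum(c.n_taxa for c in self.clades)

    def radiation(self) -> str:
        if self.radiation_clade is not None:
            return self.radiation_clade
        return max(self.clades, key=lambda c: c.n_taxa).name


def default_config(seed: int = 0) -> ScenarioConfig:
    """Genus-scale default: ~1000 taxa, one young radiation holding most
    of the diversity, several older species-poor clades, 100 trees."""
    clades = [
        CladeSpec("CAPE", crown_age=15.0, n_taxa=720),
        CladeSpec("TEA", crown_age=28.0, n_taxa=140),
        CladeSpec("ARB", crown_age=30.0, n_taxa=8),
        CladeSpec("TRIM", crown_age=25.0, n_taxa=6),
        CladeSpec("KIN", crown_age=25.0, n_taxa=4),
        CladeSpec("EUR1", crown_age=55.0, n_taxa=34),
        CladeSpec("EUR2", crown_age=52.0, n_taxa=34),
        CladeSpec("EUR3", crown_age=48.0, n_taxa=34),
        CladeSpec("EUR4", crown_age=45.0, n_taxa=34),
        CladeSpec("EUR5", crown_age=42.0, n_taxa=34),
    ]
    return ScenarioConfig(clades=clades, n_trees=100, root_height=62.0, seed=seed)


def yule_tree(
    n_tips: int,
    crown_age: float,
    labels: Sequence[str],
    rng: np.random.Generator,
    namespace: dendropy.TaxonNamespace,
) -> dendropy.Node:
    """Simulate a pure-birth clade subtree and return its crown node.

    Convention: the crown starts with two lineages; inter-speciation
    waits are Exp(k * rate); after the n-th tip appears the clade runs an
    Exp(n * rate) stem-of-the-present interval; all node times are then
    rescaled so the crown sits exactly ``crown_age`` before the present.
    """
    if len(labels) != n_tips:
        raise ValueError("label count must equal tip count")
    if n_tips == 1:
        leaf = dendropy.Node(taxon=namespace.require_taxon(label=labels[0]))
        leaf.edge.length = crown_age  # pendant placeholder; caller rescales stems
        return leaf
    crown = dendropy.Node()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        crown.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = rng.integers(k)
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / n_tips)
    order = rng.permutation(n_tips)
    for (node, birth), lab in zip(active, (labels[i] for i in order)):
        node.edge.length = t_end - birth
        node.taxon = namespace.require_taxon(label=lab)
    # rescale so crown age is exact
    scale = crown_age / t_end
    stack = [crown]
    while stack:
        nd = stack.pop()
        for ch in nd.child_nodes():
            ch.edge.length *= scale
            stack.append(ch)
    return crown


def _assemble_tree(
    config: ScenarioConfig,
    tips_per_clade: dict[str, list[str]],
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Graft per-clade Yule subtrees onto a pectinate backbone of fixed
    root height; all tips end at the present."""
    ns = dendropy.TaxonNamespace()
    clades = sorted(config.clades, key=lambda c: (-c.crown_age, c.name))
    ages = [c.crown_age for c in clades]
    H = config.root_height
    if len(clades) > 1 and H <= ages[0]:
        raise ValueError(
            f"root height {H} not above oldest clade crown age {ages[0]}"
        )
    crowns = {}
    for spec in clades:
        labels = tips_per_clade[spec.name]
        crowns[spec.name] = yule_tree(len(labels), spec.crown_age, labels, rng, ns)

    def stem(crown_node: dendropy.Node, spec: CladeSpec, attach_height: float):
        if crown_node.is_leaf():
            crown_node.edge.length = attach_height  # single-taxon clade
        else:
            crown_node.edge.length = attach_height - spec.crown_age
        return crown_node

    if len(clades) == 1:
        spec = clades[0]
        root = crowns[spec.name]
        if root.is_leaf():
            root.edge.length = spec.crown_age
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = root
        return _reparse(tree)
    heights = [H]
    for i in range(1, len(clades) - 1):
        heights.append((heights[-1] + ages[i]) / 2.0)
    root = dendropy.Node()
    backbone = root
    for i, spec in enumerate(clades[:-1]):
        h = heights[i]
        backbone.add_child(stem(crowns[spec.name], spec, h))
        if i < len(clades) - 2:
            nxt = dendropy.Node()
            backbone.add_child(nxt)
            nxt.edge.length = h - heights[i + 1]
            backbone = nxt
        else:
            last = clades[-1]
            backbone.add_child(stem(crowns[last.name], last, h))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    return _reparse(tree)


def _reparse(tree: dendropy.Tree) -> dendropy.Tree:
    # normalise internals (bipartitions, namespaces) by a write/parse cycle
    return parse_newick(write_newick(tree))[0]


def _taxon_names(config: ScenarioConfig) -> dict[str, list[str]]:
    return {
        c.name: [f"{c.name}_t{i:04d}" for i in range(1, c.n_taxa + 1)]
        for c in config.clades
    }


def _sampling_split(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per clade, choose which taxa are sequenced ("sampled") and which
    must be imputed; at least one sampled anchor per clade."""
    names = _taxon_names(config)
    sampled, missing = {}, {}
    for c in config.clades:
        labels = names[c.name]
        n_samp = max(1, int(round(c.sampled_fraction * c.n_taxa)))
        idx = rng.permutation(c.n_taxa)
        keep = sorted(idx[:n_samp])
        sampled[c.name] = [labels[i] for i in keep]
        missing[c.name] = [l for i, l in enumerate(labels) if i not in set(keep)]
    return sampled, missing


def simulate_treeset(
    config: ScenarioConfig, n_trees: int | None = None
) -> tuple[TreeSet, dict]:
    """Simulate the posterior-like tree set over the sampled taxa.

    Returns the trees plus a manifest recording, per taxon, its clade,
    whether it is on the trees, and any conspecific-group key.
    """
    n_trees = config.n_trees if n_trees is None else n_trees
    master = np.random.default_rng([config.seed, 1])
    sampled, missing = _sampling_split(config, master)

    # optionally recast some missing radiation taxa as subspecies of
    # sampled ones, to exercise conspecific grouping downstream
    groups: dict[str, str] = {}
    if config.n_conspecific_groups:
        rad = config.radiation()
        pool = list(missing[rad])
        hosts = list(sampled[rad])
        k = min(config.n_conspecific_groups, len(pool), len(hosts))
        chosen = master.choice(len(pool), size=k, replace=False)
        host_idx = master.choice(len(hosts), size=k, replace=False)
        for j, (ci, hi) in enumerate(zip(chosen, host_idx)):
            old = pool[ci]
            host = hosts[hi]
            new = f"{host}_ssp_{j + 1}"
            missing[rad][missing[rad].index(old)] = new
            groups[new] = host

    trees = []
    for t in range(n_trees):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, t]).generate_state(1)[0]
        )
        trees.append(_assemble_tree(config, sampled, rng))
    manifest = {
        "seed": config.seed,
        "n_trees": n_trees,
        "root_height": config.root_height,
        "clades": {
            c.name: {"crown_age": c.crown_age, "n_taxa": c.n_taxa} for c in config.clades
        },
        "taxa": [
            {
                "taxon": lab,
                "clade": c.name,
                "sampled": lab in set(sampled[c.name]),
                "group_key": groups.get(lab),
            }
            for c in config.clades
            for lab in sampled[c.name] + missing[c.name]
        ],
    }
    return TreeSet(trees), manifest


def clade_assignments_from_manifest(manifest: dict) -> list[CladeAssignment]:
    return [
        CladeAssignment(t["taxon"], t["clade"], t.get("group_key"))
        for t in manifest["taxa"]
        if not t["sampled"]
    ]


def clade_map_from_manifest(manifest: dict) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for t in manifest["taxa"]:
        if t["sampled"]:
            out.setdefault(t["clade"], []).append(t["taxon"])
    return out


def simulate_assessments(
    config: ScenarioConfig, manifest: dict
) -> AssessmentTable:
    """Assign Red List categories by exact quota (deterministic totals).

    With ``threat_bias`` b, each CR/EN/VU slot goes to a radiation-clade
    taxon with probability b (while both pools last), emulating threat
    concentrated in the young radiation.
    """
    rng = np.random.default_rng([config.seed, 3])
    taxa = [t["taxon"] for t in manifest["taxa"]]
    clade_of = {t["taxon"]: t["clade"] for t in manifest["taxa"]}
    if len(taxa) != sum(config.quotas.values()):
        raise ValueError(
            f"quotas sum to {sum(config.quotas.values())} but scenario has "
            f"{len(taxa)} taxa"
        )
    categories: dict[str, str] = {}
    if config.threat_bias is None:
        pool = list(taxa)
        rng.shuffle(pool)
        i = 0
        for cat, count in config.quotas.items():
            for lab in pool[i : i + count]:
                categories[lab] = cat
            i += count
    else:
        rad = config.radiation()
        rad_pool = [t for t in taxa if clade_of[t] == rad]
        other_pool = [t for t in taxa if clade_of[t] != rad]
        rng.shuffle(rad_pool)
        rng.shuffle(other_pool)
        b = config.threat_bias
        for cat in ("CR", "EN", "VU"):
            for _ in range(config.quotas.get(cat, 0)):
                use_rad = rng.uniform() < b
                if use_rad and rad_pool:
                    categories[rad_pool.pop()] = cat
                elif other_pool:
                    categories[other_pool.pop()] = cat
                else:
                    categories[rad_pool.pop()] = cat
        rest = rad_pool + other_pool
        rng.shuffle(rest)
        i = 0
        for cat, count in config.quotas.items():
            if cat in ("CR", "EN", "VU"):
                continue
            for lab in rest[i : i + count]:
                categories[lab] = cat
            i += count
    return AssessmentTable({t: categories[t] for t in taxa})


def simulate_occurrences(
    config: ScenarioConfig, manifest: dict
) -> pd.DataFrame:
    """Occurrence records of narrow-range taxa on the one-row landscape.

    Each taxon holds a contiguous run of cells (geometric range size);
    radiation-clade taxa start near the configured hot cell; per-record
    points are uniform within a cell. A configured fraction of rows is
    deliberately corrupted ((0,0) points or out-of-range coordinates).
    """
    rng = np.random.default_rng([config.seed, 4])
    land = config.landscape
    rad = config.radiation()
    rows = []
    for entry in manifest["taxa"]:
        taxon, clade = entry["taxon"], entry["clade"]
        size = min(int(rng.geometric(1.0 / land.range_mean)), land.n_cells)
        if clade == rad:
            start = int(
                np.clip(
                    land.radiation_cell
                    + rng.integers(-land.radiation_spread, land.radiation_spread + 1),
                    0,
                    land.n_cells - size,
                )
            )
        else:
            start = int(rng.integers(0, land.n_cells - size + 1))
        n_rec = 1 + rng.poisson(max(land.records_mean - 1.0, 0.0))
        for _ in range(n_rec):
            cell = start + int(rng.integers(size))
            lon = land.origin_lon + 0.25 * cell + rng.uniform(0.0, 0.25)
            lat = land.origin_lat + rng.uniform(0.0, 0.25)
            if rng.uniform() < land.invalid_fraction:
                kind = rng.integers(3)
                if kind == 0:
                    lon, lat = 0.0, 0.0
                elif kind == 1:
                    lat = 95.0 + rng.uniform(0, 50)
                else:
                    lon = 185.0 + rng.uniform(0, 50)
            rows.append({"taxon": taxon, "longitude": lon, "latitude": lat})
    return pd.DataFrame(rows)


@dataclass
class Scenario:
    """A fully materialised synthetic study system."""

    config: ScenarioConfig
    trees: TreeSet
    assessments: AssessmentTable
    clade_assignments: list[CladeAssignment]
    clade_map: dict[str, list[str]]
    occurrences: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        """Emit the exact text formats the pipeline consumes."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trees.write(out / "trees.nwk")
        self.assessments.to_dataframe().to_csv(out / "assessments.csv", index=False)
        pd.DataFrame(
            [
                {"taxon": a.taxon, "clade": a.clade, "group_key": a.group_key or ""}
                for a in self.clade_assignments
            ]
        ).to_csv(out / "clades.csv", index=False)
        self.occurrences.to_csv(out / "occurrences.csv", index=False)
        manifest = dict(self.manifest)
        manifest["clade_map"] = self.clade_map
        manifest["config"] = _config_dict(self.config)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _config_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["clades"] = [asdict(c) for c in config.clades]
    return d


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate every input the pipeline consumes, plus the ground truth."""
    trees, manifest = simulate_treeset(config)
    assessments = simulate_assessments(config, manifest)
    for entry, cat in zip(
        manifest["taxa"], (assessments[t["taxon"]] for t in manifest["taxa"])
    ):
        entry["category"] = cat
    occurrences = simulate_occurrences(config, manifest)
    return Scenario(
        config=config,
        trees=trees,
        assessments=assessments,
        clade_assignments=clade_assignments_from_manifest(manifest),
        clade_map=clade_map_from_manifest(manifest),
        occurrences=occurrences,
        manifest=manifest,
    )
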