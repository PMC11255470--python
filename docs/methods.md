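# Methods

## Model

The package computes extinction-risk-weighted phylogenetic diversity on
a set of rooted ultrametric trees with branch lengths in millions of
years. The probabilistic model is the standard "field of bullets with
unequal bullets": every terminal taxon *i* goes extinct independently
with probability `p_i`, and a branch is lost exactly when all tips
descending from it are lost. Under that model,

- `ePDloss = Σ_b L_b · Π_{j∈tips(b)} p_j` is the expectation of the
  phylogenetic diversity (PD) removed from the tree;
- `ED2_i = Σ_{b∈path(i→root)} L_b · Π_{j∈tips(b), j≠i} p_j` is tip *i*'s
  expected marginal contribution to surviving PD (the empty product on
  the pendant edge is 1, so a tip always "owns" its terminal branch);
- `EDGE2_i = p_i · ED2_i` is the expected PD loss attributable to *i*.

These closed forms are the only formalisation consistent with the
exhaustive-expectation semantics, and the test suite pins them to brute
force enumeration over all `2^n` survival outcomes on trees of up to 10
tips: any alternative reading would fail those oracles. Equivalently,
`EDGE2_i` is the root-path sum on the *risk-weighted tree* whose branch
lengths are `L'_b = L_b · Π_{j∈tips(b)} p_j`; the conservation identity
`Σ_b L'_b = ePDloss` is asserted exactly.

Assumptions worth keeping in mind: extinctions are independent across
taxa (no spatially or phylogenetically correlated threats), `p_i` is
constant within an iteration, and branch lengths are taken at face
value (dating error is only represented through the spread of the tree
set).

## Extinction-probability sampling

Scores are replicated once per tree. In every iteration each taxon
draws `p_i` from a distribution keyed on its Red List category:

- EX and EW taxa get `p = 1` exactly (EW is treated as extinct for
  wild-PD purposes; the set of "extinct" categories is configurable);
- LC, NT, VU, EN, CR draw from the five equal-probability bands, in
  that order, of a right-skewed base distribution on [0, 1] — default
  `Beta(0.6, 2.4)`;
- DD and NE draw from the full pooled distribution, which is what makes
  a Research list possible: an unassessed taxon's score distribution
  spans all plausible threat levels.

The published EDGE2 protocol does not print its category→probability
distribution in a reusable closed form, so the banded sampler here is
an explicit stand-in that preserves the protocol's qualitative
contract — stochastic ordering of categories by threat and pooled
DD/NE draws — and is deliberately configurable (`PextSamplerConfig`),
including a deterministic `fixed` mode (defaults LC 0.0625 … CR 0.9)
for exact tests. Absolute score magnitudes therefore depend on this
choice; ranks and list membership are much less sensitive because all
taxa share the base distribution.

A draw is deterministic given `(seed, iteration)`; unseeded pipeline
calls are rejected rather than silently non-reproducible.

## Imputation of unsampled taxa

Scoring needs complete species-level trees. Each missing taxon carries
a clade assignment (clade = crown subtree of the MRCA of user-supplied
anchor tips); per tree, the taxon attaches to a branch drawn within
that crown with probability proportional to branch length (a
branch-uniform alternative is provided — the underlying "bind to a
randomly selected close relative" rule is underdetermined, and
length-proportional placement is the natural uniform-over-the-tree
choice). The attachment height is uniform along the chosen branch and
the new pendant edge closes to the present, so ultrametricity is
preserved by construction (checked to 1e-6 relative). The clade stem is
excluded: imputed taxa stay inside the crown.

Subspecific taxa sharing a conspecific-group key are inserted as a
unit: the first member attaches to the sampled conspecific's pendant
edge when one is on the tree (matched by name prefix/token), later
members attach within the group's subtree, and completed group subtrees
are closed to unrelated insertions, so conspecifics end up mutually
monophyletic on every output tree. Insertion order of units is
shuffled per tree; per-tree seeds derive from the master seed and tree
index, so placements are independent across trees yet exactly
reproducible.

## Aggregation and lists

Per-taxon `ED.med`, `EDGE.med`, `TBL.med` are medians over iterations
(even counts use the mean of the central pair); `TBL%` is
`100·TBL.med/ED.med` rounded to one decimal (undefined when ED.med is
0, reported missing). In each iteration the across-taxa median of
EDGE2 is computed over *all* terminals of the complete tree (sampled,
imputed and extinct alike; configurable); a taxon is "above" only on a
strict `>`, so exact ties never count. The EDGE Species list takes
taxa with category in {VU, EN, CR, EW, EX} whose above-median count is
at least `ceil(0.95 · n_iterations)` — the comparison is inclusive, so
95 of 100 qualifies; EX/EW inclusion is default-on because formally
described extinct taxa still appear in published EDGE tables, and it
is configurable. DD/NE taxa satisfying the same count rule form the
Research list. Ranks order by `EDGE.med` descending with `ED.med` and
then name as tie-breaks. Scores are stored and reported in raw Ma; any
log scaling is left to display code.

The ceiling computation subtracts 1e-9 before `ceil` to guard against
binary-float overshoot (`0.95 × 100` is fractionally above 95).

## Spatial metrics

Records are binned to quarter-degree squares on a grid anchored at
integer degrees with half-open `[i·0.25, (i+1)·0.25)` cells, the
convention that reproduces the published southern-African QDS
centroids (e.g. 3418BB → 18.875, −34.125); boundary points go to the
higher-index cell. Cells in the south/east domain carry the
four-digit-two-letter QDS code, others a numeric fallback code.
Cleaning drops unparseable, non-finite, out-of-range and exact-(0,0)
coordinates, applies the user synonym map and deduplicates to one
presence per (taxon, cell), logging counts per rule; it deliberately
implements only these minimal validity filters, not the full
coordinate-cleaning batteries used on raw aggregator downloads.

Per occupied cell: taxon richness counts every taxon present, including
taxa that cannot be placed on the trees (they are logged and excluded
from PD quantities only — configurable in effect, since the presence
matrix is user-accessible); EDGE richness counts present EDGE-species;
`PD.med` is the median over trees of the Faith PD of the present taxa,
where PD of a tip set is MRCA-rooted (no stem) and a singleton cell
scores the taxon's terminal branch length, the value a one-terminal
pruned tree retains; `ePDloss.med` prunes the globally risk-weighted
trees rather than reweighting within the cell, so a cell is charged
each branch's full joint-extinction weight exactly once.

## Synthetic scenarios

The generator emulates the study system's structure: per-clade
pure-birth (Yule) subtrees grafted onto a pectinate backbone at a fixed
root height (default 62 Ma), a dominant young radiation plus older
species-poor clades, a configurable sampled fraction per clade
(default 0.55) with the withheld taxa routed through imputation, exact
Red List quotas (defaults 51 CR / 62 EN / 86 VU / 9 NT / 562 LC /
4 EX / 274 DD+NE over 1048 taxa; the DD/NE split is even, as only the
pooled count is reported for the genus), and narrow-range occurrences
on a one-row QDS landscape (geometric range sizes with mean 2 cells,
Poisson record counts, radiation taxa concentrated near one hot cell,
an optional fraction of deliberately invalid rows). The Yule
convention is: crown starts at two lineages, exponential waits, an
`Exp(n·λ)` interval after the n-th tip, then rescaling to the exact
crown age; tests compare total-length distributions against an
independently coded Gillespie reference.

What the generator does *not* emulate: real geography and range
shapes, spatial autocorrelation of threat, gene-tree conflict,
taxonomic churn, and non-uniform sampling of DNA data with respect to
threat status. Passing tests therefore demonstrate the correctness of
the computations and the qualitative behaviour of the method (e.g.
richness–PD decoupling, recovery of a long-branch threatened relict),
not calibration against any real genus.

## Numerical and scale choices

- Products over up to ~1000 `p_j` terms are computed in log space with
  an exact-zero short-circuit.
- Ultrametricity is checked at 1e-6 relative on tip depths and
  violations warn rather than fail (rate-smoothed inputs carry noise);
  newick round-trips preserve lengths to 1e-9.
- Zero-length branches are legal (resolved polytomies); under
  length-proportional attachment they have zero mass, and the
  branch-uniform rule can still select them.
- Test and validation problem sizes are chosen for exactness per CPU
  second rather than realism: enumeration oracles stop at 10 tips
  (1024 outcomes), the placement-law check uses 1000 placements on a
  4-tip clade, and the end-to-end recovery study uses a 52-taxon
  system with 100 trees per run across 100 master seeds — 100
  iterations is kept there because the 95%-of-iterations rule's
  tolerance (five below-median iterations in 100) is part of the
  method's behaviour and changes if the iteration count is scaled.

## Known limitations

- The category→probability distribution is a configurable stand-in;
  absolute EDGE2 magnitudes (though not the worked identities) shift
  under a different base distribution.
- Imputation assumes clade assignments are correct and complete;
  unresolvable taxa must be excluded by the user.
- Per-cell expected PD loss uses global weights; it answers "how much
  at-risk PD occurs here", not "how much PD would this cell lose if
  only its own taxa went extinct".
- The spatial stage treats records as point presences; no range
  modelling, no sampling-effort correction.
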