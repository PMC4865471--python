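# Methods

## The model

`landgen` is a target-driven neutral landscape model.  Instead of generating
a categorical raster from a stochastic process with landscape-level knobs
(class proportions, spatial autocorrelation), it *searches* for a landscape
whose class- and patch-level pattern metrics match user-specified target
values.  The search state is a grid of integer land-use codes; the only move
is the exchange of two cells' codes, so the landscape composition (the
number of cells per class, hence PLAND) is an exact invariant of the search
and is fixed entirely by the initial raster.

The initial raster is either a percolation map — cells assigned at random
with exact per-class counts obtained by largest-remainder apportionment of
`proportion x assignable cells` (ties broken by ascending class code) — or a
real landscape in which some cells are flagged *fixed* and never change.
NODATA cells are always fixed.  Exact-count assignment, rather than per-cell
Bernoulli draws, is deliberate: it makes PLAND targets exactly attainable,
because no sequence of swaps can repair a composition that starts wrong
(such runs are reported `infeasible` immediately).

## Metrics and conventions

Patches are rook-connected (four-neighbor) components of one class;
diagonal contact does not join patches.  Conventions fixed by this
implementation, consistently across metrics, the optimizer and the test
oracles:

* **Perimeter / total edge.** Every cell side facing a different class,
  NODATA, or the raster boundary counts one edge segment.  TE of a class
  equals the sum of its patch perimeters; a k x k single-class raster has
  TE 4k.  This is the convention under which the landscape-series edge
  bounds (e.g. a 25 x 25 block having perimeter 100) reproduce exactly.
* **Like-adjacency tallies** (AI, CLUMPY) count each interior cell pair
  once and exclude boundary sides.
* **ECON** is binary: contrast weight 1 between one declared class pair, 0
  elsewhere.  Boundary and NODATA sides count in the denominator only.
* **AREA_pct** of a patch is percent of its *class's* cell count, not of
  the landscape.  This matches the series designs, where a dominant patch
  of a 35%-class carries an AREA target of 89 (percent of the class).
* **SHAPE** uses the integer minimal-perimeter denominator
  `minimal_perimeter(a) = 4n, 4n+2 or 4n+4` (n = floor(sqrt(a))), which
  equals the known closed form `2*ceil(2*sqrt(a))`; it is exact for small
  patches where `0.25 p / sqrt(a)` is not.
* **ENN** is the Euclidean distance between nearest cell centers of
  distinct same-class patches.
* **NLSI** normalizes TE between the compact bound `minimal_perimeter(A)`
  and the fully disaggregated bound `4A`.
* A metric that is undefined for a class (ENN with one patch, IJI with
  fewer than three classes, AI of a one-cell class, CLUMPY of a class
  filling the landscape) is a flagged `None`, excluded from means — never a
  silent zero.

FRAGSTATS parity is a design goal but not the test surface: FRAGSTATS
versions differ in boundary handling, and CLUMPY's small-sample correction
is not reproduced.  Correctness is established against independent
brute-force recounts (straight-from-definition Python loops in the test
suite), not against FRAGSTATS output.

## Objectives and the sequential acceptance rule

A target is `(metric, class, [patch rank], value, tolerance, bound)`;
TE and PERIM are upper bounds ("maximum total edge", "patch maximum
perimeter"), everything else is equality within an absolute tolerance.
Patch-level targets are matched to patches by rank: the targets of a
(metric, class) group, sorted by value descending, pair with the class's
patches sorted by area descending.  Area is the ranking key for every patch
metric, so the AREA and PERIM targets of one rank bind the *same* physical
patch — the derivation workflow predicts the perimeters of the largest
patches, and ranking PERIM bounds by perimeter instead would effectively
cap every patch at the smallest bound (the k-th highest perimeter must not
exceed the k-th bound), which makes derived target sets infeasible that
their own reference landscape satisfies.  A target with no matching patch
scores deviation = value.

Optimization is sequential: the *focus* is always the first unsatisfied
objective in list order.  A proposed swap is accepted iff

1. no objective before the focus leaves its tolerance band, and
2. the focus deviation strictly decreases, **or** it is unchanged and a
   secondary potential strictly decreases:
   * for rank-matched patch targets, the group's total deviation — rank
     deviations are order statistics, and when two patches tie at the focus
     value no single swap can strictly reduce the statistic even though the
     configuration is improvable;
   * for NP and TE, the class's aggregation potential `sum(sqrt(area))` —
     it strictly falls when mass concentrates, which lets stranded compact
     patches evaporate into larger ones when no one-cell bridge exists and
     claws back edge slack before new patches are seeded;
   * at the third level, the landscape's total edge (every class) —
     shape smoothing frees slack under pinned edge bounds so that later
     cell transfers (each of which can cost +2 segments between compact
     patches) stay payable; smoothing moves for non-focus classes are
     proposed at a low rate for exactly this purpose.

The triple (focus deviation, secondary, tertiary) decreases strictly and
lexicographically on every acceptance, so the search cannot random-walk and
the focus deviation is monotone non-increasing between focus changes.  The
plain strict-decrease rule (without the tie-break chain) is exposed as
`acceptance_rule` and is what the deviation semantics are defined by; the
tie-break only ever accepts deviation-*preserving* moves, never worsening
ones.  Pure strict decrease was evaluated first and deadlocks on three
reproducible plateau classes (tied order statistics; stranded compact
patches; transfers at a pinned edge bound), which is why the chain exists.

After every acceptance the focus retreats to the first unsatisfied
objective, so later phases that disturb an earlier objective hand control
back to it.

## Proposal kernels

Acceptance is indifferent to how a proposal was produced, so proposal
design affects speed only.  A configurable fraction (default 0.9) of
proposals is metric-aware; the rest use the uniform kernel (`propose_swap`,
uniform over ordered pairs of swappable differing-class cells by rejection
sampling):

* **NP too high** — relocate a singleton next to another patch, or place a
  *bridge* cell adjacent to two distinct patches while eroding the smallest
  patch (so small patches are consumed while bridges still exist);
  with no bridge available, propose pure concentration moves.
* **NP too low** — seed a cell with no same-class neighbors, taken from a
  low-exposure donor; interleaved concentration moves recover the edge
  cost.
* **TE / PERIM over bound** — move a low-exposure cell (few same-class
  neighbors) into a notch (many same-class neighbors), within the focal
  patch for PERIM, from any donor patch for class-level TE.
* **AREA off target** — transfer cells between the rank-matched focus patch
  and the patch with the most (growth) or least (shrink) slack relative to
  its own matched target; attach sites are chosen notch-first so growing
  patches stay near-square, plus occasional smoothing moves.
* **ECON off target** — swap contrast-class against other-class cells along
  the focal patch's boundary.

Site selection is greedy (deepest notch, most exposed tip) with a 30%
uniform-exploration mix; pure greed can re-propose a single vetoed move
indefinitely when a cross-class constraint rejects it.

Stalls (`stall_limit` proposals without an acceptance, default 50 000)
trigger a restart: the non-fixed cells are reshuffled — a fresh percolation
start — with a seed derived from (seed, restart index).  A run that
exhausts `restarts` or `max_proposals` reports `stalled` with the full
per-objective report; failure is an expected outcome of tight target sets,
not an exception.

## Objective order in the series builders

Order is user-controlled and matters.  The builders emit: PLAND, then edge
bounds (TE), then patch counts (NP, best-connected class first), then AREA
ranks (largest first).  Driving total edge down first consolidates the
percolation soup into a few compact patches while patch counts are still
unconstrained; NP then seeds or merges patches inside the edge slack; AREA
redistributes cells between compact patches.  The reverse order (NP before
TE) was evaluated and is structurally worse: merging patches first builds
dendritic shapes whose within-patch smoothing is invisible to every
objective that is then active.

## Incremental state

`incremental_update` applies a swap and updates the patch labeling and
adjacency tallies by relabeling only the two touched classes (splits into
up to four components and multi-patch merges are exact) and by an O(1)
local recount of the segments incident to the two cells.  Canonical patch
numbering (ascending class, scan order within class) makes the result
bit-identical to a full recomputation, which the test suite and the
optimizer's `verify_incremental` mode assert after every accepted swap.
The optimizer's own cache works the same way: a swap invalidates exactly
the two touched classes.

## Synthetic data and what the tests show

No external data is used anywhere.  Test inputs are (a) named fixture
patterns with hand-derivable metrics (uniform, checkerboard, centered
square block), (b) seeded random rasters up to 12 x 12 with up to 4 classes
and optional NODATA holes, against brute-force oracles, and (c) percolation
maps as optimizer starting points, which is exactly the initial condition
the generation workflows specify.  The reference landscape in the
recreation round trip is itself generated (three classes, 30 x 30, patch
counts 4/4/5, shaped by patch counts only so its boundaries keep the
roughness of real land-use mosaics — references that come out near-compact
are redrawn, because an edge-minimal reference leaves the recreation no
total-edge slack and real landscapes are not edge-minimal) and labeled
synthetic; it emulates the *structure* of a real mountain land-use mosaic
(a few dominant patches per class, a patch-size distribution spanning two
orders of magnitude) but none of its terrain-driven anisotropy —
ridgelines, valley corridors, elevation belts.  Not every percolation start
converges on a tight derived target set; like the original workflow, the
round trip screens repeat attempts and reports the attempt count.  Success on these tests
shows the machinery is correct and the workflows are solvable at reduced
scale; it does not show that recreated real landscapes match in metrics the
targets do not constrain.

## Problem sizes and defaults

The published series designs run on 50 x 50 grids; the bundled acceptance
checks run the full 16-configuration series-1 sweep at 30 x 30 and the
calibration instance (PLAND 35/65, 5 patches, TE at 150% of the compact
bound) at 25 x 25, sizes at which a configuration typically completes in
seconds on one core.  Reduced scale makes the instances *harder* per patch
(edge slack scales with sqrt(area)), so success there is conservative.
Generation runs in the tests and the acceptance script use
`max_proposals = 3*10^5`, `stall_limit = 8000`, `restarts = 8–10`; the
library defaults (`2*10^6 / 5*10^4 / 3`) are sized for 50 x 50 runs.
Tolerances: AREA targets carry the series' 1-percent-point band; integer
metrics default to tolerance 0; all comparisons use an absolute epsilon of
1e-9.

## Validation statistics

Repeat runs of one target set differ (the search is stochastic), so
recreated landscapes are summarized by 95% confidence intervals of each
metric over repeats (t-based by default; switchable to normal).  The
scaled deviation of a reference value is its distance to the nearest CI
bound as a percentage of the spread of the reference values, signed
negative when the recreated values lie below the reference — zero when the
reference falls inside the interval.  Accuracy and precision of the
generator for one metric are read from an OLS regression of repeat means on
reference values: accurate when the 95% CI of the slope contains 1 and that
of the intercept contains 0; precision is the r².  Because those CIs are
95% intervals, a faithful generator still fails each flag 5% of the time by
construction — the harness scores flags individually, not jointly.

## Known limitations

* The acceptance tie-break chain is a design choice of this implementation;
  other rules (e.g. accepting deviation-preserving random walks) would
  explore differently and may reach targets this rule stalls on.
* ARBB/PBB targets are evaluated and enforced but have no guided kernel;
  optimizing them relies on uniform proposals and is slow.
* ECON targets with tolerance 0 are rarely exactly attainable; give them a
  band.
* Eight-neighbor adjacency, weighted (non-binary) edge contrast,
  core-area/contagion/fractal metrics and landscape-level aggregate metrics
  are out of scope.
* Runtime grows steeply with grid size (each proposal relabels two classes,
  and acceptance rates fall as targets tighten); 100 x 100 multi-class
  recreations are feasible but take hours, consistent with the method's
  known cost profile.
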