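# landgen

A target-driven neutral landscape model for landscape ecology and spatial
ecological simulation.  `landgen` generates categorical raster landscapes
whose class- and patch-level pattern metrics match user-specified target
values, by iteratively swapping pairs of raster cells and accepting swaps
that move the landscape closer to the objectives.

Classical neutral landscape models (percolation maps, midpoint-displacement
surfaces) are controlled by a few landscape-level parameters, which makes it
hard to reproduce the pattern of a specific real landscape or to vary one
pattern property of one land-use class while holding everything else fixed.
`landgen` instead takes an ordered list of metric targets —

| Metric | Level | Meaning |
|---|---|---|
| PLAND | class | percent of the landscape occupied |
| NP | class | number of patches (rook / four-neighbor delineation) |
| TE | class | maximum total edge, in cell-side segments |
| AREA | patch | patch size, percent of its class |
| PERIM | patch | maximum patch perimeter, in segments |
| ECON | patch | percent of the patch perimeter adjacent to a contrast class |
| ARBB / PBB | patch | bounding-box aspect ratio / fill proportion |

— and runs a sequential multiobjective search: the first unsatisfied
objective drives the search, a swap is accepted only if it strictly improves
that objective (or preserves it while strictly improving a documented
tie-break potential) without breaking any earlier objective.  Composition is
conserved exactly by construction, failures (infeasible or stalled searches)
are first-class reported outcomes, and every run is seed-reproducible.

The package also implements the surrounding workflows:

* **recreation** — derive targets from a reference landscape's summary
  statistics: patch counts and edge bounds from PD/ED densities, sizes of a
  random draw of large patches, and their perimeters predicted from a
  log–log perimeter~area regression;
* **landscape series** — two fully parameterized 16-configuration series
  (patch count x largest-patch dominance; focal-patch perimeter x
  class adjacency) for simulation experiments;
* **validation** — 95% confidence intervals over repeated runs,
  spread-scaled deviations from reference values, and slope/intercept
  accuracy regressions;
* **evaluation metrics** — PD, ED, LPI, SHAPE_MN, ENN_MN/CV, ECON_MN,
  CLUMPY, IJI, AI, NLSI for comparing landscapes.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Generate one landscape of the first series — two land uses (35% / 65%),
nine class-1 patches with one dominant patch, total edge capped at 120% of
the square-patch bound — on a 30 x 30 grid:

```python
import landgen as lg

obj = lg.series1_targets(9, 4, grid=(30, 30))
raster = lg.percolation_map(30, 30, obj.pland_proportions(), seed=42)
res = lg.optimize(raster, obj, lg.OptimizerConfig(seed=42,
                  max_proposals=300_000, stall_limit=8_000, restarts=8))
```

The run prints (`res.objectives`, formatted):

```
status: success | proposals: 1125 | accepted swaps: 434
  PLAND LU1: target 35 -> achieved 35.00 (deviation 0.00)
  PLAND LU2: target 65 -> achieved 65.00 (deviation 0.00)
  TE LU1: target 165 -> achieved 160.00 (deviation 0.00)
  NP LU2: target 1 -> achieved 1.00 (deviation 0.00)
  NP LU1: target 9 -> achieved 9.00 (deviation 0.00)
  AREA LU1 p0: target 87 -> achieved 86.98 (deviation 0.02)
  AREA LU1 p4: target 2 -> achieved 1.59 (deviation 0.41)
  ...
class-1 patch areas: [274, 7, 7, 6, 5, 4, 4, 4, 4]
```

Reading this: the percolation start already fixes PLAND exactly (swaps
conserve composition).  The search then drove class-1 total edge under its
bound of 165 segments (achieved 160), merged class 2 into a single patch and
class 1 into exactly nine, and redistributed cells until the dominant patch
held 86.98% of the class (target 87 ± 1) with the eight small patches inside
their 2 ± 1 percent bands.  On the paper-scale 50 x 50 grid the same design
yields the published input settings (total edge 267, dominant patch 89).

The same run from the command line:

```bash
landgen series1 --n-patches 9 --level 4 --grid 30 30 --out demo/
landgen generate --targets demo/series1_np9_level4.txt \
    --out-raster demo/out.asc --report demo/report.json --seed 42
```

`generate` exits 0 on success, 1 on infeasible/stalled (report still
written), 2 on usage errors.  Other subcommands: `batch`, `metrics`,
`series2`, `derive-targets`, `validate`, `fixtures`.

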