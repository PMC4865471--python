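"""Construct objective lists: reference-landscape derivation and series designs.

Two workflows are covered:

* *recreation* — turn class-level densities (PD, ED) and a per-patch
  area/perimeter table measured on a reference landscape into generator
  targets (patch counts, total-edge bounds, and the sizes/perimeters of a few
  randomly drawn large patches, with perimeters predicted from a log-log
  area~perimeter regression);
* *series* — two fully parameterized landscape-series designs on a square
  grid: series 1 varies the patch count and the dominance of the largest
  patch of one class; series 2 varies the perimeter of a single focal patch
  and its adjacency to a second class.

Unit convention: one cell = one area unit; the density conversions expose a
``cell_size`` parameter for rasters whose cells are e.g. 1 ha.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .objectives import ObjectiveList, TargetSpec

__all__ = [
    "ReferencePatchTable",
    "RegressionFit",
    "np_te_from_densities",
    "fit_loglog_area_perim",
    "draw_top_patches",
    "series1_targets",
    "series2_targets",
    "recreation_targets",
    "SERIES_LEVELS",
    "SERIES1_NP",
    "SERIES2_ECON",
]

SERIES_LEVELS = (1, 2, 3, 4)
SERIES1_NP = (3, 9, 15, 21)
SERIES2_ECON = (15, 35, 55, 75)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ReferencePatchTable:
    """Per-patch (class, AREA, PERIM) summary of a reference landscape."""

    frame: pd.DataFrame  # columns: class_code, area, perim

    def __post_init__(self):
        need = {"class_code", "area", "perim"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"patch table needs columns {sorted(need)}")
        if (self.frame["area"] <= 0).any() or (self.frame["perim"] <= 0).any():
            raise ValueError("patch areas and perimeters must be positive")

    def for_class(self, class_code: int) -> pd.DataFrame:
        return self.frame[self.frame["class_code"] == class_code]

    @classmethod
    def from_labeling(cls, labeling) -> "ReferencePatchTable":
        rows = [
            {"class_code": p.class_code, "area": p.area, "perim": p.perimeter}
            for p in labeling.patches
        ]
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log(PERIM) = intercept + slope * log(AREA)."""

    intercept: float
    slope: float
    r_squared: float
    se_intercept: float
    se_slope: float

    def predict_perimeter(self, area: float) -> float:
        return math.exp(self.intercept) * area**self.slope


def np_te_from_densities(
    pd_value: float, ed_value: float, area: float
) -> tuple[int, float]:
    """Patch count and total edge implied by densities over a total area.

    ``pd_value`` and ``ed_value`` are per 100 area units; NP = round(pd *
    area / 100) (half-up), TE likewise.  A PD that rounds to zero patches is
    floored at one patch (with a warning): a class that is present must form
    at least one patch.
    """
    if pd_value < 0 or ed_value < 0 or area < 0:
        raise ValueError("densities and area must be >= 0")
    n_patches = _round_half_up(pd_value * area / 100.0)
    if n_patches == 0 and pd_value > 0:
        warnings.warn(
            "patch density rounds to 0 patches; flooring NP at 1", stacklevel=2
        )
        n_patches = 1
    te = float(_round_half_up(ed_value * area / 100.0))
    return n_patches, te


def fit_loglog_area_perim(
    table: ReferencePatchTable, class_code: int
) -> RegressionFit:
    """Ordinary least squares on (log AREA, log PERIM) pairs of one class."""
    sub = table.for_class(class_code)
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 patches of class {class_code} for the regression"
        )
    x = np.log(sub["area"].to_numpy(dtype=float))
    y = np.log(sub["perim"].to_numpy(dtype=float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
    )


def draw_top_patches(
    table: ReferencePatchTable,
    class_code: int,
    n_patches: int,
    k: int = 3,
    min_area_pct: float = 2.0,
    seed: int | np.random.Generator = 0,
    fit: RegressionFit | None = None,
) -> list[tuple[float, float]]:
    """Seeded draw of the k largest of ``n_patches`` random reference patches.

    Draws ``n_patches`` patches of the class without replacement (with
    replacement, logged via warning, only when the class has fewer patches),
    keeps the drawn patches whose area exceeds ``min_area_pct`` percent of
    the class's total area, and returns the ``k`` largest as (AREA,
    predicted PERIM) pairs, largest first, with perimeters taken from the
    log-log regression.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = table.for_class(class_code)
    if sub.empty:
        raise ValueError(f"no patches of class {class_code} in the table")
    if n_patches < k:
        raise ValueError("n_patches must be >= k")
    areas = sub["area"].to_numpy(dtype=float)
    replace = n_patches > len(areas)
    if replace:
        warnings.warn(
            "drawing with replacement: NP exceeds available patches", stacklevel=2
        )
    drawn = rng.choice(areas, size=n_patches, replace=replace)
    floor = min_area_pct / 100.0 * areas.sum()
    kept = np.sort(drawn[drawn > floor])[::-1]
    if kept.size == 0:
        raise ValueError(
            f"no drawn patch exceeds the {min_area_pct}% area floor; "
            "targets would be infeasible"
        )
    if fit is None:
        fit = fit_loglog_area_perim(table, class_code)
    top = kept[: min(k, kept.size)]
    return [(float(a), fit.predict_perimeter(float(a))) for a in top]


def _series_class_cells(grid: tuple[int, int], pland: tuple[float, ...]) -> list[int]:
    """Exact per-class cell counts via largest-remainder apportionment."""
    from .raster import _apportion

    n = grid[0] * grid[1]
    props = {i + 1: p / 100.0 for i, p in enumerate(pland)}
    counts = _apportion(props, n)
    return [counts[i + 1] for i in range(len(pland))]


def _largest_patch_area(a_class: int, n_patches: int, level: int) -> float:
    """Largest-patch area for a dominance level in 1..4.

    Level 1: all patches equal.  Level 4: the largest patch takes 90% of the
    area it would have if every other patch occupied a single cell.  Levels
    2 and 3 interpolate linearly.
    """
    lo = a_class / n_patches
    hi = 0.9 * (a_class - (n_patches - 1))
    return lo + (level - 1) / 3.0 * (hi - lo)


def series1_patch_areas(
    n_patches: int, level: int, a_class: int
) -> list[int]:
    """Integer patch areas (largest first) for a series-1 configuration.

    Non-largest patches get the nearest whole number of cells; the largest
    patch absorbs the remainder so the areas sum exactly to the class area.
    """
    if n_patches == 1:
        return [a_class]
    L = _largest_patch_area(a_class, n_patches, level)
    small = _round_half_up((a_class - L) / (n_patches - 1))
    small = max(small, 1)
    largest = a_class - small * (n_patches - 1)
    # rounding the equal share up can leave the remainder below the others
    # (e.g. 875 cells over 21 equal patches); shrink the share until the
    # largest patch really is the largest
    while largest < small and small > 1:
        small -= 1
        largest = a_class - small * (n_patches - 1)
    return [largest] + [small] * (n_patches - 1)


def _square_te_bound(areas: list[int], factor: float) -> int:
    """Total-edge bound: ``factor`` times the summed square-patch perimeters."""
    return _round_half_up(factor * sum(4.0 * math.sqrt(a) for a in areas))


def series1_targets(
    n_patches: int,
    level: int,
    grid: tuple[int, int] = (50, 50),
    pland: tuple[float, float] = (35.0, 65.0),
    te_factor: float = 1.2,
    area_tolerance: float = 1.0,
) -> ObjectiveList:
    """Series-1 design: two classes, variable NP and largest-patch dominance.

    Class 1 holds ``pland[0]`` percent of the grid in ``n_patches`` patches
    whose size distribution is set by ``level`` (1 = all equal, 4 = one
    dominant patch); class 2 is a single patch.  AREA targets are percent of
    the class, rounded to integers, with a 1-percent-point tolerance; the
    class-1 total edge is bounded at 120% of the summed perimeters the
    patches would have as perfect squares.

    The emitted order is PLAND, NP (dominant class first), the TE bound,
    then AREA (largest first); order drives the sequential optimizer and
    this one proved the most reliable (see docs/methods.md).
    """
    if n_patches not in SERIES1_NP:
        raise ValueError(f"n_patches must be one of {SERIES1_NP}")
    if level not in SERIES_LEVELS:
        raise ValueError(f"level must be one of {SERIES_LEVELS}")
    cells = _series_class_cells(grid, pland)
    a1 = cells[0]
    areas = series1_patch_areas(n_patches, level, a1)
    te_bound = _square_te_bound(areas, te_factor)
    # Order matters for the sequential optimizer.  The TE bound leads:
    # driving total edge down consolidates the percolation soup into a few
    # compact patches while patch counts are still unconstrained.  NP then
    # adjusts the patch count (dominant, well-connected class first) inside
    # the TE slack, and the AREA targets redistribute cells between the
    # compact patches.
    targets = [
        TargetSpec("PLAND", 1, value=float(pland[0])),
        TargetSpec("PLAND", 2, value=float(pland[1])),
        TargetSpec("TE", 1, value=float(te_bound), bound="max"),
        TargetSpec("NP", 2, value=1.0),
        TargetSpec("NP", 1, value=float(n_patches)),
    ]
    for rank, a in enumerate(areas):
        pct = _round_half_up(100.0 * a / a1)
        targets.append(
            TargetSpec(
                "AREA", 1, value=float(pct), tolerance=area_tolerance, patch_rank=rank
            )
        )
    return ObjectiveList(targets=targets, grid=grid)


def series2_targets(
    perim_level: int,
    econ: float,
    grid: tuple[int, int] = (50, 50),
    pland: tuple[float, float, float] = (25.0, 40.0, 35.0),
    econ_tolerance: float = 0.0,
) -> ObjectiveList:
    """Series-2 design: focal-patch perimeter versus class-1/class-2 adjacency.

    Class 1 is a single patch whose perimeter bound ranges from 130% of a
    square patch (level 1) to 90% of a one-cell-wide line (level 4), with
    levels 2 and 3 at equal intervals (nearest-integer rounding).  Class 2
    forms 10 patches with total edge bounded at 200% of ten equal square
    patches.  The focal patch's edge contrast against class 2 is the ``econ``
    percentage.  On the default 50x50 grid the perimeter levels are 130, 462,
    795 and 1127 and the class-2 edge bound is 800.
    """
    if perim_level not in SERIES_LEVELS:
        raise ValueError(f"perim_level must be one of {SERIES_LEVELS}")
    if econ not in SERIES2_ECON:
        raise ValueError(f"econ must be one of {SERIES2_ECON}")
    cells = _series_class_cells(grid, pland)
    a1, a2 = cells[0], cells[1]
    lo = 1.3 * 4.0 * math.sqrt(a1)
    hi = 0.9 * (2.0 * a1 + 2.0)
    perim_bound = _round_half_up(lo + (perim_level - 1) / 3.0 * (hi - lo))
    n2 = 10
    te2 = _round_half_up(2.0 * n2 * 4.0 * math.sqrt(a2 / n2))
    targets = [
        TargetSpec("PLAND", 1, value=float(pland[0])),
        TargetSpec("PLAND", 2, value=float(pland[1])),
        TargetSpec("PLAND", 3, value=float(pland[2])),
        TargetSpec("NP", 2, value=float(n2)),
        TargetSpec("NP", 1, value=1.0),
        TargetSpec("PERIM", 1, value=float(perim_bound), patch_rank=0, bound="max"),
        TargetSpec("TE", 2, value=float(te2), bound="max"),
        TargetSpec(
            "ECON", 1, value=float(econ), tolerance=econ_tolerance, patch_rank=0
        ),
    ]
    return ObjectiveList(targets=targets, grid=grid, contrast=(1, 2))


def recreation_targets(
    pland: dict[int, float],
    pd_values: dict[int, float],
    ed_values: dict[int, float],
    area: float,
    table: ReferencePatchTable,
    seed: int | np.random.Generator = 0,
    grid: tuple[int, int] | None = None,
    k: int = 3,
    area_tolerance: float = 1.0,
) -> ObjectiveList:
    """Targets for recreating a reference landscape's pattern.

    For each class: PLAND, NP (from PD), a TE bound (from ED), and the AREA
    (percent of class) and predicted PERIM of the ``k`` largest of NP randomly
    drawn reference patches.  ``area`` is the total landscape area in the
    units the densities refer to.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = sorted(pland)
    np_te = {c: np_te_from_densities(pd_values[c], ed_values[c], area) for c in classes}
    # emission order follows the sequential optimizer's sweet spot: edge
    # bounds first (consolidation), then patch counts for the best-connected
    # classes first, then the patch-level size/perimeter targets
    targets: list[TargetSpec] = [
        TargetSpec("PLAND", c, value=float(pland[c])) for c in classes
    ]
    targets += [
        TargetSpec("TE", c, value=np_te[c][1], bound="max") for c in classes
    ]
    targets += [
        TargetSpec("NP", c, value=float(np_te[c][0]))
        for c in sorted(classes, key=lambda c: -pland[c])
    ]
    for c in classes:
        if len(table.for_class(c)) < 3:
            # too few reference patches for the perimeter regression; the
            # class keeps its NP/TE targets but gets no patch-level ones
            warnings.warn(
                f"class {c}: fewer than 3 reference patches; skipping "
                "AREA/PERIM target derivation",
                stacklevel=2,
            )
            continue
        fit = fit_loglog_area_perim(table, c)
        class_area = float(table.for_class(c)["area"].sum())
        picks = draw_top_patches(table, c, np_te[c][0], k=k, seed=rng, fit=fit)
        for rank, (a, perim) in enumerate(picks):
            targets.append(
                TargetSpec(
                    "AREA",
                    c,
                    value=round(100.0 * a / class_area, 1),
                    tolerance=area_tolerance,
                    patch_rank=rank,
                )
            )
            targets.append(
                TargetSpec(
                    "PERIM",
                    c,
                    value=float(_round_half_up(perim)),
                    patch_rank=rank,
                    bound="max",
                )
            )
    return ObjectiveList(targets=targets, grid=grid)
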