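"""Categorical raster state and elementary spatial operations.

A landscape is a grid of integer land-use codes. All pattern metrics and the
swap-based optimizer act on :class:`LandscapeRaster`, which couples the code
grid with a per-cell *fixed* flag (cells that may never change category, e.g.
NODATA cells or land uses that are pinned when recreating a landscape around
existing features).

Patches are delineated with the four-neighbor (rook) criterion: two cells
belong to the same patch iff they share a class and are connected through a
chain of orthogonal adjacencies.  Diagonal contact does not connect patches.

Perimeter convention: every cell side that faces a different class, a NODATA
cell, or the raster boundary counts one edge segment.  This makes the total
edge of a class equal to the sum of its patch perimeters, and a k-by-k
single-class raster has perimeter 4k.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LandscapeRaster",
    "PatchInfo",
    "PatchLabeling",
    "AdjacencyTally",
    "percolation_map",
    "label_patches",
    "adjacency_tally",
    "swap_cells",
    "synth_landscape",
    "ROOK_STRUCTURE",
]

#: rook (four-neighbor) connectivity structure for scipy.ndimage.label
ROOK_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class InfeasibleCompositionError(ValueError):
    """Requested class cell counts exceed the assignable cells."""


@dataclass
class LandscapeRaster:
    """Grid of integer category codes with NODATA and a per-cell fixed flag.

    Parameters
    ----------
    codes
        rows x cols array of integer category codes (>= 0), or
        ``nodata_code`` for NODATA cells.
    fixed
        rows x cols booleans; True cells never change category.  NODATA
        cells are forced to fixed.  Defaults to all-False (plus NODATA).
    cell_size
        Side length of a cell in map units (1-ha cells => cell_size 1 with
        areas expressed in ha).
    nodata_code
        Reserved integer code for NODATA cells (default -1).
    """

    codes: np.ndarray
    fixed: np.ndarray | None = None
    cell_size: float = 1.0
    nodata_code: int = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2 or self.codes.size < 1:
            raise ValueError("codes must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.fixed is None:
            self.fixed = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.fixed = np.array(self.fixed, dtype=bool)
            if self.fixed.shape != self.codes.shape:
                raise ValueError("fixed mask shape must match codes shape")
        # NODATA cells are always fixed
        self.fixed |= self.codes == self.nodata_code
        if np.any((self.codes < 0) & (self.codes != self.nodata_code)):
            raise ValueError("category codes must be >= 0 (or the NODATA code)")

    @property
    def rows(self) -> int:
        return self.codes.shape[0]

    @property
    def cols(self) -> int:
        return self.codes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-NODATA cells."""
        return self.codes != self.nodata_code

    @property
    def swappable(self) -> np.ndarray:
        """Boolean mask of cells the optimizer may change (non-fixed)."""
        return ~self.fixed

    def classes(self) -> list[int]:
        """Sorted category codes present (NODATA excluded)."""
        vals = np.unique(self.codes)
        return [int(v) for v in vals if v != self.nodata_code]

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.count_nonzero(self.codes == c)) for c in self.classes()}

    def copy(self) -> "LandscapeRaster":
        return LandscapeRaster(
            self.codes.copy(), self.fixed.copy(), self.cell_size, self.nodata_code
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandscapeRaster):
            return NotImplemented
        return (
            self.codes.shape == other.codes.shape
            and bool(np.array_equal(self.codes, other.codes))
            and bool(np.array_equal(self.fixed, other.fixed))
            and self.cell_size == other.cell_size
            and self.nodata_code == other.nodata_code
        )


@dataclass(frozen=True)
class PatchInfo:
    """One rook-connected patch: id, class, area, perimeter, bounding box."""

    patch_id: int
    class_code: int
    area: int  # cell count
    perimeter: int  # edge segments (boundary/NODATA sides included)
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), inclusive

    @property
    def bbox_rows(self) -> int:
        return self.bbox[1] - self.bbox[0] + 1

    @property
    def bbox_cols(self) -> int:
        return self.bbox[3] - self.bbox[2] + 1


@dataclass
class PatchLabeling:
    """Result of four-neighbor patch delineation.

    ``labels`` holds a positive patch id per cell (0 on NODATA); ids are
    assigned per class in ascending class order, scan order within a class,
    so the labeling is a pure function of the raster.
    """

    labels: np.ndarray
    patches: list[PatchInfo]
    class_labels: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def patches_of(self, class_code: int) -> list[PatchInfo]:
        return [p for p in self.patches if p.class_code == class_code]

    def n_patches(self, class_code: int) -> int:
        return sum(1 for p in self.patches if p.class_code == class_code)


def _apportion(proportions: dict[int, float], n: int) -> dict[int, int]:
    """Largest-remainder apportionment of n cells among classes.

    Ties in the fractional remainders are broken by ascending class code, so
    the split is deterministic.
    """
    items = sorted(proportions.items())
    for c, p in items:
        if p < 0:
            raise ValueError(f"negative proportion for class {c}: {p}")
    total = sum(p for _, p in items)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {total})")
    quotas = [(c, p * n) for c, p in items]
    counts = {c: int(math.floor(q)) for c, q in quotas}
    short = n - sum(counts.values())
    # distribute the remainder to the largest fractional parts
    order = sorted(quotas, key=lambda cq: (-(cq[1] - math.floor(cq[1])), cq[0]))
    for c, _ in order[:short]:
        counts[c] += 1
    return counts


def percolation_map(
    rows: int,
    cols: int,
    proportions: dict[int, float],
    seed: int | np.random.Generator,
    template: LandscapeRaster | None = None,
    cell_size: float = 1.0,
) -> LandscapeRaster:
    """Random landscape with exact per-class cell counts.

    Each assignable cell gets a category drawn so that the final count per
    class equals the largest-remainder apportionment of ``proportion x
    assignable cells`` — counts are exact, not expected values, which makes
    PLAND targets exactly attainable (cell swaps conserve composition).

    When a ``template`` is given, only its non-fixed cells are (re)assigned;
    fixed and NODATA cells pass through untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if template is not None:
        out = template.copy()
        assign = np.flatnonzero(out.swappable)
    else:
        out = LandscapeRaster(
            np.zeros((rows, cols), dtype=np.int32), cell_size=cell_size
        )
        assign = np.arange(rows * cols)
    n = assign.size
    counts = _apportion(proportions, n)
    if sum(counts.values()) > n:
        raise InfeasibleCompositionError("class cells exceed assignable cells")
    fill = np.concatenate(
        [np.full(k, c, dtype=np.int32) for c, k in sorted(counts.items())]
    ) if counts else np.empty(0, dtype=np.int32)
    perm = rng.permutation(n)
    flat = out.codes.ravel()
    flat[assign[perm]] = fill
    out.codes = flat.reshape(out.shape)
    return out


def _neighbor_mismatch_counts(labels: np.ndarray) -> np.ndarray:
    """Per-cell count of sides facing a different label or the boundary."""
    padded = np.pad(labels, 1, constant_values=-1)
    center = padded[1:-1, 1:-1]
    out = np.zeros(labels.shape, dtype=np.int32)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        out += (nb != center).astype(np.int32)
    return out


def label_patches(raster: LandscapeRaster) -> PatchLabeling:
    """Four-neighbor connected components per class, with patch summaries.

    Per-patch perimeter counts every cell side adjacent to a different class,
    NODATA, or the raster boundary.  An all-NODATA raster yields an empty
    patch list.
    """
    labels = np.zeros(raster.shape, dtype=np.int32)
    class_labels: dict[int, np.ndarray] = {}
    patches: list[PatchInfo] = []
    offset = 0
    per_cell_perim: np.ndarray | None = None
    for c in raster.classes():
        mask = raster.codes == c
        sub, n = ndimage.label(mask, structure=ROOK_STRUCTURE)
        sub = sub.astype(np.int32)
        class_labels[c] = sub
        labels[mask] = sub[mask] + offset
        if n:
            if per_cell_perim is None:
                per_cell_perim = _neighbor_mismatch_counts_for(raster)
            areas = np.bincount(sub[mask], minlength=n + 1)[1:]
            perims = np.bincount(
                sub[mask], weights=per_cell_perim[mask], minlength=n + 1
            )[1:].astype(np.int64)
            slices = ndimage.find_objects(sub, max_label=n)
            for i in range(n):
                sl = slices[i]
                patches.append(
                    PatchInfo(
                        patch_id=offset + i + 1,
                        class_code=c,
                        area=int(areas[i]),
                        perimeter=int(perims[i]),
                        bbox=(
                            sl[0].start,
                            sl[0].stop - 1,
                            sl[1].start,
                            sl[1].stop - 1,
                        ),
                    )
                )
        offset += n
    return PatchLabeling(labels=labels, patches=patches, class_labels=class_labels)


def _neighbor_mismatch_counts_for(raster: LandscapeRaster) -> np.ndarray:
    """Per-cell count of sides facing another class, NODATA or the boundary."""
    # NODATA cells carry the nodata code, which differs from every class code,
    # and the pad value differs from everything, so one pass suffices.
    return _neighbor_mismatch_counts(raster.codes)


@dataclass
class AdjacencyTally:
    """Edge-segment bookkeeping for a raster.

    ``pairs[(a, b)]`` (a <= b) counts interior orthogonal cell pairs whose two
    cells hold classes a and b — each pair of cells contributes exactly one
    segment.  ``boundary[c]`` counts class-c cell sides on the raster boundary
    or facing NODATA.
    """

    pairs: dict[tuple[int, int], int]
    boundary: dict[int, int]

    def get(self, a: int, b: int) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.pairs.get(key, 0)

    def like(self, c: int) -> int:
        """Like-adjacency segment count g_cc (single count)."""
        return self.pairs.get((c, c), 0)

    def total_segments(self) -> int:
        return sum(self.pairs.values()) + sum(self.boundary.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencyTally):
            return NotImplemented
        strip = lambda d: {k: v for k, v in d.items() if v}
        return strip(self.pairs) == strip(other.pairs) and strip(
            self.boundary
        ) == strip(other.boundary)


def adjacency_tally(raster: LandscapeRaster) -> AdjacencyTally:
    """Count interior class/class edge segments and per-class boundary sides."""
    codes = raster.codes
    nodata = raster.nodata_code
    pairs: dict[tuple[int, int], int] = {}
    # horizontal and vertical interior pairs
    for a, b in ((codes[:, :-1], codes[:, 1:]), (codes[:-1, :], codes[1:, :])):
        lo = np.minimum(a, b).ravel()
        hi = np.maximum(a, b).ravel()
        keep = lo != nodata  # NODATA contacts are tallied as boundary below
        keys, counts = np.unique(
            np.stack([lo[keep], hi[keep]], axis=1), axis=0, return_counts=True
        ) if np.any(keep) else (np.empty((0, 2), int), np.empty(0, int))
        for (a_, b_), n in zip(keys, counts):
            pairs[(int(a_), int(b_))] = pairs.get((int(a_), int(b_)), 0) + int(n)
    # boundary: raster edge sides plus sides facing NODATA
    padded = np.pad(codes, 1, constant_values=nodata)
    boundary: dict[int, int] = {}
    center = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        hit = (nb == nodata) & (center != nodata)
        if np.any(hit):
            cls, cnt = np.unique(center[hit], return_counts=True)
            for c, n in zip(cls, cnt):
                boundary[int(c)] = boundary.get(int(c), 0) + int(n)
    return AdjacencyTally(pairs=pairs, boundary=boundary)


class SwapContractError(ValueError):
    """A swap touched a fixed or NODATA cell."""


class NoOpSwapError(ValueError):
    """Both cells hold the same category; the swap would be a no-op."""


def swap_cells(
    raster: LandscapeRaster,
    cell_a: tuple[int, int],
    cell_b: tuple[int, int],
) -> LandscapeRaster:
    """Return a new raster with the two cells' category codes exchanged.

    Swapping conserves composition (the multiset of codes is unchanged) and is
    an involution.  Fixed or NODATA cells may not be swapped; equal categories
    are rejected as a no-op.
    """
    for cell in (cell_a, cell_b):
        if raster.fixed[cell]:
            raise SwapContractError(f"cell {cell} is fixed or NODATA")
    ca, cb = raster.codes[cell_a], raster.codes[cell_b]
    if ca == cb:
        raise NoOpSwapError(f"cells {cell_a} and {cell_b} share category {int(ca)}")
    out = raster.copy()
    out.codes[cell_a], out.codes[cell_b] = cb, ca
    return out


def synth_landscape(
    pattern: str,
    rows: int = 10,
    cols: int = 10,
    seed: int = 0,
    **params,
) -> LandscapeRaster:
    """Deterministic fixture landscapes with documented metric values.

    Patterns
    --------
    uniform
        Single class (``code``, default 1) everywhere; PLAND 100, one patch,
        perimeter 2(rows+cols).
    checkerboard
        Alternating codes (1, 2); every cell is its own patch under rook
        adjacency.
    square_block
        A ``block``-sized square of ``fg`` (default 1) centered in ``bg``
        (default 2); the block patch has perimeter 4*block.
    random
        Percolation map with ``proportions`` (default {1: 0.5, 2: 0.5}).
    """
    if pattern == "uniform":
        code = params.get("code", 1)
        return LandscapeRaster(np.full((rows, cols), code, dtype=np.int32))
    if pattern == "checkerboard":
        r, c = np.indices((rows, cols))
        codes = np.where((r + c) % 2 == 0, 1, 2).astype(np.int32)
        return LandscapeRaster(codes)
    if pattern == "square_block":
        block = params.get("block")
        if block is None or block > min(rows, cols):
            raise ValueError("square_block requires block <= min(rows, cols)")
        fg, bg = params.get("fg", 1), params.get("bg", 2)
        codes = np.full((rows, cols), bg, dtype=np.int32)
        r0 = (rows - block) // 2
        c0 = (cols - block) // 2
        codes[r0 : r0 + block, c0 : c0 + block] = fg
        return LandscapeRaster(codes)
    if pattern == "random":
        proportions = params.get("proportions", {1: 0.5, 2: 0.5})
        return percolation_map(rows, cols, proportions, seed)
    raise ValueError(f"unknown synthetic pattern: {pattern!r}")
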