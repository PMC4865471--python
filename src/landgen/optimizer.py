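"""Sequential multiobjective optimization by random cell-pair swaps.

The generator starts from an input raster (typically a percolation map, or a
real landscape with fixed cells) and repeatedly swaps pairs of non-fixed
cells.  Objectives are pursued *sequentially* in list order: at any moment a
single *focus* objective — the first unsatisfied one — drives the search, and
a swap is accepted iff it strictly reduces the focus objective's deviation
without knocking any earlier objective out of its tolerance band.  After an
acceptance the focus retreats to the first unsatisfied objective, so earlier
objectives are re-entered whenever a later move disturbed them.

Swaps conserve composition exactly, so PLAND targets must hold at
initialization (a conflicting PLAND target makes the run infeasible
immediately) and are invariant afterwards.

Proposals mix the uniform kernel :func:`propose_swap` with metric-aware
guided moves (bridging patches to cut NP, notch-filling transfers to cut
TE/PERIM, donor-to-focus-patch transfers for AREA targets, boundary-class
swaps for ECON); the acceptance rule is indifferent to how a proposal was
produced, so the guidance only affects speed, never the invariants.  When no
proposal is accepted for ``stall_limit`` tries the non-fixed cells are
reshuffled (a fresh percolation start with a derived seed) up to ``restarts``
times; a run that exhausts its budgets reports ``stalled`` — failure is a
first-class outcome, not an exception.
"""
from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .objectives import (
    ObjectiveList,
    ObjectiveStatus,
    evaluate_objectives,
)
from .raster import (
    ROOK_STRUCTURE,
    AdjacencyTally,
    LandscapeRaster,
    PatchLabeling,
    label_patches,
    swap_cells,
)

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "optimize",
    "propose_swap",
    "acceptance_rule",
    "incremental_update",
    "batch_generate",
    "NoLegalPairError",
]

_EPS = 1e-9
_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


class NoLegalPairError(RuntimeError):
    """No pair of swappable cells with differing categories exists."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Search budgets and reproducibility knobs.

    ``stall_limit`` proposals without an acceptance trigger a restart
    (reshuffle of the non-fixed cells with a seed derived from ``seed`` and
    the restart index); after ``restarts`` restarts the run reports stalled.
    ``verify_incremental`` cross-checks the incrementally maintained state
    against a full recomputation after every accepted swap (used by the test
    suite; expensive).
    """

    seed: int = 0
    max_proposals: int = 2_000_000
    stall_limit: int = 50_000
    restarts: int = 3
    guided_fraction: float = 0.9
    verbose: bool = False
    verify_incremental: bool = False
    collect_trace: bool = False

    def __post_init__(self):
        if self.max_proposals <= 0 or self.stall_limit <= 0 or self.restarts < 0:
            raise ValueError("budgets must be positive")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0.0 <= self.guided_fraction <= 1.0:
            raise ValueError("guided_fraction must be in [0, 1]")


@dataclass
class OptimizationResult:
    raster: LandscapeRaster
    status: str  # success | infeasible | stalled
    objectives: list[ObjectiveStatus]
    proposals: int
    acceptances: int
    seed: int
    proposals_per_objective: list[int]
    restarts_used: int = 0
    message: str = ""
    #: per-acceptance records (proposal index, focus index, deviation before,
    #: deviation after) when config.collect_trace is set
    trace: list[tuple[int, int, float, float]] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.status == "success"

    def report(self) -> dict:
        """JSON-serializable run report."""
        return {
            "status": self.status,
            "seed": self.seed,
            "proposals": self.proposals,
            "acceptances": self.acceptances,
            "restarts_used": self.restarts_used,
            "message": self.message,
            "objectives": [
                {
                    "metric": s.target.metric,
                    "class": s.target.class_code,
                    "patch_rank": s.target.patch_rank,
                    "value": s.target.value,
                    "tolerance": s.target.tolerance,
                    "bound": s.target.bound,
                    "achieved": s.achieved,
                    "deviation": s.deviation,
                    "satisfied": s.satisfied,
                    "proposals": p,
                }
                for s, p in zip(self.objectives, self.proposals_per_objective)
            ],
        }


def propose_swap(
    raster: LandscapeRaster, rng: np.random.Generator
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Uniform proposal over ordered pairs of swappable, differing-class cells.

    Rejection sampling: two independent uniform draws from the swappable
    cells, redrawn until the categories differ; never returns fixed or
    NODATA cells.  Raises :class:`NoLegalPairError` when the swappable cells
    hold fewer than two categories.
    """
    idx = np.flatnonzero(raster.swappable)
    if idx.size < 2 or np.unique(raster.codes.ravel()[idx]).size < 2:
        raise NoLegalPairError("no two swappable cells with differing categories")
    flat = raster.codes.ravel()
    cols = raster.cols
    while True:
        i, j = idx[rng.integers(0, idx.size, size=2)]
        if flat[i] != flat[j]:
            return (int(i) // cols, int(i) % cols), (int(j) // cols, int(j) % cols)


def acceptance_rule(
    objectives: ObjectiveList,
    deviations_before: list[float],
    deviations_after: list[float],
    focus_index: int,
) -> tuple[bool, int]:
    """Strict-improvement lexicographic acceptance.

    Accept iff the focus objective's deviation strictly decreases and no
    objective before the focus leaves its tolerance band.  The new focus is
    the first unsatisfied objective of the resulting deviations (past the end
    when all are satisfied).
    """
    tols = [t.tolerance for t in objectives.targets]
    after = deviations_after
    accept = after[focus_index] < deviations_before[focus_index] - _EPS and all(
        after[i] <= tols[i] + _EPS for i in range(focus_index)
    )
    ref = after if accept else deviations_before
    new_focus = next(
        (i for i, d in enumerate(ref) if d > tols[i] + _EPS), len(ref)
    )
    return accept, new_focus


# ---------------------------------------------------------------------------
# incremental state maintenance


def _incident_segments(
    codes: np.ndarray, nodata: int, cells: list[tuple[int, int]]
) -> tuple[collections.Counter, collections.Counter]:
    """Tally contributions of all segments incident to the given cells.

    Returns (pair segment counter keyed (lo, hi), boundary side counter per
    class), with the segment between two listed cells counted once.
    """
    rows, cols = codes.shape
    pairs: collections.Counter = collections.Counter()
    boundary: collections.Counter = collections.Counter()
    cellset = set(cells)
    seen = set()
    for r, c in cells:
        v = int(codes[r, c])
        for dr, dc in _DIRS:
            nr, nc_ = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc_ < cols:
                key = ((r, c), (nr, nc_)) if (r, c) < (nr, nc_) else ((nr, nc_), (r, c))
                if (nr, nc_) in cellset and key in seen:
                    continue
                seen.add(key)
                w = int(codes[nr, nc_])
                if v == nodata and w == nodata:
                    continue
                if v == nodata:
                    boundary[w] += 1
                elif w == nodata:
                    boundary[v] += 1
                else:
                    pairs[(min(v, w), max(v, w))] += 1
            elif v != nodata:
                boundary[v] += 1
    return pairs, boundary


def incremental_update(
    raster: LandscapeRaster,
    labeling: PatchLabeling,
    tally: AdjacencyTally,
    cell_a: tuple[int, int],
    cell_b: tuple[int, int],
) -> tuple[LandscapeRaster, PatchLabeling, AdjacencyTally]:
    """Apply a swap and update labeling and adjacency tallies incrementally.

    Only the two classes the swap touches are relabeled (a swapped-out cell
    may split its former patch into up to four components; a swapped-in cell
    may merge several); all other classes' patch summaries are reused.  The
    adjacency tally is updated from the segments incident to the two cells.
    The result equals a full recomputation on the post-swap raster.
    """
    pre_pairs, pre_bound = _incident_segments(
        raster.codes, raster.nodata_code, [cell_a, cell_b]
    )
    post = swap_cells(raster, cell_a, cell_b)
    post_pairs, post_bound = _incident_segments(
        post.codes, post.nodata_code, [cell_a, cell_b]
    )
    pairs = dict(tally.pairs)
    for key, n in pre_pairs.items():
        pairs[key] = pairs.get(key, 0) - n
    for key, n in post_pairs.items():
        pairs[key] = pairs.get(key, 0) + n
    boundary = dict(tally.boundary)
    for c, n in pre_bound.items():
        boundary[c] = boundary.get(c, 0) - n
    for c, n in post_bound.items():
        boundary[c] = boundary.get(c, 0) + n
    new_tally = AdjacencyTally(
        pairs={k: v for k, v in pairs.items() if v},
        boundary={k: v for k, v in boundary.items() if v},
    )

    touched = {int(raster.codes[cell_a]), int(raster.codes[cell_b])}
    from .raster import PatchInfo, _neighbor_mismatch_counts_for

    per_cell_perim = None
    labels = np.zeros(post.shape, dtype=np.int32)
    class_labels: dict[int, np.ndarray] = {}
    patches: list[PatchInfo] = []
    offset = 0
    for c in post.classes():
        mask = post.codes == c
        if c in touched or c not in labeling.class_labels:
            sub, n = ndimage.label(mask, structure=ROOK_STRUCTURE)
            sub = sub.astype(np.int32)
            if n and per_cell_perim is None:
                per_cell_perim = _neighbor_mismatch_counts_for(post)
            areas = np.bincount(sub[mask], minlength=n + 1)[1:] if n else []
            perims = (
                np.bincount(sub[mask], weights=per_cell_perim[mask], minlength=n + 1)[
                    1:
                ].astype(np.int64)
                if n
                else []
            )
            slices = ndimage.find_objects(sub, max_label=n)
            infos = [
                PatchInfo(
                    patch_id=offset + i + 1,
                    class_code=c,
                    area=int(areas[i]),
                    perimeter=int(perims[i]),
                    bbox=(
                        slices[i][0].start,
                        slices[i][0].stop - 1,
                        slices[i][1].start,
                        slices[i][1].stop - 1,
                    ),
                )
                for i in range(n)
            ]
        else:
            sub = labeling.class_labels[c]
            old = labeling.patches_of(c)
            n = len(old)
            infos = [
                PatchInfo(
                    patch_id=offset + i + 1,
                    class_code=c,
                    area=p.area,
                    perimeter=p.perimeter,
                    bbox=p.bbox,
                )
                for i, p in enumerate(old)
            ]
        class_labels[c] = sub
        labels[mask] = sub[mask] + offset
        patches.extend(infos)
        offset += n
    return post, PatchLabeling(labels, patches, class_labels), new_tally


# ---------------------------------------------------------------------------
# engine


class _ClassStats:
    """Lazily computed per-class state the evaluator and kernels read."""

    __slots__ = ("mask", "labels", "n", "areas", "_te", "_perims", "_nb", "_slices")

    def __init__(self, mask: np.ndarray):
        self.mask = mask
        sub, n = ndimage.label(mask, structure=ROOK_STRUCTURE)
        self.labels = sub.astype(np.int32)
        self.n = int(n)
        self.areas = (
            np.bincount(self.labels[mask], minlength=n + 1)[1:]
            if n
            else np.zeros(0, dtype=np.int64)
        )
        self._te = None
        self._perims = None
        self._nb = None
        self._slices = None

    def te(self) -> int:
        if self._te is None:
            mask = self.mask
            pad = np.pad(mask, 1, constant_values=False)
            te = 0
            for dr, dc in _DIRS:
                nb = pad[1 + dr : pad.shape[0] - 1 + dr, 1 + dc : pad.shape[1] - 1 + dc]
                te += int(np.count_nonzero(mask & ~nb))
            self._te = te
        return self._te

    def perims(self) -> np.ndarray:
        if self._perims is None:
            mask, labels = self.mask, self.labels
            pad = np.pad(labels, 1, constant_values=0)
            out = np.zeros(self.n + 1, dtype=np.int64)
            for dr, dc in _DIRS:
                nb = pad[1 + dr : pad.shape[0] - 1 + dr, 1 + dc : pad.shape[1] - 1 + dc]
                edge = mask & (nb != labels)
                np.add.at(out, labels[edge], 1)
            self._perims = out[1:]
        return self._perims

    def neighbor_info(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(m, nbmax, multi): per cell, the count of rook neighbors inside the
        class, the largest neighboring patch label (0 if none), and whether
        two distinct patches neighbor the cell."""
        if self._nb is None:
            pad = np.pad(self.labels, 1, constant_values=0)
            shifts = [
                pad[1 + dr : pad.shape[0] - 1 + dr, 1 + dc : pad.shape[1] - 1 + dc]
                for dr, dc in _DIRS
            ]
            m = sum((s > 0).astype(np.int8) for s in shifts)
            nbmax = np.maximum.reduce(shifts)
            multi = np.zeros(self.labels.shape, dtype=bool)
            for s in shifts:
                multi |= (s > 0) & (s != nbmax)
            self._nb = (m, nbmax, multi)
        return self._nb

    def slices_for(self) -> list:
        if self._slices is None:
            self._slices = ndimage.find_objects(self.labels, max_label=self.n)
        return self._slices


class _Engine:
    """Mutable optimization state with per-class caches."""

    def __init__(self, raster: LandscapeRaster, objectives: ObjectiveList):
        self.raster = raster
        self.codes = raster.codes
        self.swappable = raster.swappable
        self.nodata = raster.nodata_code
        self.objectives = objectives
        self.n_valid = int(np.count_nonzero(raster.valid))
        self.counts = dict(raster.class_counts())
        self.cache: dict[int, _ClassStats] = {}
        self.version = 0
        # rank order of patch-level targets within each (metric, class) group
        self.group_rank: dict[int, int] = {}
        self.groups: dict[tuple[str, int], list[int]] = {}
        for i, t in enumerate(objectives.targets):
            if t.patch_rank is not None:
                self.groups.setdefault((t.metric, t.class_code), []).append(i)
        for key, idxs in self.groups.items():
            order = sorted(idxs, key=lambda i: -objectives.targets[i].value)
            self.groups[key] = order
            for rank, i in enumerate(order):
                self.group_rank[i] = rank

    def stats(self, c: int) -> _ClassStats:
        st = self.cache.get(c)
        if st is None:
            st = _ClassStats(self.codes == c)
            self.cache[c] = st
        return st

    # -- evaluation --------------------------------------------------------

    def _contrast_partner(self, c: int) -> int:
        a, b = self.objectives.contrast
        return b if c == a else a

    def _patch_achieved(self, idx: int) -> float | None:
        t = self.objectives.targets[idx]
        st = self.stats(t.class_code)
        rank = self.group_rank[idx]
        if rank >= st.n:
            return None
        order = np.argsort(-st.areas, kind="stable")
        lab = int(order[rank]) + 1
        if t.metric == "AREA":
            return 100.0 * float(st.areas[lab - 1]) / self.counts[t.class_code]
        if t.metric == "PERIM":
            return float(st.perims()[lab - 1])
        if t.metric == "ECON":
            k = self._contrast_partner(t.class_code)
            pad = np.pad(self.codes, 1, constant_values=self.nodata)
            seg = 0
            cells = st.labels == lab
            for dr, dc in _DIRS:
                nb = pad[1 + dr : pad.shape[0] - 1 + dr, 1 + dc : pad.shape[1] - 1 + dc]
                seg += int(np.count_nonzero(cells & (nb == k)))
            return 100.0 * seg / float(st.perims()[lab - 1])
        sl = st.slices_for()[lab - 1]
        br = sl[0].stop - sl[0].start
        bc = sl[1].stop - sl[1].start
        if t.metric == "ARBB":
            return max(br, bc) / min(br, bc)
        return float(st.areas[lab - 1]) / (br * bc)  # PBB

    def achieved(self, idx: int) -> float | None:
        t = self.objectives.targets[idx]
        if t.patch_rank is not None:
            return self._patch_achieved(idx)
        c = t.class_code
        if t.metric == "PLAND":
            return 100.0 * self.counts.get(c, 0) / self.n_valid
        st = self.stats(c)
        if t.metric == "NP":
            return float(st.n)
        return float(st.te())  # TE

    def deviation(self, idx: int) -> float:
        t = self.objectives.targets[idx]
        a = self.achieved(idx)
        if a is None:
            return float(t.value)
        if t.bound == "max":
            return max(0.0, a - t.value)
        return abs(a - t.value)

    def deviations(self, upto: int | None = None) -> list[float]:
        n = len(self.objectives.targets) if upto is None else upto + 1
        return [self.deviation(i) for i in range(n)]

    def first_unsatisfied(self, devs: list[float]) -> int:
        tols = [t.tolerance for t in self.objectives.targets]
        return next(
            (i for i, d in enumerate(devs) if d > tols[i] + _EPS), len(devs)
        )

    # -- mutation ----------------------------------------------------------

    def apply(self, a: tuple[int, int], b: tuple[int, int]) -> dict:
        ca, cb = int(self.codes[a]), int(self.codes[b])
        saved = {ca: self.cache.pop(ca, None), cb: self.cache.pop(cb, None)}
        self.codes[a], self.codes[b] = cb, ca
        return {"cells": (a, b), "saved": saved}

    def revert(self, token: dict) -> None:
        a, b = token["cells"]
        self.codes[a], self.codes[b] = self.codes[b], self.codes[a]
        for c, st in token["saved"].items():
            if st is None:
                self.cache.pop(c, None)
            else:
                self.cache[c] = st

    def commit(self) -> None:
        self.version += 1

    def reshuffle(self, rng: np.random.Generator) -> None:
        vals = self.codes[self.swappable]
        rng.shuffle(vals)
        self.codes[self.swappable] = vals
        self.cache.clear()
        self.version += 1


def _pick(rng: np.random.Generator, mask: np.ndarray, weights: np.ndarray | None = None):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    if weights is None:
        return int(idx[rng.integers(idx.size)])
    w = weights.ravel()[idx].astype(float)
    tot = w.sum()
    if tot <= 0:
        return int(idx[rng.integers(idx.size)])
    return int(rng.choice(idx, p=w / tot))


def _pick_best(rng: np.random.Generator, mask: np.ndarray, score: np.ndarray):
    """Uniform choice among the mask cells attaining the best (max) score.

    Greedy site selection keeps growing patches near-square (fill the
    deepest notch first, peel the most exposed tip first), which is what
    keeps total edge close to its compact bound without a dedicated
    smoothing pass.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    s = score.ravel()[idx]
    if rng.random() < 0.3:
        # exploration: a purely greedy pick can re-propose one vetoed move
        # forever when a cross-class constraint rejects it
        return int(idx[rng.integers(idx.size)])
    best = idx[s == s.max()]
    return int(best[rng.integers(best.size)])


def _unflat(i: int, cols: int) -> tuple[int, int]:
    return i // cols, i % cols



class _Guide:
    """Metric-aware proposal kernels; pure speed, no effect on acceptance."""

    def __init__(self, engine: _Engine):
        self.e = engine

    def propose(self, focus: int, rng: np.random.Generator):
        e = self.e
        t = e.objectives.targets[focus]
        c = t.class_code
        dev = e.deviation(focus)
        if dev <= t.tolerance + _EPS:
            return None
        # occasional smoothing of any class: deviation-preserving swaps that
        # cut total edge rebuild the slack that pinned edge bounds consume
        if rng.random() < 0.15:
            classes = list(e.counts)
            other = classes[rng.integers(len(classes))]
            pair = self._compaction(other, rng, None)
            if pair is not None:
                return pair
        try:
            if t.metric == "NP":
                ach = e.achieved(focus)
                return (
                    self._np_decrease(c, rng)
                    if ach > t.value
                    else self._np_increase(c, rng)
                )
            if t.metric == "TE":
                return self._compaction(c, rng, None)
            if t.metric == "PERIM":
                lab = self._ranked_label(focus)
                return self._compaction(c, rng, lab) if lab else None
            if t.metric == "AREA":
                return self._area(focus, rng)
            if t.metric == "ECON":
                return self._econ(focus, rng)
        except (IndexError, KeyError):
            return None
        return None  # PLAND (infeasible anyway), ARBB/PBB: uniform fallback

    def _ranked_label(self, idx: int) -> int | None:
        e = self.e
        st = e.stats(e.objectives.targets[idx].class_code)
        rank = e.group_rank[idx]
        if rank >= st.n:
            return None
        return int(np.argsort(-st.areas, kind="stable")[rank]) + 1

    def _np_decrease(self, c: int, rng):
        e = self.e
        st = e.stats(c)
        if st.n <= 1:
            return None
        m, nbmax, multi = st.neighbor_info()
        S = e.swappable
        other = ~st.mask & S & (e.codes != e.nodata)
        single_mask = st.mask & S
        if st.n and np.any(st.areas == 1):
            singles = single_mask & np.isin(st.labels, np.flatnonzero(st.areas == 1) + 1)
            a = _pick(rng, singles)
            if a is not None:
                la = int(st.labels.ravel()[a])
                b = _pick(rng, other & (m >= 1) & (multi | (nbmax != la)))
                if b is not None:
                    return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])
        b = _pick(rng, other & multi)
        if b is None:
            # no bridge site: erode the smallest patch onto the largest
            # (patch count is preserved, but the move concentrates mass and
            # is accepted through the aggregation-potential tie-break until
            # the remnant becomes a relocatable singleton)
            return self._concentrate(c, rng)
        # donate from the smallest patch: consuming small patches while
        # bridges still exist leaves singletons that can be relocate-killed,
        # instead of stranding compact remnants with no neighbors
        a = None
        for L in np.argsort(st.areas, kind="stable") + 1:
            cand = single_mask & (st.labels == L)
            a = _pick(rng, cand & (m <= 1))
            if a is None:
                a = _pick(rng, cand & (m <= 2))
            if a is not None:
                break
        if a is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])

    def _np_increase(self, c: int, rng):
        e = self.e
        st = e.stats(c)
        m, _, _ = st.neighbor_info()
        S = e.swappable
        # seeding a new patch costs a little total edge; interleave
        # concentration moves that claw that slack back from small patches
        if rng.random() < 0.4:
            pair = self._concentrate(c, rng)
            if pair is not None:
                return pair
        b = _pick(rng, ~st.mask & S & (e.codes != e.nodata) & (m == 0))
        if b is None:
            return None
        big = np.isin(st.labels, np.flatnonzero(st.areas >= 2) + 1)
        a = _pick(rng, st.mask & S & big & (m <= 1))
        if a is None:
            a = _pick(rng, st.mask & S & big & (m <= 2))
        if a is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])

    def _concentrate(self, c: int, rng):
        """Move a tip cell of the smallest (multi-cell) patch into a notch of
        the largest patch; the swap preserves NP and total edge but strictly
        lowers the aggregation potential."""
        e = self.e
        st = e.stats(c)
        if st.n < 2:
            return None
        m, nbmax, multi = st.neighbor_info()
        S = e.swappable
        big = int(np.argmax(st.areas)) + 1
        b = _pick_best(
            rng,
            ~st.mask & S & (e.codes != e.nodata) & (m >= 1) & ~multi & (nbmax == big),
            m,
        )
        if b is None:
            return None
        a = None
        for L in np.argsort(st.areas, kind="stable") + 1:
            if int(L) == big or st.areas[L - 1] < 2:
                continue
            cand = st.mask & S & (st.labels == L)
            a = _pick_best(rng, cand & (m <= 2), -m)
            if a is not None:
                break
        if a is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])

    def _compaction(self, c: int, rng, only_label: int | None):
        """Within-patch transfer that fills a notch (m high) from a protrusion
        (m low); strictly reduces perimeter when the donor side is more
        exposed than the receiving side."""
        e = self.e
        st = e.stats(c)
        m, nbmax, multi = st.neighbor_info()
        S = e.swappable
        bmask = ~st.mask & S & (e.codes != e.nodata) & (m >= 2) & ~multi
        if only_label is not None:
            bmask &= nbmax == only_label
        b = _pick_best(rng, bmask, m)
        if b is None:
            return None
        lab = int(nbmax.ravel()[b])
        mb = int(m.ravel()[b])
        # a focal-patch PERIM move keeps the transfer within the patch (its
        # area likely sits in an AREA band); class-level TE may take the
        # donor cell from any patch — AREA bands are earlier objectives and
        # the acceptance check protects them
        if only_label is not None:
            amask = (st.labels == lab) & S & (m <= mb)
        else:
            amask = st.mask & S & (m <= mb)
        a = _pick_best(rng, amask, -m)
        if a is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])

    def _area(self, idx: int, rng):
        e = self.e
        t = e.objectives.targets[idx]
        c = t.class_code
        st = e.stats(c)
        # transfers between compact patches cost edge; mix in smoothing
        # moves that repay it (accepted through the total-edge tie-break)
        if rng.random() < 0.25:
            pair = self._compaction(c, rng, None)
            if pair is not None:
                return pair
        rank = e.group_rank[idx]
        if rank >= st.n:  # missing patch: seed a new one in isolation
            m, _, _ = st.neighbor_info()
            b = _pick(rng, ~st.mask & e.swappable & (e.codes != e.nodata) & (m == 0))
            a = _pick(rng, st.mask & e.swappable & (m <= 1))
            if a is None or b is None:
                return None
            return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])
        order = np.argsort(-st.areas, kind="stable")
        lab = int(order[rank]) + 1
        achieved = 100.0 * float(st.areas[lab - 1]) / e.counts[c]
        m, nbmax, multi = st.neighbor_info()
        S = e.swappable
        grow = achieved < t.value
        # slack of every other patch relative to the target its rank matches
        # (patches beyond the target list are pure surplus); a growth move
        # takes a cell from the slackest patch, a shrink move gives one to
        # the neediest, which keeps earlier-ranked patches inside their bands
        group = e.groups[("AREA", c)]
        slack = []  # (slack vs matched target, label, area, constrained?)
        for r in range(st.n):
            if r == rank:
                continue
            L = int(order[r]) + 1
            a_cells = float(st.areas[L - 1])
            constrained = r < len(group)
            tgt = (
                e.objectives.targets[group[r]].value / 100.0 * e.counts[c]
                if constrained
                else 0.0
            )
            slack.append((a_cells - tgt, L, a_cells, constrained))
        if not slack:
            return None
        if grow:
            donors = [s for s in slack if s[2] >= 2]
            if not donors:
                return None
            donor = max(donors)[1]
            b = _pick_best(rng, ~st.mask & S & (e.codes != e.nodata) & (m >= 1)
                           & ~multi & (nbmax == lab), m)
            if b is None:
                return None
            a = _pick_best(rng, (st.labels == donor) & S & (m <= 2), -m)
        else:
            # shed cells onto a patch no target constrains when one exists
            # (its size is free); otherwise onto the neediest matched patch
            surplus = [s for s in slack if not s[3]]
            accept_lab = max(surplus)[1] if surplus else min(slack)[1]
            b = _pick_best(rng, ~st.mask & S & (e.codes != e.nodata) & (m >= 1)
                           & ~multi & (nbmax == accept_lab), m)
            if b is None:
                return None
            a = _pick_best(rng, (st.labels == lab) & S & (m <= 2), -m)
        if a is None or b is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])

    def _econ(self, idx: int, rng):
        e = self.e
        t = e.objectives.targets[idx]
        c = t.class_code
        k = e._contrast_partner(c)
        st = e.stats(c)
        lab = self._ranked_label(idx)
        if lab is None:
            return None
        achieved = e._patch_achieved(idx)
        if achieved is None:
            return None
        m, nbmax, multi = st.neighbor_info()
        adj = (m >= 1) & ((nbmax == lab) | multi) & ~st.mask & (e.codes != e.nodata)
        S = e.swappable
        other = (e.codes != c) & (e.codes != k) & (e.codes != e.nodata)
        if achieved < t.value:  # swap a non-contrast neighbor for a contrast cell
            a = _pick(rng, adj & S & other)
            b = _pick(rng, (e.codes == k) & S & ~adj)
        else:
            a = _pick(rng, adj & S & (e.codes == k))
            b = _pick(rng, other & S & ~adj)
        if a is None or b is None:
            return None
        return _unflat(a, e.codes.shape[1]), _unflat(b, e.codes.shape[1])


def _verify_state(engine: _Engine, raster: LandscapeRaster) -> None:
    """Cross-check cached per-class state against a full recomputation."""
    fresh = label_patches(raster)
    for c, st in engine.cache.items():
        sub, n = ndimage.label(raster.codes == c, structure=ROOK_STRUCTURE)
        assert st.n == n, f"class {c}: cached NP {st.n} != recomputed {n}"
        assert np.array_equal(st.labels, sub.astype(np.int32)), (
            f"class {c}: cached labels diverged from recomputation"
        )
        areas = np.bincount(sub[raster.codes == c], minlength=n + 1)[1:]
        assert np.array_equal(st.areas, areas)
        if st._te is not None:
            te = sum(p.perimeter for p in fresh.patches_of(c))
            assert st.te() == te, f"class {c}: cached TE {st.te()} != {te}"


def optimize(
    raster: LandscapeRaster,
    objectives: ObjectiveList,
    config: OptimizerConfig | None = None,
) -> OptimizationResult:
    """Run the sequential swap search until success or exhausted budgets.

    The input raster is not modified.  Results are a pure function of
    (raster, objectives, config.seed): the same call yields the identical
    final raster and report.
    """
    config = config or OptimizerConfig()
    if objectives.grid is not None and objectives.grid != raster.shape:
        raise ValueError(
            f"objectives declare grid {objectives.grid}, raster is {raster.shape}"
        )
    work = raster.copy()
    engine = _Engine(work, objectives)
    guide = _Guide(engine)
    rng = np.random.default_rng(config.seed)
    n_targets = len(objectives.targets)
    per_objective = [0] * n_targets

    trace: list[tuple[int, int, float, float]] = []

    def finish(status: str, proposals: int, acceptances: int, restarts_used: int,
               message: str = "") -> OptimizationResult:
        statuses = evaluate_objectives(work, None, objectives)
        if status != "infeasible" and all(s.satisfied for s in statuses):
            status = "success"
        return OptimizationResult(
            raster=work,
            status=status,
            objectives=statuses,
            proposals=proposals,
            acceptances=acceptances,
            seed=config.seed,
            proposals_per_objective=per_objective,
            restarts_used=restarts_used,
            message=message,
            trace=trace,
        )

    # PLAND feasibility: swaps conserve composition, so a violated PLAND
    # target can never be repaired.
    for i, t in enumerate(objectives.targets):
        if t.metric == "PLAND":
            a = engine.achieved(i)
            if abs(a - t.value) > t.tolerance + _EPS:
                return finish(
                    "infeasible", 0, 0, 0,
                    f"PLAND target {t.value} for class {t.class_code} conflicts "
                    f"with the composition ({a:.3f}); swaps conserve composition",
                )

    if n_targets == 0:
        return finish("success", 0, 0, 0)

    devs = engine.deviations()
    focus = engine.first_unsatisfied(devs)
    proposals = acceptances = 0
    since_accept = 0
    restarts_used = 0

    while focus < n_targets and proposals < config.max_proposals:
        if since_accept >= config.stall_limit:
            if restarts_used >= config.restarts:
                return finish(
                    "stalled", proposals, acceptances, restarts_used,
                    f"no acceptance within {config.stall_limit} proposals",
                )
            restarts_used += 1
            rs = np.random.default_rng(
                np.random.SeedSequence([config.seed, restarts_used])
            )
            engine.reshuffle(rs)
            devs = engine.deviations()
            focus = engine.first_unsatisfied(devs)
            since_accept = 0
            continue

        pair = None
        if rng.random() < config.guided_fraction:
            pair = guide.propose(focus, rng)
        if pair is None:
            try:
                pair = propose_swap(work, rng)
            except NoLegalPairError:
                return finish(
                    "stalled", proposals, acceptances, restarts_used,
                    "no legal swap pair exists",
                )
        proposals += 1
        per_objective[focus] += 1
        since_accept += 1

        a, b = pair
        if work.codes[a] == work.codes[b]:  # guided kernels may race ranks
            continue
        focus_target = objectives.targets[focus]
        group = (
            engine.groups.get((focus_target.metric, focus_target.class_code))
            if focus_target.patch_rank is not None
            else None
        )
        # Tie-break potentials for deviation-preserving moves (see below):
        # the group's total deviation for rank-matched patch targets or the
        # class's aggregation potential sum(sqrt(area)) for NP/TE, then the
        # class's total edge.
        def _potential() -> tuple[float, float]:
            st = engine.stats(focus_target.class_code)
            first = (
                sum(engine.deviation(i) for i in group)
                if group
                else float(np.sqrt(st.areas).sum())
            )
            total_te = float(sum(engine.stats(c).te() for c in engine.counts))
            return first, total_te

        pot_before = _potential()
        token = engine.apply(a, b)
        after = engine.deviations(upto=focus)
        tols = [t.tolerance for t in objectives.targets]
        earlier_ok = all(after[i] <= tols[i] + _EPS for i in range(focus))
        ok = earlier_ok and after[focus] < devs[focus] - _EPS
        if not ok and earlier_ok and after[focus] <= devs[focus] + _EPS:
            # Strict decrease alone deadlocks on plateaus: rank-matched
            # targets are order statistics (tied patch sizes pin them),
            # integer NP/TE cannot change when stranded compact patches have
            # no single-swap merge, and transfers between compact patches
            # cost edge that a bound at its limit cannot pay.  Deviation-
            # preserving moves are therefore accepted when they strictly
            # reduce a lexicographic potential: the group's total deviation
            # (patch targets) or the aggregation potential sum(sqrt(area))
            # (NP/TE; falls when mass concentrates, so stranded patches can
            # evaporate into larger ones), then the class's total edge
            # (shape smoothing frees slack under a TE bound).  The triple
            # (focus deviation, potential) decreases strictly on every
            # acceptance, so the search cannot random-walk and the focus
            # deviation stays monotone.
            pot_after = _potential()
            ok = pot_after[0] < pot_before[0] - _EPS or (
                pot_after[0] <= pot_before[0] + _EPS
                and pot_after[1] < pot_before[1] - _EPS
            )
        if ok:
            engine.commit()
            acceptances += 1
            since_accept = 0
            if config.collect_trace:
                trace.append((proposals, focus, devs[focus], after[focus]))
            if config.verify_incremental:
                _verify_state(engine, work)
            devs = engine.deviations()
            focus = engine.first_unsatisfied(devs)
        else:
            engine.revert(token)

    if focus >= n_targets:
        return finish("success", proposals, acceptances, restarts_used)
    return finish(
        "stalled", proposals, acceptances, restarts_used,
        f"proposal budget {config.max_proposals} exhausted",
    )


def _run_job(job) -> OptimizationResult:
    raster, objectives, config = job
    return optimize(raster, objectives, config)


def batch_generate(jobs, workers: int = 1) -> list[OptimizationResult]:
    """Run many (raster, objectives, config) jobs; order-preserving.

    Each job carries its own seed, so results are independent of the worker
    count and scheduling.  Failed jobs are reported in their result status,
    never raised.
    """
    jobs = list(jobs)
    if not jobs:
        return []
    if workers <= 1:
        return [_run_job(j) for j in jobs]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=workers)(delayed(_run_job)(j) for j in jobs)
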