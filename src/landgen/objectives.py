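"""Ordered metric targets and their evaluation against a landscape.

A target list drives the sequential optimizer: objectives are pursued in
list order, so the order is preserved exactly as given (it can decide
whether and how fast an optimization converges).

Targets file grammar, one entry per line::

    # comment (ignored)
    GRID <rows> <cols>
    CONTRAST <classA> <classB>
    <METRIC> <CLASS> [<PATCH_RANK>] <VALUE> [<TOLERANCE>]

``METRIC`` is one of PLAND, NP, TE (class level) or AREA, PERIM, ECON, ARBB,
PBB (patch level; these take a patch rank, 0 = largest target).  ``VALUE`` is
in the metric's units (percent for PLAND/AREA/ECON, counts for NP, edge
segments for TE/PERIM).  ``TOLERANCE`` is absolute in the same units and
defaults to 0.  TE and PERIM are upper bounds ("maximum total edge" / "patch
maximum perimeter"); all other metrics are equality-with-tolerance targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import _patch_contrast_segments, class_metrics
from .raster import LandscapeRaster, PatchLabeling, label_patches

__all__ = [
    "CLASS_METRICS",
    "PATCH_METRICS",
    "TargetSpec",
    "ObjectiveList",
    "ObjectiveStatus",
    "parse_targets_file",
    "write_targets_file",
    "evaluate_objectives",
    "TargetsParseError",
]

CLASS_METRICS = ("PLAND", "NP", "TE")
PATCH_METRICS = ("AREA", "PERIM", "ECON", "ARBB", "PBB")
#: metrics treated as upper bounds rather than equality targets
MAX_BOUND_METRICS = ("TE", "PERIM")


class TargetsParseError(ValueError):
    """Malformed targets file; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class TargetSpec:
    """One metric objective.

    ``bound`` is ``"max"`` for upper-bound metrics (deviation is the excess
    over the value, zero when at or below it) and ``"equal"`` otherwise
    (deviation is the absolute difference).  ``patch_rank`` is present iff
    the metric is patch level; rank 0 denotes the largest target of its
    (metric, class) group.
    """

    metric: str
    class_code: int
    value: float
    tolerance: float = 0.0
    patch_rank: int | None = None
    bound: str = "equal"

    def __post_init__(self):
        if self.metric not in CLASS_METRICS + PATCH_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if (self.patch_rank is not None) != (self.metric in PATCH_METRICS):
            raise ValueError(
                f"{self.metric}: patch rank present iff the metric is patch level"
            )
        if self.patch_rank is not None and self.patch_rank < 0:
            raise ValueError("patch rank must be >= 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.bound not in ("equal", "max"):
            raise ValueError(f"bound must be 'equal' or 'max', got {self.bound!r}")

    @staticmethod
    def default_bound(metric: str) -> str:
        return "max" if metric in MAX_BOUND_METRICS else "equal"


@dataclass
class ObjectiveList:
    """Ordered targets plus grid and contrast-pair declarations."""

    targets: list[TargetSpec] = field(default_factory=list)
    grid: tuple[int, int] | None = None
    contrast: tuple[int, int] | None = None

    def __post_init__(self):
        if any(t.metric == "ECON" for t in self.targets) and self.contrast is None:
            raise ValueError("ECON targets require a CONTRAST declaration")

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets)

    def pland_proportions(self) -> dict[int, float] | None:
        """Class proportions implied by the PLAND targets, if any."""
        pland = {t.class_code: t.value / 100.0 for t in self.targets if t.metric == "PLAND"}
        return pland or None


def parse_targets_file(text: str) -> ObjectiveList:
    """Parse the targets grammar; raises :class:`TargetsParseError` on errors."""
    targets: list[TargetSpec] = []
    grid = contrast = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        key = tok[0].upper()
        try:
            if key == "GRID":
                if len(tok) != 3:
                    raise ValueError("GRID takes exactly 2 integers")
                grid = (int(tok[1]), int(tok[2]))
                continue
            if key == "CONTRAST":
                if len(tok) != 3:
                    raise ValueError("CONTRAST takes exactly 2 class codes")
                contrast = (int(tok[1]), int(tok[2]))
                continue
            if key not in CLASS_METRICS + PATCH_METRICS:
                raise ValueError(f"unknown metric keyword {tok[0]!r}")
            patch_level = key in PATCH_METRICS
            want = 2 + (1 if patch_level else 0)  # class [rank] value
            if len(tok) - 1 < want or len(tok) - 1 > want + 1:
                raise ValueError(
                    f"{key} takes CLASS{' PATCH_RANK' if patch_level else ''}"
                    " VALUE [TOLERANCE]"
                )
            class_code = int(tok[1])
            rank = int(tok[2]) if patch_level else None
            value = float(tok[3 if patch_level else 2])
            tol_idx = 4 if patch_level else 3
            tolerance = float(tok[tol_idx]) if len(tok) - 1 > want else 0.0
            targets.append(
                TargetSpec(
                    metric=key,
                    class_code=class_code,
                    value=value,
                    tolerance=tolerance,
                    patch_rank=rank,
                    bound=TargetSpec.default_bound(key),
                )
            )
        except TargetsParseError:
            raise
        except ValueError as exc:
            raise TargetsParseError(lineno, str(exc)) from exc
    try:
        return ObjectiveList(targets=targets, grid=grid, contrast=contrast)
    except ValueError as exc:
        raise TargetsParseError(0, str(exc)) from exc


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_targets_file(objectives: ObjectiveList) -> str:
    """Canonical serialization; ``parse_targets_file`` round-trips it exactly.

    Zero tolerances are omitted, numbers are printed as integers when whole.
    """
    lines = []
    if objectives.grid is not None:
        lines.append(f"GRID {objectives.grid[0]} {objectives.grid[1]}")
    if objectives.contrast is not None:
        lines.append(f"CONTRAST {objectives.contrast[0]} {objectives.contrast[1]}")
    for t in objectives.targets:
        parts = [t.metric, str(t.class_code)]
        if t.patch_rank is not None:
            parts.append(str(t.patch_rank))
        parts.append(_fmt(t.value))
        if t.tolerance:
            parts.append(_fmt(t.tolerance))
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ObjectiveStatus:
    """Achieved value, deviation and satisfaction for one target."""

    target: TargetSpec
    achieved: float | None  # None when no patch matched the rank
    deviation: float
    satisfied: bool


def _deviation(target: TargetSpec, achieved: float) -> float:
    if target.bound == "max":
        return max(0.0, achieved - target.value)
    return abs(achieved - target.value)


def evaluate_objectives(
    raster: LandscapeRaster,
    labeling: PatchLabeling | None,
    objectives: ObjectiveList,
) -> list[ObjectiveStatus]:
    """Evaluate every target against the landscape, in list order.

    Patch-level targets are matched by rank: the targets of a (metric, class)
    group sorted by value descending pair with the class's actual patches
    sorted by area descending, so e.g. the largest PERIM bound binds the
    largest patch.  A target without a matching patch (fewer patches than
    targets) scores deviation = value and is unsatisfied — a shortfall, not
    an exception.

    Evaluation is a pure function of (raster, objectives).
    """
    if labeling is None:
        labeling = label_patches(raster)
    cm = {m.class_code: m for m in class_metrics(raster, labeling)}

    # group patch-level targets to resolve rank matching
    groups: dict[tuple[str, int], list[int]] = {}
    for i, t in enumerate(objectives.targets):
        if t.patch_rank is not None:
            groups.setdefault((t.metric, t.class_code), []).append(i)

    contrast_seg: dict[int, np.ndarray] = {}

    def patch_value(metric: str, patch, class_code: int) -> float:
        if metric == "AREA":
            n = int(np.count_nonzero(raster.codes == class_code))
            return 100.0 * patch.area / n
        if metric == "PERIM":
            return float(patch.perimeter)
        if metric == "ECON":
            if class_code not in contrast_seg:
                a, b = objectives.contrast
                other = b if class_code == a else a
                contrast_seg[class_code] = _patch_contrast_segments(
                    raster, labeling, other
                )
            seg = contrast_seg[class_code]
            return 100.0 * float(seg[patch.patch_id - 1]) / patch.perimeter
        bb = (patch.bbox_rows, patch.bbox_cols)
        if metric == "ARBB":
            return max(bb) / min(bb)
        if metric == "PBB":
            return patch.area / (bb[0] * bb[1])
        raise AssertionError(metric)

    achieved: dict[int, float | None] = {}
    for (metric, class_code), idxs in groups.items():
        patches = labeling.patches_of(class_code)
        ranked = sorted(patches, key=lambda p: p.area, reverse=True)
        # targets sorted by value descending; ties keep list order
        order = sorted(idxs, key=lambda i: -objectives.targets[i].value)
        for rank, i in enumerate(order):
            achieved[i] = (
                patch_value(metric, ranked[rank], class_code)
                if rank < len(ranked)
                else None
            )

    out = []
    for i, t in enumerate(objectives.targets):
        if t.patch_rank is None:
            m = cm.get(t.class_code)
            if m is None:  # class absent entirely
                value: float | None = 0.0
            else:
                value = float(getattr(m, t.metric))
            dev = _deviation(t, value)
        else:
            value = achieved[i]
            dev = _deviation(t, value) if value is not None else float(t.value)
        out.append(
            ObjectiveStatus(
                target=t,
                achieved=value,
                deviation=dev,
                satisfied=dev <= t.tolerance + 1e-12,
            )
        )
    return out
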