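"""Class- and patch-level pattern metrics.

Two metric families are provided:

* the *target* metrics the generator can optimize toward — PLAND, NP, TE at
  class level; AREA, PERIM, ECON, ARBB/PBB at patch level;
* the *evaluation* suite used to compare real and generated landscapes —
  PD, ED, LPI, SHAPE_MN, ENN_MN, ENN_CV, ECON_MN, CLUMPY, IJI, AI, NLSI.

Conventions (fixed for this implementation and mirrored by the test oracles):

* four-neighbor (rook) patch delineation;
* patch perimeter and total edge count raster-boundary and NODATA sides;
* like-adjacency tallies (used by AI and CLUMPY) count each interior cell
  pair once and exclude boundary sides;
* edge contrast is binary: weight 1 between one designated class pair,
  0 elsewhere;
* a metric that is undefined for a class (e.g. ENN with fewer than two
  patches, IJI with fewer than three classes) is reported as ``None`` and
  excluded from means — never silently zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial.distance import cdist

from .raster import (
    AdjacencyTally,
    LandscapeRaster,
    PatchInfo,
    PatchLabeling,
    adjacency_tally,
    label_patches,
)

__all__ = [
    "ClassMetrics",
    "PatchMetrics",
    "MetricReport",
    "class_metrics",
    "patch_metrics",
    "minimal_perimeter",
    "evaluation_metrics",
]


class UndefinedMetricsError(ValueError):
    """Metrics requested on an all-NODATA raster."""


@dataclass(frozen=True)
class ClassMetrics:
    class_code: int
    PLAND: float  # % of non-NODATA landscape
    NP: int  # patch count
    TE: int  # edge segments (boundary convention included)
    PD: float  # patches per 100 area units
    ED: float  # edge length per 100 area units


@dataclass(frozen=True)
class PatchMetrics:
    patch_id: int
    class_code: int
    AREA_cells: int
    AREA_pct: float  # % of the patch's *class* cell count
    PERIM: int
    ECON: float | None  # % of perimeter adjacent to the contrast class
    ARBB: float  # bounding-box aspect ratio, long side / short side (>= 1)
    PBB: float  # patch area / bounding-box area, in (0, 1]


@dataclass(frozen=True)
class MetricReport:
    """Evaluation metrics for one class; ``None`` marks undefined values."""

    class_code: int
    PLAND: float
    NP: int
    TE: int
    PD: float
    ED: float
    LPI: float
    SHAPE_MN: float
    ENN_MN: float | None
    ENN_CV: float | None
    ECON_MN: float | None
    CLUMPY: float | None
    IJI: float | None
    AI: float | None
    NLSI: float | None

    def as_dict(self) -> dict[str, float | int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def minimal_perimeter(a: int) -> int:
    """Smallest perimeter of any rook-connected arrangement of ``a`` cells.

    With n = floor(sqrt(a)): 4n for a perfect square, 4n+2 while the extra
    cells fit along one side (a <= n(n+1)), 4n+4 beyond.  Equals the known
    closed form 2*ceil(2*sqrt(a)).
    """
    if a < 1:
        raise ValueError("area must be >= 1")
    n = math.isqrt(a)
    if n * n == a:
        return 4 * n
    if a <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def _landscape_area(raster: LandscapeRaster) -> float:
    n_valid = int(np.count_nonzero(raster.valid))
    if n_valid == 0:
        raise UndefinedMetricsError("all-NODATA raster has no defined metrics")
    return n_valid * raster.cell_size**2


def class_metrics(
    raster: LandscapeRaster, labeling: PatchLabeling | None = None
) -> list[ClassMetrics]:
    """PLAND, NP, TE, PD and ED for every class present.

    PD and ED are expressed per 100 area units (with 1-ha cells: per 100 ha),
    edge length in cell-side units (segments x cell_size).
    """
    if labeling is None:
        labeling = label_patches(raster)
    area = _landscape_area(raster)
    n_valid = int(np.count_nonzero(raster.valid))
    out = []
    for c in raster.classes():
        patches = labeling.patches_of(c)
        n_cells = int(np.count_nonzero(raster.codes == c))
        te = sum(p.perimeter for p in patches)
        out.append(
            ClassMetrics(
                class_code=c,
                PLAND=100.0 * n_cells / n_valid,
                NP=len(patches),
                TE=te,
                PD=100.0 * len(patches) / area,
                ED=100.0 * te * raster.cell_size / area,
            )
        )
    return out


def _patch_contrast_segments(
    raster: LandscapeRaster, labeling: PatchLabeling, contrast_class: int
) -> np.ndarray:
    """Per-patch count of perimeter segments facing the contrast class."""
    padded = np.pad(raster.codes, 1, constant_values=raster.nodata_code)
    lab = labeling.labels
    n = len(labeling.patches)
    out = np.zeros(n + 1, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        hit = nb == contrast_class
        np.add.at(out, lab[hit], 1)
    return out[1:]


def patch_metrics(
    raster: LandscapeRaster,
    labeling: PatchLabeling,
    patch_id: int,
    contrast_class: int | None = None,
) -> PatchMetrics:
    """Patch-level target metrics for one patch.

    ECON is the percentage of the patch's perimeter adjacent to
    ``contrast_class`` cells; sides on the raster boundary or facing NODATA
    count in the denominator only.  ``None`` when no contrast class is given.
    AREA_pct is percent of the *class's* cell count (so a class consisting of
    one patch always has AREA_pct 100 regardless of PLAND).
    """
    patch = next((p for p in labeling.patches if p.patch_id == patch_id), None)
    if patch is None:
        raise ValueError(f"no patch with id {patch_id}")
    class_cells = int(np.count_nonzero(raster.codes == patch.class_code))
    econ: float | None = None
    if contrast_class is not None:
        if contrast_class not in raster.classes() and not np.any(
            raster.codes == contrast_class
        ):
            raise ValueError(f"contrast class {contrast_class} absent from raster")
        seg = _patch_contrast_segments(raster, labeling, contrast_class)
        econ = 100.0 * float(seg[patch_id - 1]) / patch.perimeter
    bb_r, bb_c = patch.bbox_rows, patch.bbox_cols
    return PatchMetrics(
        patch_id=patch.patch_id,
        class_code=patch.class_code,
        AREA_cells=patch.area,
        AREA_pct=100.0 * patch.area / class_cells,
        PERIM=patch.perimeter,
        ECON=econ,
        ARBB=max(bb_r, bb_c) / min(bb_r, bb_c),
        PBB=patch.area / (bb_r * bb_c),
    )


def _max_like_adjacencies(a: int) -> int:
    """Largest possible single-count like-adjacency tally for ``a`` cells.

    Compact-arrangement bound: with n = floor(sqrt(a)) and m = a - n^2,
    2n(n-1) for m = 0, plus 2m-1 when m <= n, plus 2m-2 when m > n.
    """
    n = math.isqrt(a)
    m = a - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


def _enn_distances(
    raster: LandscapeRaster, patches: list[PatchInfo], labels: np.ndarray
) -> list[float]:
    """Per-patch Euclidean nearest-neighbor distance (cell centers).

    Distance from each patch to the closest cell of any *other* patch of the
    same class, in cell_size units.  Requires >= 2 patches.
    """
    coords = [
        np.argwhere(labels == p.patch_id).astype(float) for p in patches
    ]
    n = len(patches)
    dmin = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(coords[i], coords[j]).min()
            dmin[i, j] = dmin[j, i] = d
    return [float(dmin[i].min()) * raster.cell_size for i in range(n)]


def evaluation_metrics(
    raster: LandscapeRaster,
    labeling: PatchLabeling | None = None,
    contrast_pair: tuple[int, int] | None = None,
    tally: AdjacencyTally | None = None,
) -> list[MetricReport]:
    """Per-class evaluation suite for comparing landscapes.

    LPI
        Largest patch of the class as % of the non-NODATA landscape.
    SHAPE_MN
        Mean over patches of PERIM / minimal_perimeter(AREA); 1 on compact
        patches.
    ENN_MN / ENN_CV
        Mean and 100*sd/mean of per-patch nearest-neighbor distances;
        undefined with fewer than two patches.
    ECON_MN
        Mean patch edge contrast under the binary ``contrast_pair``;
        classes outside the pair score 0, undefined without a pair.
    CLUMPY
        (G - P) normalized clumpiness from the like-adjacency fraction
        G = g_ii / sum_k g_ik versus the class proportion P.
    IJI
        Evenness of the class's interior edge distribution over the other
        classes; needs >= 3 classes and at least one interior unlike edge.
    AI
        100 * g_ii / max g_ii for the class's cell count.
    NLSI
        (TE - min) / (max - min) with the compact bound minimal_perimeter(A)
        and the fully disaggregated bound 4A.
    """
    if labeling is None:
        labeling = label_patches(raster)
    if tally is None:
        tally = adjacency_tally(raster)
    classes = raster.classes()
    if not classes:
        raise UndefinedMetricsError("all-NODATA raster has no defined metrics")
    n_valid = int(np.count_nonzero(raster.valid))
    cls = {m.class_code: m for m in class_metrics(raster, labeling)}
    m_classes = len(classes)

    contrast_seg: dict[int, np.ndarray] = {}
    if contrast_pair is not None:
        a, b = contrast_pair
        contrast_seg[a] = _patch_contrast_segments(raster, labeling, b)
        contrast_seg[b] = _patch_contrast_segments(raster, labeling, a)

    reports = []
    for c in classes:
        patches = labeling.patches_of(c)
        areas = np.array([p.area for p in patches])
        a_total = int(areas.sum())
        base = cls[c]

        lpi = 100.0 * areas.max() / n_valid
        shape_mn = float(
            np.mean([p.perimeter / minimal_perimeter(p.area) for p in patches])
        )

        enn_mn = enn_cv = None
        if len(patches) >= 2:
            dists = _enn_distances(raster, patches, labeling.labels)
            enn_mn = float(np.mean(dists))
            sd = float(np.std(dists, ddof=1))
            enn_cv = 100.0 * sd / enn_mn if enn_mn > 0 else 0.0

        econ_mn = None
        if contrast_pair is not None:
            if c in contrast_seg:
                seg = contrast_seg[c]
                econ_mn = float(
                    np.mean(
                        [100.0 * seg[p.patch_id - 1] / p.perimeter for p in patches]
                    )
                )
            else:
                econ_mn = 0.0  # all contrast weights are zero for this class

        g_ii = tally.like(c)
        g_row = sum(tally.get(c, k) for k in classes)
        clumpy = None
        if g_row > 0:
            G = g_ii / g_row
            P = a_total / n_valid
            if G < P and P < 0.5:
                clumpy = (G - P) / P
            elif P < 1.0:
                clumpy = (G - P) / (1.0 - P)
            else:
                clumpy = None  # class fills the landscape; aggregation trivial

        iji = None
        if m_classes >= 3:
            e = np.array([tally.get(c, k) for k in classes if k != c], dtype=float)
            e_sum = e.sum()
            if e_sum > 0:
                p = e[e > 0] / e_sum
                iji = float(100.0 * -(p * np.log(p)).sum() / math.log(m_classes - 1))

        max_g = _max_like_adjacencies(a_total)
        ai = 100.0 * g_ii / max_g if max_g > 0 else None

        min_e = minimal_perimeter(a_total)
        max_e = 4 * a_total
        nlsi = (base.TE - min_e) / (max_e - min_e) if max_e > min_e else None

        reports.append(
            MetricReport(
                class_code=c,
                PLAND=base.PLAND,
                NP=base.NP,
                TE=base.TE,
                PD=base.PD,
                ED=base.ED,
                LPI=lpi,
                SHAPE_MN=shape_mn,
                ENN_MN=enn_mn,
                ENN_CV=enn_cv,
                ECON_MN=econ_mn,
                CLUMPY=clumpy,
                IJI=iji,
                AI=ai,
                NLSI=nlsi,
            )
        )
    return reports
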