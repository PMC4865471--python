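"""Independent brute-force reimplementations used as test oracles.

Everything here recounts metrics straight from their definitions with plain
Python loops — no code, arrays tricks or conventions shared with the package
under test (beyond the documented boundary-counting convention itself).
"""
from __future__ import annotations

import math


def flood_fill_label(codes, nodata=-1):
    """Rook-connected components per class via explicit stack flood fill.

    Returns (labels, patches) with labels[r][c] = 0 on NODATA and patch ids
    assigned in ascending class order, scan order within a class — the same
    canonical numbering the package documents.
    """
    rows, cols = len(codes), len(codes[0])
    labels = [[0] * cols for _ in range(rows)]
    patches = []
    next_id = 1
    classes = sorted({codes[r][c] for r in range(rows) for c in range(cols)}
                     - {nodata})
    for cls in classes:
        for r0 in range(rows):
            for c0 in range(cols):
                if codes[r0][c0] != cls or labels[r0][c0] != 0:
                    continue
                stack = [(r0, c0)]
                cells = []
                labels[r0][c0] = next_id
                while stack:
                    r, c = stack.pop()
                    cells.append((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = r + dr, c + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and codes[nr][nc] == cls and labels[nr][nc] == 0):
                            labels[nr][nc] = next_id
                            stack.append((nr, nc))
                perim = 0
                for r, c in cells:
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = r + dr, c + dc
                        if not (0 <= nr < rows and 0 <= nc < cols):
                            perim += 1
                        elif codes[nr][nc] != cls:
                            perim += 1
                rs = [r for r, _ in cells]
                cs = [c for _, c in cells]
                patches.append({
                    "id": next_id,
                    "class": cls,
                    "area": len(cells),
                    "perim": perim,
                    "bbox": (min(rs), max(rs), min(cs), max(cs)),
                    "cells": cells,
                })
                next_id += 1
    return labels, patches


def adjacency_counts(codes, nodata=-1):
    """Interior pair tallies and per-class boundary sides, by enumeration."""
    rows, cols = len(codes), len(codes[0])
    pairs: dict[tuple[int, int], int] = {}
    boundary: dict[int, int] = {}
    for r in range(rows):
        for c in range(cols):
            v = codes[r][c]
            for dr, dc in ((0, 1), (1, 0)):  # each interior pair once
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    w = codes[nr][nc]
                    if v == nodata and w == nodata:
                        continue
                    if v == nodata:
                        boundary[w] = boundary.get(w, 0) + 1
                    elif w == nodata:
                        boundary[v] = boundary.get(v, 0) + 1
                    else:
                        key = (min(v, w), max(v, w))
                        pairs[key] = pairs.get(key, 0) + 1
            if v != nodata:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < rows and 0 <= nc < cols):
                        boundary[v] = boundary.get(v, 0) + 1
    return pairs, boundary


def min_perimeter(a: int) -> int:
    """Closed form 2*ceil(2*sqrt(a)) — distinct expression from the package."""
    return 2 * math.ceil(2.0 * math.sqrt(a))


def class_level(codes, nodata=-1):
    """PLAND/NP/TE/PD/ED per class, recounted from definitions."""
    labels, patches = flood_fill_label(codes, nodata)
    rows, cols = len(codes), len(codes[0])
    n_valid = sum(
        1 for r in range(rows) for c in range(cols) if codes[r][c] != nodata
    )
    out = {}
    classes = sorted({p["class"] for p in patches})
    for cls in classes:
        mine = [p for p in patches if p["class"] == cls]
        n_cells = sum(p["area"] for p in mine)
        te = sum(p["perim"] for p in mine)
        out[cls] = {
            "PLAND": 100.0 * n_cells / n_valid,
            "NP": len(mine),
            "TE": te,
            "PD": 100.0 * len(mine) / n_valid,
            "ED": 100.0 * te / n_valid,
        }
    return out


def _max_like_adj(a: int) -> int:
    n = int(math.isqrt(a))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def evaluation_level(codes, nodata=-1, contrast_pair=None):
    """The evaluation metric suite, recounted from definitions.

    Undefined metrics come back as None, matching the documented policy.
    """
    labels, patches = flood_fill_label(codes, nodata)
    pairs, _ = adjacency_counts(codes, nodata)
    rows, cols = len(codes), len(codes[0])
    n_valid = sum(
        1 for r in range(rows) for c in range(cols) if codes[r][c] != nodata
    )
    classes = sorted({p["class"] for p in patches})
    m_classes = len(classes)

    def tally(a, b):
        return pairs.get((min(a, b), max(a, b)), 0)

    def patch_contrast(patch, other_cls):
        seg = 0
        for r, c in patch["cells"]:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and codes[nr][nc] == other_cls:
                    seg += 1
        return seg

    out = {}
    for cls in classes:
        mine = [p for p in patches if p["class"] == cls]
        a_total = sum(p["area"] for p in mine)
        lpi = 100.0 * max(p["area"] for p in mine) / n_valid
        shapes = [p["perim"] / min_perimeter(p["area"]) for p in mine]
        shape_mn = sum(shapes) / len(shapes)

        enn_mn = enn_cv = None
        if len(mine) >= 2:
            dists = []
            for p in mine:
                best = None
                for q in mine:
                    if q["id"] == p["id"]:
                        continue
                    for r1, c1 in p["cells"]:
                        for r2, c2 in q["cells"]:
                            d = math.hypot(r1 - r2, c1 - c2)
                            if best is None or d < best:
                                best = d
                dists.append(best)
            enn_mn = sum(dists) / len(dists)
            if len(dists) > 1:
                mean = enn_mn
                var = sum((d - mean) ** 2 for d in dists) / (len(dists) - 1)
                enn_cv = 100.0 * math.sqrt(var) / mean if mean > 0 else 0.0

        econ_mn = None
        if contrast_pair is not None:
            if cls in contrast_pair:
                other = contrast_pair[1] if cls == contrast_pair[0] else contrast_pair[0]
                econ_mn = sum(
                    100.0 * patch_contrast(p, other) / p["perim"] for p in mine
                ) / len(mine)
            else:
                econ_mn = 0.0

        g_ii = tally(cls, cls)
        g_row = sum(tally(cls, k) for k in classes)
        clumpy = None
        if g_row > 0:
            G = g_ii / g_row
            P = a_total / n_valid
            if P >= 1.0:
                clumpy = None
            elif G >= P or P >= 0.5:
                clumpy = (G - P) / (1.0 - P)
            else:
                clumpy = (G - P) / P

        iji = None
        if m_classes >= 3:
            e = [tally(cls, k) for k in classes if k != cls]
            tot = sum(e)
            if tot > 0:
                acc = 0.0
                for v in e:
                    if v > 0:
                        frac = v / tot
                        acc -= frac * math.log(frac)
                iji = 100.0 * acc / math.log(m_classes - 1)

        max_g = _max_like_adj(a_total)
        ai = 100.0 * g_ii / max_g if max_g > 0 else None

        te = sum(p["perim"] for p in mine)
        min_e = min_perimeter(a_total)
        max_e = 4 * a_total
        nlsi = (te - min_e) / (max_e - min_e) if max_e > min_e else None

        out[cls] = {
            "LPI": lpi,
            "SHAPE_MN": shape_mn,
            "ENN_MN": enn_mn,
            "ENN_CV": enn_cv,
            "ECON_MN": econ_mn,
            "CLUMPY": clumpy,
            "IJI": iji,
            "AI": ai,
            "NLSI": nlsi,
        }
    return out


def enumerate_polyomino_min_perimeter(n: int) -> int:
    """Exhaustive minimum perimeter over all fixed polyominoes of n cells.

    Grows polyominoes cell by cell with canonical de-duplication; practical
    up to n ~ 8.
    """
    start = frozenset([(0, 0)])
    shapes = {start}
    for _ in range(n - 1):
        grown = set()
        for shape in shapes:
            for r, c in shape:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cell = (r + dr, c + dc)
                    if cell in shape:
                        continue
                    new = shape | {cell}
                    minr = min(x for x, _ in new)
                    minc = min(y for _, y in new)
                    grown.add(frozenset((x - minr, y - minc) for x, y in new))
        shapes = grown
    best = None
    for shape in shapes:
        perim = 0
        for r, c in shape:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (r + dr, c + dc) not in shape:
                    perim += 1
        if best is None or perim < best:
            best = perim
    return best
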